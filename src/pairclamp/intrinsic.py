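"""Spike detection, phase-plot threshold, F-I metrics and passive properties.

Spike detection registers a spike at the first sample where the smoothed
first derivative of the membrane voltage exceeds a criterion (default
1.5 mV/ms, i.e. 0.15 mV per 10-kHz sample) *and* the following 2 ms contain
an excursion of at least 20 mV above that sample -- the excursion gate
rejects derivative crossings produced by noise or by synaptic events.  The
voltage at the crossing sample is the per-spike firing threshold; on a
phase plot (dV/dt against V) it is the starting point of the spike loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .recordings import Recording, Trace, extract_window

__all__ = [
    "SpikeTrain",
    "PhasePlot",
    "FICurve",
    "PassiveProps",
    "ThresholdEstimate",
    "smoothed_dvdt",
    "detect_spikes",
    "phase_plot",
    "firing_threshold_60pA",
    "fi_curve",
    "input_resistance",
    "resting_potential",
]

DVDT_THRESHOLD_DEFAULT = 1.5  # mV/ms
LOCKOUT_MS = 2.0
PEAK_GATE_MS = 2.0
PEAK_GATE_MV = 20.0
THRESHOLD_BOUNDS = (-80.0, 0.0)


@dataclass(frozen=True)
class SpikeTrain:
    """Detected spikes of one sweep: take-off times and per-spike thresholds."""

    times: np.ndarray  # ms, strictly increasing
    thresholds: np.ndarray  # mV at take-off
    sweep_index: int = 0
    step_amplitude: Optional[float] = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class PhasePlot:
    """(V, dV/dt) loop of one spike with its threshold point."""

    voltage: np.ndarray  # mV
    dvdt: np.ndarray  # mV/ms
    threshold_point: tuple[float, float]  # (mV, mV/ms) at first criterion crossing


@dataclass(frozen=True)
class FICurve:
    """Per-step excitability metrics from an I-V step recording."""

    step_amplitudes: np.ndarray  # pA
    spike_counts: np.ndarray  # spikes per step window
    mean_inst_freq: np.ndarray  # Hz, nan where < 2 spikes
    first_two_freq: np.ndarray  # Hz, nan where < 2 spikes
    rheobase: Optional[float]  # pA, None if no step fired


@dataclass(frozen=True)
class PassiveProps:
    input_resistance: float  # MOhm
    resting_potential: float  # mV
    fit_points: np.ndarray  # (n, 2) array of (pA, mV)


@dataclass(frozen=True)
class ThresholdEstimate:
    value: Optional[float]  # mV, None when unavailable
    diagnostic: Optional[str] = None


def smoothed_dvdt(trace: Trace) -> tuple[np.ndarray, np.ndarray]:
    """3-point-smoothed voltage and its central-difference derivative (mV/ms)."""
    v = trace.samples
    if v.size < 5:
        raise ValueError("trace shorter than the derivative kernel")
    v_sm = np.convolve(v, np.full(3, 1.0 / 3.0), mode="same")
    v_sm[0], v_sm[-1] = v[0], v[-1]
    dvdt = np.gradient(v_sm, trace.dt)
    return v_sm, dvdt


def detect_spikes(
    trace: Trace, dvdt_threshold: float = DVDT_THRESHOLD_DEFAULT, sweep_index: int = 0,
    step_amplitude: Optional[float] = None,
) -> SpikeTrain:
    """Detect spike take-off times and thresholds in a voltage trace.

    Invariant to DC offsets (derivative-based); a refractory lockout of 2 ms
    follows each accepted spike.
    """
    if trace.signal_kind != "voltage":
        raise ValueError("spike detection requires a voltage trace")
    if dvdt_threshold <= 0:
        raise ValueError("dvdt_threshold must be positive")
    v_sm, dvdt = smoothed_dvdt(trace)
    dt = trace.dt
    above = dvdt > dvdt_threshold
    rising = np.flatnonzero(above & ~np.roll(above, 1))
    rising = rising[rising > 0]
    n_gate = int(round(PEAK_GATE_MS / dt))
    n_lock = int(round(LOCKOUT_MS / dt))
    times, thresholds = [], []
    last = -10 * n_lock
    n = v_sm.size
    for i in rising:
        if i < last + n_lock:
            continue
        j = min(i + n_gate + 1, n)
        if v_sm[i:j].max() - v_sm[i] < PEAK_GATE_MV:
            continue
        thr = v_sm[i]
        if not (THRESHOLD_BOUNDS[0] < thr < THRESHOLD_BOUNDS[1]):
            continue
        times.append(trace.t0 + i * dt)
        thresholds.append(thr)
        last = i
    return SpikeTrain(
        np.asarray(times), np.asarray(thresholds), sweep_index, step_amplitude
    )


def phase_plot(
    trace: Trace,
    spike_time: float,
    window: tuple[float, float] = (-5.0, 5.0),
    dvdt_threshold: float = DVDT_THRESHOLD_DEFAULT,
) -> PhasePlot:
    """Build the (V, dV/dt) loop around one spike.

    The threshold point is the first rising crossing of the derivative
    criterion inside the window; a windowed segment with no crossing (e.g. a
    pure ramp) raises ValueError.
    """
    t_lo = spike_time + window[0]
    t_hi = spike_time + window[1]
    if t_lo < trace.t0 or t_hi > trace.t0 + trace.duration:
        raise ValueError("phase-plot window exceeds the trace span")
    v_sm, dvdt = smoothed_dvdt(trace)
    i0 = int(math.ceil((t_lo - trace.t0) / trace.dt - 1e-9))
    i1 = int(math.ceil((t_hi - trace.t0) / trace.dt - 1e-9))
    v_w, d_w = v_sm[i0:i1], dvdt[i0:i1]
    above = d_w > dvdt_threshold
    rising = np.flatnonzero(above & ~np.roll(above, 1))
    rising = rising[rising > 0]
    if rising.size == 0:
        raise ValueError("no derivative-criterion crossing inside the window")
    k = int(rising[0])
    return PhasePlot(voltage=v_w, dvdt=d_w, threshold_point=(float(v_w[k]), float(d_w[k])))


def _step_window(rec: Recording) -> tuple[float, float]:
    meta = rec.meta or {}
    try:
        start = float(meta["step_start_ms"])
        dur = float(meta["step_duration_ms"])
    except KeyError as exc:
        raise ValueError("recording lacks step window annotations") from exc
    return start, dur


def _step_spikes(
    rec: Recording, dvdt_threshold: float
) -> list[SpikeTrain]:
    """Spikes of each sweep restricted to the step window."""
    start, dur = _step_window(rec)
    trains = []
    for idx, sw in enumerate(rec.sweeps):
        st = detect_spikes(sw.voltage, dvdt_threshold, idx, sw.step_amplitude)
        t0 = sw.voltage.t0
        keep = (st.times >= t0 + start) & (st.times < t0 + start + dur)
        trains.append(
            SpikeTrain(st.times[keep], st.thresholds[keep], idx, sw.step_amplitude)
        )
    return trains


def firing_threshold_60pA(
    rec: Recording,
    dvdt_threshold: float = DVDT_THRESHOLD_DEFAULT,
    step_amplitude: float = 60.0,
) -> ThresholdEstimate:
    """Phase-plot threshold of the first spike of the 60-pA step.

    Returns an absent estimate (with a diagnostic) when the 60-pA sweep has
    no spike; raises when the recording has no 60-pA sweep at all.
    """
    sweep = None
    index = None
    for idx, sw in enumerate(rec.sweeps):
        if sw.step_amplitude is not None and math.isclose(
            sw.step_amplitude, step_amplitude, abs_tol=1e-6
        ):
            sweep, index = sw, idx
            break
    if sweep is None:
        raise ValueError(f"no {step_amplitude:g} pA sweep in recording")
    train = _step_spikes(rec, dvdt_threshold)[index]
    if train.n == 0:
        return ThresholdEstimate(None, f"no spike at {step_amplitude:g} pA")
    pp = phase_plot(sweep.voltage, float(train.times[0]), dvdt_threshold=dvdt_threshold)
    return ThresholdEstimate(pp.threshold_point[0])


def fi_curve(rec: Recording, dvdt_threshold: float = DVDT_THRESHOLD_DEFAULT) -> FICurve:
    """Spike count, mean instantaneous frequency and first-two-spike
    frequency per current step, plus the rheobase.

    Instantaneous frequencies are 1000/ISI over consecutive spike pairs
    within each step window, averaged per step; steps with fewer than two
    spikes report nan frequencies.
    """
    trains = _step_spikes(rec, dvdt_threshold)
    amps, counts, mean_if, first2 = [], [], [], []
    for st in trains:
        if st.step_amplitude is None:
            continue
        amps.append(st.step_amplitude)
        counts.append(st.n)
        if st.n >= 2:
            isis = np.diff(st.times)
            mean_if.append(float(np.mean(1000.0 / isis)))
            first2.append(1000.0 / float(isis[0]))
        else:
            mean_if.append(np.nan)
            first2.append(np.nan)
    if not amps:
        raise ValueError("recording has no step-annotated sweeps")
    amps_arr = np.asarray(amps)
    counts_arr = np.asarray(counts)
    fired = amps_arr[counts_arr >= 1]
    rheobase = float(fired.min()) if fired.size else None
    return FICurve(
        step_amplitudes=amps_arr,
        spike_counts=counts_arr,
        mean_inst_freq=np.asarray(mean_if),
        first_two_freq=np.asarray(first2),
        rheobase=rheobase,
    )


def input_resistance(
    rec: Recording,
    i_min: float = -100.0,
    i_max: float = 40.0,
    steady_ms: float = 100.0,
    dvdt_threshold: float = DVDT_THRESHOLD_DEFAULT,
) -> PassiveProps:
    """Input resistance from the slope of the steady-state I-V relationship.

    Uses subthreshold steps in [i_min, i_max] pA, excluding any sweep with a
    detected spike; the steady-state voltage is the mean over the last
    ``steady_ms`` of the step; the slope is an ordinary least-squares fit in
    MOhm.  The resting potential is the median of the zero-command
    (pre-step) samples of the usable sweeps.
    """
    start, dur = _step_window(rec)
    points = []
    rest_segments = []
    for idx, sw in enumerate(rec.sweeps):
        amp = sw.step_amplitude
        if amp is None or not (i_min <= amp <= i_max):
            continue
        if detect_spikes(sw.voltage, dvdt_threshold, idx, amp).n > 0:
            continue
        t0 = sw.voltage.t0
        steady = extract_window(sw.voltage, t0 + start + dur - steady_ms, t0 + start + dur)
        points.append((amp, float(np.mean(steady.samples))))
        if start > 0:
            pre = extract_window(sw.voltage, t0, t0 + start)
            rest_segments.append(pre.samples)
    if len(points) < 3:
        raise ValueError(f"only {len(points)} usable subthreshold steps (need >= 3)")
    pts = np.asarray(points)
    slope = np.polyfit(pts[:, 0], pts[:, 1], 1)[0]  # mV per pA
    resistance = float(slope * 1000.0)  # MOhm
    if resistance <= 0:
        raise ValueError("non-positive fitted input resistance")
    rest = float(np.median(np.concatenate(rest_segments))) if rest_segments else np.nan
    return PassiveProps(resistance, rest, pts)


def resting_potential(trace: Trace, min_duration_ms: float = 10000.0) -> float:
    """Median membrane potential of a zero-command spontaneous segment."""
    if trace.duration < min_duration_ms:
        raise ValueError(
            f"segment of {trace.duration:g} ms shorter than required "
            f"{min_duration_ms:g} ms"
        )
    return float(np.median(trace.samples))
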