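"""Parameter containers and ground-truth bundle for the trace generator."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SpikeTemplate",
    "NeuronParams",
    "SynapseParams",
    "BackgroundParams",
    "ProtocolSpec",
    "EffectSpec",
    "GroundTruthBundle",
    "make_spike_template",
]


@dataclass(frozen=True)
class SpikeTemplate:
    """A stereotyped action-potential waveform in absolute mV.

    ``samples[take_off_index]`` equals the firing threshold: it is the first
    sample whose (smoothed) derivative exceeds the phase-plot detection
    criterion.  The waveform starts at the splice voltage (threshold minus
    the approach depth) with a sub-criterion approach, so a detector scanning
    for the first fast-rising sample lands exactly on the take-off point.
    """

    samples: np.ndarray
    take_off_index: int
    dt: float

    @property
    def take_off_voltage(self) -> float:
        return float(self.samples[self.take_off_index])


def make_spike_template(
    v_threshold: float,
    v_reset: float,
    dt: float,
    approach_depth: float = 16.0,
    spike_height: float = 55.0,
    pre_takeoff_ms: float = 3.0,
    pre_takeoff_slope: float = 0.2,
    approach_slope: float = 8.0,
    repol_ms: float = 2.5,
) -> SpikeTemplate:
    """Build the default spike waveform for a given threshold/reset pair.

    Segments: a fast sub-spike approach from the splice voltage, a slow
    (sub-criterion) final creep into threshold, an accelerating upstroke to
    ``v_threshold + spike_height``, and a half-cosine repolarization down to
    ``v_reset``.
    """
    if approach_depth <= pre_takeoff_ms * pre_takeoff_slope:
        raise ValueError("approach depth too small for the pre-takeoff creep")
    v_init = v_threshold - approach_depth
    creep_depth = pre_takeoff_ms * pre_takeoff_slope
    # Per-sample increments (mV).
    steps: list[float] = []
    # Approach from v_init up to (v_threshold - creep_depth).
    remaining = approach_depth - creep_depth
    while remaining > 1e-12:
        inc = min(approach_slope * dt, remaining)
        steps.append(inc)
        remaining -= inc
    # Slow creep into threshold; last creep sample sits exactly at v_threshold.
    n_creep = max(1, int(round(pre_takeoff_ms / dt)))
    steps.extend([creep_depth / n_creep] * n_creep)
    take_off_index = len(steps)
    # Accelerating upstroke (slopes in mV/ms, geometric-ish growth).
    up_slopes = [3.0, 6.0, 12.0, 24.0, 48.0, 96.0, 160.0]
    climbed = 0.0
    i = 0
    while climbed < spike_height - 1e-12:
        slope = up_slopes[min(i, len(up_slopes) - 1)]
        inc = min(slope * dt, spike_height - climbed)
        steps.append(inc)
        climbed += inc
        i += 1
    values = v_init + np.concatenate([[0.0], np.cumsum(steps)])
    peak = values[-1]
    # Half-cosine repolarization from the peak down to v_reset.
    n_rep = max(2, int(round(repol_ms / dt)))
    phase = np.linspace(0.0, np.pi, n_rep + 1)[1:]
    repol = v_reset + (peak - v_reset) * 0.5 * (1.0 + np.cos(phase))
    samples = np.concatenate([values, repol])
    tpl = SpikeTemplate(samples=samples, take_off_index=take_off_index, dt=dt)
    assert abs(tpl.take_off_voltage - v_threshold) < 0.01
    return tpl


@dataclass(frozen=True)
class NeuronParams:
    """Passive and spike-generation parameters of a simulated cell.

    The membrane follows an exponential integrate-and-fire equation; once
    the voltage reaches ``V_T - approach_depth`` a stereotyped spike
    waveform (whose take-off voltage equals ``V_T``) is spliced in and the
    membrane restarts from ``V_reset`` after a refractory period.
    """

    C: float = 100.0  # pF
    R: float = 278.0  # MOhm
    E_rest: float = -73.0  # mV
    V_T: float = -41.0  # mV
    Delta_T: float = 0.5  # mV
    V_reset: float = -61.0  # mV
    t_ref: float = 25.0  # ms
    approach_depth: float = 16.0  # mV between splice voltage and V_T
    spike_height: float = 55.0  # mV above threshold at the spike peak
    spike_template: Optional[SpikeTemplate] = None

    def __post_init__(self):
        if min(self.R, self.C, self.Delta_T, self.t_ref) <= 0:
            raise ValueError("R, C, Delta_T and t_ref must be positive")
        if not (self.V_reset < self.V_T < 0):
            raise ValueError("require V_reset < V_T < 0")
        if self.V_reset >= self.V_T - self.approach_depth:
            raise ValueError("V_reset must lie below the splice voltage")
        if self.spike_template is not None:
            if abs(self.spike_template.take_off_voltage - self.V_T) > 0.01:
                raise ValueError("template take-off must equal V_T within 0.01 mV")

    @property
    def tau(self) -> float:
        """Membrane time constant in ms."""
        return self.R * self.C / 1000.0

    @property
    def v_splice(self) -> float:
        return self.V_T - self.approach_depth

    def template(self, dt: float) -> SpikeTemplate:
        if self.spike_template is not None and abs(self.spike_template.dt - dt) < 1e-12:
            return self.spike_template
        return make_spike_template(
            self.V_T, self.V_reset, dt, self.approach_depth, self.spike_height
        )


@dataclass(frozen=True)
class SynapseParams:
    """Unitary synaptic response and short-term dynamics.

    ``q * U`` sets the mean first-pulse amplitude; within-train dynamics
    follow a release-fraction/recovery recursion (see
    :func:`pairclamp.synth.synapse.depletion_series`).
    """

    q: float = 40.0  # unitary amplitude scale: pA (EPSC) or mV (EPSP)
    latency: float = 2.0  # ms from presynaptic take-off to onset
    tau_rise: float = 0.5  # ms
    tau_decay: float = 4.0  # ms
    U: float = 0.35  # release fraction per spike
    tau_rec: float = 200.0  # ms recovery time constant
    failure_p: float = 0.3  # per-trial failure probability
    plasticity_scale: float = 1.0  # condition-dependent multiplier on q

    def __post_init__(self):
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("require tau_decay > tau_rise > 0")
        if not (0 <= self.U <= 1 and 0 <= self.failure_p <= 1):
            raise ValueError("U and failure_p must lie in [0, 1]")
        if self.q <= 0 or self.latency < 0:
            raise ValueError("q must be positive and latency non-negative")


@dataclass(frozen=True)
class BackgroundParams:
    """Poisson synaptic barrage with truncated-lognormal amplitudes (mV)."""

    rate_per_min: float = 430.0  # total event rate (detectable + sub-threshold)
    amp_median: float = 0.2  # mV, lognormal median
    amp_sigma: float = 0.5  # lognormal shape
    amp_min: float = 0.05  # mV truncation
    amp_max: float = 10.0  # mV truncation
    tau_rise: float = 1.0  # ms
    tau_decay: float = 15.0  # ms

    def __post_init__(self):
        if self.rate_per_min < 0:
            raise ValueError("rate must be non-negative")
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("require tau_decay > tau_rise > 0")
        if not (0 < self.amp_min < self.amp_max):
            raise ValueError("require 0 < amp_min < amp_max")


@dataclass(frozen=True)
class ProtocolSpec:
    """Description of one stimulation/acquisition protocol.

    Defaults mirror the experimental designs being emulated: 500-ms current
    steps from -100 to +160 pA in 20-pA increments, 20-Hz trains of ten 5-ms
    500-pA pulses, 10-Hz stimulation trains of 4 s on / 10 s rest, and
    zero-command spontaneous stretches -- all sampled at 10 kHz.
    """

    kind: str  # iv_steps | presyn_train | stim_train | spontaneous
    dt: float = 0.1  # ms (10 kHz)
    step_range: tuple[float, float, float] = (-100.0, 160.0, 20.0)
    step_duration: float = 500.0  # ms
    pre_ms: float = 100.0  # baseline before step/train onset
    post_ms: float = 150.0  # tail after step/train
    train_rate: float = 20.0  # Hz
    n_pulses: int = 10
    n_trials: int = 1
    pulse_width: float = 5.0  # ms
    pulse_amplitude: float = 500.0  # pA
    on_duration: float = 4000.0  # ms (stim_train)
    off_duration: float = 10000.0  # ms (stim_train)
    total_duration: float = 60000.0  # ms (spontaneous / stim_train)

    def __post_init__(self):
        if self.kind not in ("iv_steps", "presyn_train", "stim_train", "spontaneous"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.dt <= 0 or self.train_rate <= 0 or self.total_duration <= 0:
            raise ValueError("rates and durations must be positive")
        lo, hi, inc = self.step_range
        if inc <= 0 or (hi - lo) < 0:
            raise ValueError("bad step_range")
        n = (hi - lo) / inc
        if abs(n - round(n)) > 1e-9:
            raise ValueError("step increment must divide the step range")

    @property
    def step_amplitudes(self) -> np.ndarray:
        lo, hi, inc = self.step_range
        return lo + inc * np.arange(int(round((hi - lo) / inc)) + 1)


@dataclass(frozen=True)
class EffectSpec:
    """Programmed post-stimulation parameter shifts.

    Defaults encode the emulated effect sizes: input resistance scaled by
    305/278, threshold shifted by -2.7 mV, spontaneous-EPSP rate and
    amplitude scaled by 127/90 and 0.41/0.38, and evoked first-pulse
    amplitude scaled 1 -> 8/14 -> 20/14 across before/after/rest conditions.
    """

    rm_scale: float = 305.0 / 278.0
    threshold_shift: float = -2.7
    epsp_rate_scale: float = 127.0 / 90.0
    epsp_amp_scale: float = 0.41 / 0.38
    evoked_scale_by_condition: dict = field(
        default_factory=lambda: {
            "before": 1.0,
            "after_stim": 8.0 / 14.0,
            "rest_post": 20.0 / 14.0,
        }
    )

    def __post_init__(self):
        if min(self.rm_scale, self.epsp_rate_scale, self.epsp_amp_scale) <= 0:
            raise ValueError("scales must be positive")
        if any(v <= 0 for v in self.evoked_scale_by_condition.values()):
            raise ValueError("evoked scales must be positive")

    @classmethod
    def identity(cls) -> "EffectSpec":
        return cls(
            rm_scale=1.0,
            threshold_shift=0.0,
            epsp_rate_scale=1.0,
            epsp_amp_scale=1.0,
            evoked_scale_by_condition={
                "before": 1.0,
                "after_stim": 1.0,
                "rest_post": 1.0,
            },
        )


@dataclass
class GroundTruthBundle:
    """Simulator-emitted truth against which estimators are tested."""

    seed: Optional[int] = None
    spike_times: Optional[list] = None  # per sweep: ndarray of ms
    true_threshold: Optional[float] = None  # mV
    true_R: Optional[float] = None  # MOhm
    true_E_rest: Optional[float] = None  # mV
    epsp_event_times: Optional[np.ndarray] = None  # ms (kernel peak times)
    epsp_event_amps: Optional[np.ndarray] = None  # mV
    connected: Optional[bool] = None
    evoked_amplitudes: Optional[np.ndarray] = None  # (n_trials, n_pulses), 0 = failure
    analytic_amplitudes: Optional[np.ndarray] = None  # mean A_n series
    failure_mask: Optional[np.ndarray] = None  # (n_trials, n_pulses) bool
    shared_input_fraction: Optional[float] = None
    extras: dict = field(default_factory=dict)
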