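"""Membrane simulation: exponential integrate-and-fire with template splicing.

The subthreshold membrane follows

    dV/dt = (-(V - E_rest) + R*I + R*g_T*Delta_T*exp((V - V_T)/Delta_T)) / (R*C)

integrated by forward Euler at the protocol sampling step.  The exponential
term is calibrated so its unstable fixed point sits just below the splice
voltage ``V_T - approach_depth``; when the voltage reaches the splice
voltage, the stereotyped spike template is played back (take-off exactly at
``V_T``), the membrane restarts at ``V_reset``, and a refractory lockout
follows.  Gaussian recording noise is added to the assembled trace, so
ground-truth spike times are exact.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..recordings import Recording, Sweep, Trace
from .background import barrage_trace
from .params import BackgroundParams, GroundTruthBundle, NeuronParams, ProtocolSpec

__all__ = ["integrate_sweeps", "build_command", "simulate_neuron"]


def integrate_sweeps(
    command: np.ndarray, params: NeuronParams, dt: float
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Integrate a bank of current-clamp sweeps in parallel.

    Parameters
    ----------
    command : (n_sweeps, n_samples) array of injected current in pA.

    Returns
    -------
    voltage : (n_sweeps, n_samples) noiseless membrane voltage in mV.
    spikes : per sweep, array of take-off sample indices (as float ms offsets
        are applied by the caller).
    """
    command = np.atleast_2d(np.asarray(command, dtype=float))
    n_sweeps, n_samples = command.shape
    tpl = params.template(dt)
    tpl_samples, k_off, tpl_len = tpl.samples, tpl.take_off_index, tpl.samples.size
    tau = params.tau
    e, r = params.E_rest, params.R
    v_t, delta_t = params.V_T, params.Delta_T
    v_splice = params.v_splice
    # Calibrate exp-term gain: unstable fixed point 0.5 mV below the splice
    # voltage, so the nonlinearity is negligible in the subthreshold range.
    ln_a = (params.approach_depth + 0.5) / delta_t - 1.0
    n_ref = max(1, int(round(params.t_ref / dt)))

    v = np.full(n_sweeps, e)
    tpl_pos = np.full(n_sweeps, -1, dtype=np.int64)
    refr = np.zeros(n_sweeps, dtype=np.int64)
    out = np.empty((n_sweeps, n_samples))
    spike_idx: list[list[int]] = [[] for _ in range(n_sweeps)]

    coef = dt / tau
    for i in range(n_samples):
        playing = tpl_pos >= 0
        if playing.any():
            p = np.flatnonzero(playing)
            out[p, i] = tpl_samples[tpl_pos[p]]
            tpl_pos[p] += 1
            done = p[tpl_pos[p] >= tpl_len]
            if done.size:
                v[done] = params.V_reset
                refr[done] = n_ref
                tpl_pos[done] = -1
        active = np.flatnonzero(~playing)
        if active.size:
            va = v[active]
            arg = np.minimum(ln_a + (va - v_t) / delta_t, 10.0)
            drive = (e - va) + r * command[active, i] * 1e-3 + delta_t * np.exp(arg)
            ra = refr[active]
            # Absolute refractory hold: the membrane stays at V_reset.
            va = np.where(ra > 0, va, va + coef * drive)
            np.maximum(ra - 1, 0, out=ra)
            refr[active] = ra
            v[active] = va
            out[active, i] = va
            trig = active[(va >= v_splice) & (ra == 0)]
            if trig.size:
                out[trig, i] = tpl_samples[0]
                tpl_pos[trig] = 1
                for s in trig:
                    spike_idx[s].append(i + k_off)
    spikes = [
        np.asarray([j for j in idx if j < n_samples], dtype=np.int64)
        for idx in spike_idx
    ]
    return out, spikes


def build_command(protocol: ProtocolSpec) -> tuple[np.ndarray, list[Optional[float]], dict]:
    """Assemble the command-current matrix for a protocol.

    Returns (command (n_sweeps, n_samples) in pA, per-sweep step amplitude
    or None, layout metadata with step/train window positions in ms).
    """
    dt = protocol.dt
    if protocol.kind == "iv_steps":
        amps = protocol.step_amplitudes
        n_pre = int(round(protocol.pre_ms / dt))
        n_step = int(round(protocol.step_duration / dt))
        n_post = int(round(protocol.post_ms / dt))
        n = n_pre + n_step + n_post
        cmd = np.zeros((amps.size, n))
        cmd[:, n_pre : n_pre + n_step] = amps[:, None]
        meta = {
            "step_start_ms": protocol.pre_ms,
            "step_duration_ms": protocol.step_duration,
        }
        return cmd, [float(a) for a in amps], meta
    if protocol.kind == "presyn_train":
        period = 1000.0 / protocol.train_rate
        train_span = period * (protocol.n_pulses - 1) + protocol.pulse_width
        n = int(round((protocol.pre_ms + train_span + protocol.post_ms) / dt))
        row = np.zeros(n)
        n_pw = int(round(protocol.pulse_width / dt))
        pulse_starts = protocol.pre_ms + period * np.arange(protocol.n_pulses)
        for t in pulse_starts:
            i0 = int(round(t / dt))
            row[i0 : i0 + n_pw] = protocol.pulse_amplitude
        cmd = np.tile(row, (protocol.n_trials, 1))
        meta = {"pulse_starts_ms": pulse_starts.tolist(), "period_ms": period}
        return cmd, [None] * protocol.n_trials, meta
    if protocol.kind == "stim_train":
        n = int(round(protocol.total_duration / dt))
        row = np.zeros(n)
        n_pw = int(round(protocol.pulse_width / dt))
        period = 1000.0 / protocol.train_rate
        cycle = protocol.on_duration + protocol.off_duration
        t = 0.0
        while t < protocol.total_duration:
            t_on = t
            while t_on < min(t + protocol.on_duration, protocol.total_duration):
                i0 = int(round(t_on / dt))
                row[i0 : min(i0 + n_pw, n)] = protocol.pulse_amplitude
                t_on += period
            t += cycle
        return row[None, :], [None], {}
    # spontaneous
    n = int(round(protocol.total_duration / dt))
    return np.zeros((1, n)), [None], {}


def simulate_neuron(
    params: NeuronParams,
    protocol: ProtocolSpec,
    noise_sd: float = 0.1,
    seed: int = 0,
    background: Optional[BackgroundParams] = None,
    condition: str = "before",
    cell_id: str = "sim_cell",
    opsin: bool = False,
) -> tuple[Recording, GroundTruthBundle]:
    """Simulate one current-clamp recording with exact ground truth.

    ``background`` (spontaneous protocols only) superimposes a Poisson EPSP
    barrage on the passive membrane.  ``noise_sd`` is the SD in mV of the
    Gaussian recording noise added to the assembled voltage.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    dt = protocol.dt
    command, step_amps, meta = build_command(protocol)
    truth = GroundTruthBundle(
        seed=seed,
        true_threshold=params.V_T,
        true_R=params.R,
        true_E_rest=params.E_rest,
    )
    if protocol.kind == "spontaneous":
        n = command.shape[1]
        v = np.full((1, n), params.E_rest)
        if background is not None:
            wave, times, amps = barrage_trace(n, dt, background, rng)
            v = v + wave[None, :]
            truth.epsp_event_times = times
            truth.epsp_event_amps = amps
        spikes = [np.empty(0, dtype=np.int64)]
    else:
        v, spikes = integrate_sweeps(command, params, dt)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, v.shape)
    tag = {
        "iv_steps": "iv_step",
        "presyn_train": "presyn_train",
        "stim_train": "stim_train",
        "spontaneous": "spontaneous",
    }[protocol.kind]
    sweeps = [
        Sweep(
            Trace(v[i], dt, "voltage"),
            Trace(command[i], dt, "current"),
            protocol_tag=tag,
            step_amplitude=step_amps[i],
        )
        for i in range(v.shape[0])
    ]
    rec = Recording(
        cell_id=cell_id,
        clamp_mode="current_clamp",
        condition=condition,
        sweeps=sweeps,
        opsin_expressing=opsin,
        meta={"protocol": protocol.kind, **meta},
    )
    truth.spike_times = [idx * dt for idx in spikes]
    return rec, truth
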