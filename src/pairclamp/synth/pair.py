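"""Paired-cell simulation: shared-input spontaneous activity and evoked trains."""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
from scipy.signal import fftconvolve

from ..recordings import PairRecording, Recording, Sweep, Trace
from .background import (
    draw_events,
    events_to_wave,
    kernel_peak_delay,
    psp_kernel,
)
from .neuron import build_command, integrate_sweeps
from .params import (
    BackgroundParams,
    GroundTruthBundle,
    NeuronParams,
    ProtocolSpec,
    SynapseParams,
)
from .synapse import analytic_amplitudes

__all__ = ["simulate_pair"]


def _spont_recording(
    params: NeuronParams,
    wave: np.ndarray,
    dt: float,
    noise: np.ndarray,
    cell_id: str,
    condition: str,
) -> Recording:
    v = params.E_rest + wave + noise
    sweep = Sweep(
        Trace(v, dt, "voltage"),
        Trace(np.zeros_like(v), dt, "current"),
        protocol_tag="spontaneous",
    )
    return Recording(
        cell_id=cell_id,
        clamp_mode="current_clamp",
        condition=condition,
        sweeps=[sweep],
        meta={"protocol": "spontaneous"},
    )


def simulate_pair(
    pre_params: NeuronParams,
    post_params: NeuronParams,
    synapse: Optional[SynapseParams] = None,
    shared_input_fraction: float = 0.0,
    protocol: Optional[ProtocolSpec] = None,
    seed: int = 0,
    background: Optional[BackgroundParams] = None,
    noise_sd_mV: float = 0.05,
    noise_sd_pA: float = 2.0,
    condition: str = "before",
    pair_id: str = "pair",
) -> tuple[PairRecording, GroundTruthBundle]:
    """Simulate a pre/post pair under one protocol.

    ``spontaneous`` protocols give both cells a Poisson EPSP barrage of
    which a fraction ``shared_input_fraction`` (of the total rate) is a
    common stream with identical event times and amplitudes in both cells.
    ``presyn_train`` protocols drive the presynaptic cell with current
    pulses (current clamp) and, if a synapse is present, render depressing
    EPSCs with per-pulse failures on the postsynaptic voltage-clamp channel.
    """
    if not (0.0 <= shared_input_fraction <= 1.0):
        raise ValueError("shared_input_fraction must lie in [0, 1]")
    if protocol is None:
        protocol = ProtocolSpec(kind="spontaneous")
    rng = np.random.default_rng(seed)
    dt = protocol.dt
    truth = GroundTruthBundle(
        seed=seed,
        connected=synapse is not None,
        shared_input_fraction=shared_input_fraction,
        true_E_rest=post_params.E_rest,
        true_R=post_params.R,
        true_threshold=post_params.V_T,
    )

    if protocol.kind == "spontaneous":
        bg = background if background is not None else BackgroundParams()
        n = int(round(protocol.total_duration / dt))
        duration = n * dt
        shared_bg = replace(bg, rate_per_min=bg.rate_per_min * shared_input_fraction)
        own_bg = replace(bg, rate_per_min=bg.rate_per_min * (1 - shared_input_fraction))
        t_sh, a_sh = draw_events(duration, shared_bg, rng) if shared_bg.rate_per_min > 0 else (
            np.empty(0),
            np.empty(0),
        )
        waves, all_times, all_amps = [], [], []
        for _ in range(2):
            t_own, a_own = draw_events(duration, own_bg, rng) if own_bg.rate_per_min > 0 else (
                np.empty(0),
                np.empty(0),
            )
            t_all = np.concatenate([t_sh, t_own])
            a_all = np.concatenate([a_sh, a_own])
            order = np.argsort(t_all, kind="stable")
            t_all, a_all = t_all[order], a_all[order]
            waves.append(
                events_to_wave(t_all, a_all, n, dt, bg.tau_rise, bg.tau_decay)
            )
            all_times.append(t_all)
            all_amps.append(a_all)
        noise_pre = rng.normal(0.0, noise_sd_mV, n) if noise_sd_mV > 0 else np.zeros(n)
        noise_post = rng.normal(0.0, noise_sd_mV, n) if noise_sd_mV > 0 else np.zeros(n)
        pre_rec = _spont_recording(
            pre_params, waves[0], dt, noise_pre, f"{pair_id}_pre", condition
        )
        post_rec = _spont_recording(
            post_params, waves[1], dt, noise_post, f"{pair_id}_post", condition
        )
        delay = kernel_peak_delay(bg.tau_rise, bg.tau_decay)
        keep = all_times[1] + delay < duration
        truth.epsp_event_times = all_times[1][keep] + delay
        truth.epsp_event_amps = all_amps[1][keep]
        truth.extras["pre_event_times"] = all_times[0] + delay
        truth.extras["pre_event_amps"] = all_amps[0]
        return PairRecording(pre_rec, post_rec), truth

    if protocol.kind != "presyn_train":
        raise ValueError(f"simulate_pair does not support protocol {protocol.kind!r}")

    # --- presynaptic spikes: one noiseless trial, replicated across sweeps ---
    single = replace(protocol, n_trials=1)
    command, _, meta = build_command(single)
    v_clean, spikes = integrate_sweeps(command, pre_params, dt)
    spike_times = spikes[0] * dt
    n = command.shape[1]
    n_trials = protocol.n_trials
    pre_sweeps = []
    for _ in range(n_trials):
        noise = rng.normal(0.0, noise_sd_mV, n) if noise_sd_mV > 0 else np.zeros(n)
        pre_sweeps.append(
            Sweep(
                Trace(v_clean[0] + noise, dt, "voltage"),
                Trace(command[0], dt, "current"),
                protocol_tag="presyn_train",
            )
        )
    pre_rec = Recording(
        cell_id=f"{pair_id}_pre",
        clamp_mode="current_clamp",
        condition=condition,
        sweeps=pre_sweeps,
        meta={"protocol": "presyn_train", **meta},
    )
    truth.spike_times = [spike_times] * n_trials

    # --- postsynaptic voltage-clamp current ---
    n_pulses = spike_times.size
    post_wave = np.zeros((n_trials, n))
    if synapse is not None and n_pulses:
        a_n = analytic_amplitudes(synapse, n_pulses, protocol.train_rate)
        failures = rng.random((n_trials, n_pulses)) < synapse.failure_p
        clean = np.where(failures, 0.0, a_n[None, :])
        kernel = psp_kernel(synapse.tau_rise, synapse.tau_decay, dt)
        onset_idx = np.floor((spike_times + synapse.latency) / dt).astype(np.int64)
        impulses = np.zeros((n_trials, n))
        valid = onset_idx < n
        impulses[:, onset_idx[valid]] = -clean[:, valid]  # inward = negative
        post_wave = fftconvolve(impulses, kernel[None, :], axes=1)[:, :n]
        truth.evoked_amplitudes = clean
        truth.analytic_amplitudes = a_n
        truth.failure_mask = failures
    post_noise = rng.normal(0.0, noise_sd_pA, (n_trials, n)) if noise_sd_pA > 0 else 0.0
    post_i = post_wave + post_noise
    post_sweeps = [
        Sweep(
            Trace(post_i[t], dt, "current"),
            Trace(np.zeros(n), dt, "current"),
            protocol_tag="presyn_train",
        )
        for t in range(n_trials)
    ]
    post_rec = Recording(
        cell_id=f"{pair_id}_post",
        clamp_mode="voltage_clamp",
        condition=condition,
        sweeps=post_sweeps,
        meta={"protocol": "presyn_train", **meta},
    )
    return PairRecording(pre_rec, post_rec), truth
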