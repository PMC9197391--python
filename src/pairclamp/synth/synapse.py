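"""Short-term synaptic dynamics: depletion/recovery recursion and evoked trains.

The mean amplitude of pulse ``n`` in a regular train is ``A_n = q * U * R_n``
with resource series ``R_1 = 1`` and

    R_{n+1} = 1 - (1 - (1 - U) * R_n) * exp(-dt / tau_rec)

(``dt`` the inter-pulse interval).  For the canonical check U=0.5,
tau_rec=200 ms at 20 Hz this gives R_2 = 1 - 0.5*exp(-0.25) ~= 0.61065, i.e.
a paired-pulse ratio of ~0.611.
"""

from __future__ import annotations

import numpy as np

from .params import GroundTruthBundle, SynapseParams

__all__ = ["depletion_series", "analytic_amplitudes", "simulate_evoked_train"]


def depletion_series(U: float, tau_rec: float, dt_ms: float, n_pulses: int) -> np.ndarray:
    """Resource availability R_n for each pulse of a regular train."""
    if n_pulses < 1:
        raise ValueError("need at least one pulse")
    r = np.empty(n_pulses)
    r[0] = 1.0
    decay = np.exp(-dt_ms / tau_rec)
    for n in range(n_pulses - 1):
        r[n + 1] = 1.0 - (1.0 - (1.0 - U) * r[n]) * decay
    return r


def analytic_amplitudes(synapse: SynapseParams, n_pulses: int, rate_hz: float) -> np.ndarray:
    """Mean (pre-failure) amplitude series A_n = q * U * R_n * plasticity_scale."""
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    dt_ms = 1000.0 / rate_hz
    r = depletion_series(synapse.U, synapse.tau_rec, dt_ms, n_pulses)
    return synapse.q * synapse.U * synapse.plasticity_scale * r


def simulate_evoked_train(
    synapse: SynapseParams,
    n_pulses: int = 10,
    rate_hz: float = 20.0,
    n_trials: int = 30,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruthBundle]:
    """Draw a (n_trials, n_pulses) table of noisy per-pulse amplitudes.

    Each (trial, pulse) response fails independently with probability
    ``failure_p`` (a failure is a true zero); measurement noise is then added
    to every entry.  The truth bundle carries the analytic mean series, the
    failure mask, and the noise-free amplitudes.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    a_n = analytic_amplitudes(synapse, n_pulses, rate_hz)
    failures = rng.random((n_trials, n_pulses)) < synapse.failure_p
    clean = np.where(failures, 0.0, a_n[None, :])
    noisy = clean + rng.normal(0.0, noise_sd, clean.shape)
    truth = GroundTruthBundle(
        seed=seed,
        evoked_amplitudes=clean,
        analytic_amplitudes=a_n,
        failure_mask=failures,
        connected=True,
    )
    return noisy, truth
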