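"""Poisson synaptic barrage with truncated-lognormal amplitudes."""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import fftconvolve

from .params import BackgroundParams

__all__ = ["psp_kernel", "kernel_peak_delay", "draw_events", "events_to_wave", "barrage_trace"]


def psp_kernel(tau_rise: float, tau_decay: float, dt: float) -> np.ndarray:
    """Peak-normalized double-exponential kernel sampled at dt."""
    length = int(round(8.0 * tau_decay / dt))
    t = np.arange(length) * dt
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return k / k.max()


def kernel_peak_delay(tau_rise: float, tau_decay: float) -> float:
    """Time (ms) from event onset to kernel peak."""
    return (
        tau_rise
        * tau_decay
        / (tau_decay - tau_rise)
        * math.log(tau_decay / tau_rise)
    )


def draw_events(
    duration_ms: float, bg: BackgroundParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw Poisson event onset times (ms, sorted) and amplitudes (mV)."""
    lam = bg.rate_per_min * duration_ms / 60000.0
    n = rng.poisson(lam)
    times = np.sort(rng.uniform(0.0, duration_ms, n))
    mu = math.log(bg.amp_median)
    amps = np.exp(rng.normal(mu, bg.amp_sigma, n))
    # Truncate by resampling out-of-range draws.
    bad = (amps < bg.amp_min) | (amps > bg.amp_max)
    while bad.any():
        amps[bad] = np.exp(rng.normal(mu, bg.amp_sigma, int(bad.sum())))
        bad = (amps < bg.amp_min) | (amps > bg.amp_max)
    return times, amps


def events_to_wave(
    onset_times: np.ndarray,
    amps: np.ndarray,
    n_samples: int,
    dt: float,
    tau_rise: float,
    tau_decay: float,
) -> np.ndarray:
    """Superimpose peak-normalized kernels at the given onsets."""
    impulses = np.zeros(n_samples)
    idx = np.floor(onset_times / dt).astype(np.int64)
    keep = (idx >= 0) & (idx < n_samples)
    np.add.at(impulses, idx[keep], amps[keep])
    kernel = psp_kernel(tau_rise, tau_decay, dt)
    return fftconvolve(impulses, kernel)[:n_samples]


def barrage_trace(
    n_samples: int, dt: float, bg: BackgroundParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate a barrage waveform plus truth (kernel-peak times, amplitudes)."""
    duration = n_samples * dt
    onsets, amps = draw_events(duration, bg, rng)
    wave = events_to_wave(onsets, amps, n_samples, dt, bg.tau_rise, bg.tau_decay)
    peak_times = onsets + kernel_peak_delay(bg.tau_rise, bg.tau_decay)
    keep = peak_times < duration
    return wave, peak_times[keep], amps[keep]
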