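"""Pairwise correlation of spontaneous activity."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intrinsic import detect_spikes
from .recordings import PairRecording, Recording, Trace, extract_window
from .stats import GroupComparison, compare_groups
from .synaptic import baseline_residual

__all__ = ["CorrelationResult", "pair_correlation", "correlation_contrast"]

METHODS = ("filtered_voltage", "binned_spikes")


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    window: tuple[float, float]  # ms
    method: str
    params: dict

    def __post_init__(self):
        if self.window[1] - self.window[0] < 60000.0 - 1e-6:
            raise ValueError("correlation window must span at least 60 s")


def _spont_trace(rec: Recording) -> Trace:
    for sw in rec.sweeps:
        if sw.protocol_tag == "spontaneous":
            return sw.voltage
    raise ValueError(f"recording {rec.cell_id} has no spontaneous sweep")


def _clamp(r: float) -> float:
    if abs(r) > 1.0:
        assert abs(r) - 1.0 < 1e-9, f"correlation out of bounds: {r}"
        r = float(np.clip(r, -1.0, 1.0))
    return r


def pair_correlation(
    pair: PairRecording,
    window_min: float = 3.0,
    method: str = "filtered_voltage",
    cutoff_hz: float = 1.0,
    bin_ms: float = 100.0,
) -> CorrelationResult:
    """Product-moment correlation of the first ``window_min`` minutes of
    simultaneous zero-command activity.

    ``filtered_voltage`` correlates the baseline-subtracted (1-Hz zero-phase
    low-pass removed) voltages; ``binned_spikes`` correlates 100-ms spike
    counts.  A dead channel (zero variance) is undefined and raises.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if window_min < 1.0:
        raise ValueError("correlation window must be at least 1 min")
    tr_pre = _spont_trace(pair.pre)
    tr_post = _spont_trace(pair.post)
    span = window_min * 60000.0
    if tr_pre.duration < span or tr_post.duration < span:
        raise ValueError("window exceeds the available spontaneous data")
    w_pre = extract_window(tr_pre, tr_pre.t0, tr_pre.t0 + span)
    w_post = extract_window(tr_post, tr_post.t0, tr_post.t0 + span)
    if method == "filtered_voltage":
        x = baseline_residual(w_pre, cutoff_hz)
        y = baseline_residual(w_post, cutoff_hz)
        params = {"cutoff_hz": cutoff_hz}
    else:
        edges = np.arange(0.0, span + bin_ms / 2, bin_ms)
        x = np.histogram(detect_spikes(w_pre).times - w_pre.t0, bins=edges)[0].astype(float)
        y = np.histogram(detect_spikes(w_post).times - w_post.t0, bins=edges)[0].astype(float)
        params = {"bin_ms": bin_ms}
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("dead channel: zero variance in the correlation window")
    r = _clamp(float(np.corrcoef(x, y)[0, 1]))
    return CorrelationResult(
        coefficient=r,
        window=(tr_pre.t0, tr_pre.t0 + span),
        method=method,
        params=params,
    )


def _coeffs(values: Sequence) -> np.ndarray:
    return np.asarray(
        [v.coefficient if isinstance(v, CorrelationResult) else float(v) for v in values]
    )


def correlation_contrast(
    group_a: Sequence,
    group_b: Sequence,
    labels: tuple[str, str] = ("connected", "unconnected"),
    paired: bool = False,
) -> GroupComparison:
    """Contrast two groups of correlation coefficients.

    Unpaired contrasts (e.g. connected vs unconnected pairs) use the
    Mann-Whitney test; paired before/after contrasts use the Wilcoxon
    signed-rank test.  Groups may hold CorrelationResults or floats.
    """
    a, b = _coeffs(group_a), _coeffs(group_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 pairs")
    return compare_groups(a, b, labels=labels, paired=paired)
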