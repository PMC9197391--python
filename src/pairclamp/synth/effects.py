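"""Condition-dependent parameter adjustment (post-stimulation shifts)."""

from __future__ import annotations

from dataclasses import replace

from .params import BackgroundParams, EffectSpec, NeuronParams, SynapseParams

__all__ = ["apply_effect"]

# Conditions under which the excitability/background shifts are in force.
_SHIFTED_CONDITIONS = ("after_stim", "rest_post")


def apply_effect(base, effect: EffectSpec, condition: str):
    """Return a copy of ``base`` with the effect for ``condition`` applied.

    Pure function.  Neuron parameters: R is scaled and the threshold shifted
    for post-stimulation conditions (the excitability change persists through
    the rest period).  Synapse parameters: the evoked plasticity scale for
    the condition multiplies ``plasticity_scale``.  Background parameters:
    event rate and amplitude scale for post-stimulation conditions.
    """
    if condition not in effect.evoked_scale_by_condition:
        raise ValueError(
            f"condition {condition!r} not covered by the effect mapping "
            f"{sorted(effect.evoked_scale_by_condition)}"
        )
    if isinstance(base, NeuronParams):
        if condition in _SHIFTED_CONDITIONS:
            return replace(
                base,
                R=base.R * effect.rm_scale,
                V_T=base.V_T + effect.threshold_shift,
                spike_template=None,
            )
        return base
    if isinstance(base, SynapseParams):
        scale = effect.evoked_scale_by_condition[condition]
        return replace(base, plasticity_scale=base.plasticity_scale * scale)
    if isinstance(base, BackgroundParams):
        if condition in _SHIFTED_CONDITIONS:
            return replace(
                base,
                rate_per_min=base.rate_per_min * effect.epsp_rate_scale,
                amp_median=base.amp_median * effect.epsp_amp_scale,
            )
        return base
    raise TypeError(f"cannot apply an EffectSpec to {type(base).__name__}")
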