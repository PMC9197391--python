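"""Reproducible synthetic cohorts of recorded pairs with a truth manifest."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from ..recordings import PairRecording, Recording, write_pair, write_recording
from .effects import apply_effect
from .neuron import simulate_neuron
from .pair import simulate_pair
from .params import (
    BackgroundParams,
    EffectSpec,
    GroundTruthBundle,
    NeuronParams,
    ProtocolSpec,
    SynapseParams,
)

__all__ = ["CohortSpec", "CohortPair", "iter_cohort", "generate_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Description of a synthetic cohort.

    The default mirrors the emulated study's design: 28 recorded pairs of
    which 7 carry a monosynaptic connection.  Connected pairs receive a
    synapse whose first-pulse amplitude scales across conditions per the
    effect spec, plus a higher shared-background fraction than unconnected
    pairs.
    """

    n_pairs: int = 28
    n_connected: int = 7
    conditions: tuple[str, ...] = ("before", "after_stim", "rest_post")
    protocols: tuple[str, ...] = ("presyn_train",)
    n_trials: int = 30
    spont_duration_ms: float = 60000.0
    shared_connected: float = 0.4
    shared_unconnected: float = 0.15
    q_jitter: float = 0.08  # lognormal sigma on per-pair unitary amplitude
    noise_sd_mV: float = 0.05
    noise_sd_pA: float = 2.0
    neuron: NeuronParams = field(default_factory=NeuronParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    background: BackgroundParams = field(default_factory=BackgroundParams)
    effect: EffectSpec = field(default_factory=EffectSpec)

    def __post_init__(self):
        if self.n_connected > self.n_pairs:
            raise ValueError("n_connected cannot exceed n_pairs")
        for c in self.conditions:
            if c not in self.effect.evoked_scale_by_condition:
                raise ValueError(f"effect mapping does not cover condition {c!r}")


@dataclass
class CohortPair:
    """One simulated pair: recordings and truth per (protocol, condition)."""

    pair_id: str
    index: int
    connected: bool
    shared_input_fraction: float
    synapse: Optional[SynapseParams]
    recordings: dict[tuple[str, str], PairRecording] = field(default_factory=dict)
    truths: dict[tuple[str, str], GroundTruthBundle] = field(default_factory=dict)
    cell_recordings: dict[tuple[str, str], Recording] = field(default_factory=dict)
    cell_truths: dict[tuple[str, str], GroundTruthBundle] = field(default_factory=dict)


def iter_cohort(spec: CohortSpec, seed: int = 0) -> Iterator[CohortPair]:
    """Yield the cohort pair by pair, fully determined by the master seed."""
    master = np.random.default_rng(seed)
    for i in range(spec.n_pairs):
        connected = i < spec.n_connected
        pair_id = f"pair_{i:03d}"
        q_scale = float(np.exp(master.normal(0.0, spec.q_jitter)))
        shared = spec.shared_connected if connected else spec.shared_unconnected
        shared = float(np.clip(shared + master.normal(0.0, 0.02), 0.0, 1.0))
        synapse = replace(spec.synapse, q=spec.synapse.q * q_scale) if connected else None
        pair = CohortPair(
            pair_id=pair_id,
            index=i,
            connected=connected,
            shared_input_fraction=shared,
            synapse=synapse,
        )
        for condition in spec.conditions:
            neuron_c = apply_effect(spec.neuron, spec.effect, condition)
            bg_c = apply_effect(spec.background, spec.effect, condition)
            syn_c = (
                apply_effect(synapse, spec.effect, condition)
                if synapse is not None
                else None
            )
            for proto_name in spec.protocols:
                sim_seed = int(master.integers(2**62))
                if proto_name == "presyn_train":
                    protocol = ProtocolSpec(
                        kind="presyn_train", n_trials=spec.n_trials
                    )
                    rec, truth = simulate_pair(
                        neuron_c,
                        neuron_c,
                        synapse=syn_c,
                        shared_input_fraction=shared,
                        protocol=protocol,
                        seed=sim_seed,
                        noise_sd_mV=spec.noise_sd_mV,
                        noise_sd_pA=spec.noise_sd_pA,
                        condition=condition,
                        pair_id=pair_id,
                    )
                    pair.recordings[(proto_name, condition)] = rec
                    pair.truths[(proto_name, condition)] = truth
                elif proto_name == "spontaneous":
                    protocol = ProtocolSpec(
                        kind="spontaneous", total_duration=spec.spont_duration_ms
                    )
                    rec, truth = simulate_pair(
                        neuron_c,
                        neuron_c,
                        synapse=syn_c,
                        shared_input_fraction=shared,
                        protocol=protocol,
                        seed=sim_seed,
                        background=bg_c,
                        noise_sd_mV=spec.noise_sd_mV,
                        condition=condition,
                        pair_id=pair_id,
                    )
                    pair.recordings[(proto_name, condition)] = rec
                    pair.truths[(proto_name, condition)] = truth
                elif proto_name == "iv_steps":
                    protocol = ProtocolSpec(kind="iv_steps")
                    rec, truth = simulate_neuron(
                        neuron_c,
                        protocol,
                        noise_sd=0.1,
                        seed=sim_seed,
                        condition=condition,
                        cell_id=f"{pair_id}_post",
                    )
                    pair.cell_recordings[(proto_name, condition)] = rec
                    pair.cell_truths[(proto_name, condition)] = truth
                else:
                    raise ValueError(f"unknown cohort protocol {proto_name!r}")
        yield pair


def generate_cohort(spec: CohortSpec, path, seed: int = 0) -> Path:
    """Write the cohort to ``path`` (one directory per pair) plus a manifest.

    Layout: ``<path>/pair_000/<protocol>_<condition>/{pre,post}`` with the
    canonical sweep-directory format; single-cell protocol recordings are
    written as ``<protocol>_<condition>_post``.  ``manifest.csv`` has one
    row per pair with the generating truth.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for pair in iter_cohort(spec, seed):
        pair_dir = path / pair.pair_id
        for (proto, cond), rec in pair.recordings.items():
            write_pair(rec, pair_dir / f"{proto}_{cond}")
        for (proto, cond), rec in pair.cell_recordings.items():
            write_recording(rec, pair_dir / f"{proto}_{cond}_post")
        row = {
            "pair_id": pair.pair_id,
            "connected": pair.connected,
            "shared_input_fraction": pair.shared_input_fraction,
            "q_pA": pair.synapse.q if pair.synapse else np.nan,
            "U": pair.synapse.U if pair.synapse else np.nan,
            "failure_p": pair.synapse.failure_p if pair.synapse else np.nan,
        }
        for cond in spec.conditions:
            truth = pair.truths.get(("presyn_train", cond))
            if truth is not None and truth.analytic_amplitudes is not None:
                row[f"A1_{cond}_pA"] = truth.analytic_amplitudes[0]
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(path / "manifest.csv", index=False, float_format="%.9g")
    return path
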