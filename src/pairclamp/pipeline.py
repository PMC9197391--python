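"""End-to-end orchestration: simulate/load a cohort, run every analysis
stage, and emit deterministic CSV tables plus a run manifest."""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from . import __version__
from .correlation import correlation_contrast, pair_correlation
from .intrinsic import (
    detect_spikes,
    fi_curve,
    firing_threshold_60pA,
    input_resistance,
)
from .recordings import PairRecording, Recording, qc_recording, read_pair, read_recording
from .stats import compare_groups
from .synaptic import (
    classify_connection,
    detect_spontaneous_epsps,
    evoked_response,
    paired_pulse_ratio,
)
from .synth import CohortPair, CohortSpec, iter_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

_FLOAT_FMT = "%.9g"


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; defaults are the documented values."""

    out_dir: str = "pairclamp_out"
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    input_root: Optional[str] = None  # analyze an on-disk cohort instead
    method: str = "filtered_voltage"
    dvdt_threshold: float = 1.5  # mV/ms
    correlation_window_min: float = 1.0
    classify_k: float = 1.5
    latency_center_ms: float = 2.0
    latency_tol_ms: float = 1.0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cohort_raw = raw.pop("cohort", None)
        cfg = cls(**raw)
        if cohort_raw:
            cfg.cohort = CohortSpec(**cohort_raw)
        return cfg


def _parse_subdir(name: str) -> Optional[tuple[str, str]]:
    for proto in ("presyn_train", "spontaneous", "iv_steps"):
        if name.startswith(proto + "_"):
            rest = name[len(proto) + 1 :]
            return proto, rest
    return None


def _load_cohort(root: Path) -> Iterator[CohortPair]:
    pair_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not pair_dirs:
        raise ValueError(f"no pair directories under {root}")
    for idx, pdir in enumerate(pair_dirs):
        pair = CohortPair(
            pair_id=pdir.name,
            index=idx,
            connected=False,
            shared_input_fraction=float("nan"),
            synapse=None,
        )
        for sub in sorted(d for d in pdir.iterdir() if d.is_dir()):
            parsed = _parse_subdir(sub.name)
            if parsed is None:
                continue
            proto, cond = parsed
            if cond.endswith("_post"):
                pair.cell_recordings[(proto, cond[: -len("_post")])] = read_recording(sub)
            else:
                pair.recordings[(proto, cond)] = read_pair(sub)
        yield pair


def _analyze_pair(pair: CohortPair, cfg: PipelineConfig, tables: dict) -> None:
    conditions_seen = sorted({c for (_, c) in pair.recordings} | {c for (_, c) in pair.cell_recordings})
    calls = {}
    for cond in conditions_seen:
        rec = pair.recordings.get(("presyn_train", cond))
        if rec is not None:
            trains = [
                detect_spikes(sw.voltage, cfg.dvdt_threshold, i)
                for i, sw in enumerate(rec.pre.sweeps)
            ]
            resp = evoked_response(rec, trains, mode="EPSC")
            call = classify_connection(
                resp,
                k=cfg.classify_k,
                latency_center=cfg.latency_center_ms,
                latency_tol=cfg.latency_tol_ms,
            )
            calls[cond] = call
            tables["pairs"].append(
                {
                    "pair_id": pair.pair_id,
                    "condition": cond,
                    "mean_epsc1_pA": resp.mean_epsc1,
                    "mean_epsc2_pA": resp.mean_epsc2,
                    "ppr": paired_pulse_ratio(resp),
                    "latency_ms": resp.latency,
                    "failure_rate": resp.failure_rate,
                    "connected": call.connected,
                    "noise_sd_pA": resp.noise_sd,
                }
            )
        srec = pair.recordings.get(("spontaneous", cond))
        if srec is not None:
            window = min(
                cfg.correlation_window_min,
                srec.post.sweeps[0].voltage.duration / 60000.0,
            )
            try:
                corr = pair_correlation(srec, window_min=window, method=cfg.method)
                tables["correlations"].append(
                    {
                        "pair_id": pair.pair_id,
                        "condition": cond,
                        "method": corr.method,
                        "window_s": (corr.window[1] - corr.window[0]) / 1000.0,
                        "coefficient": corr.coefficient,
                    }
                )
            except ValueError as exc:
                tables["errors"].append(
                    {"pair_id": pair.pair_id, "stage": "correlation", "error": str(exc)}
                )
            try:
                _, summary = detect_spontaneous_epsps(srec.post.sweeps[0].voltage)
                tables["epsp"].append(
                    {
                        "cell_id": srec.post.cell_id,
                        "pair_id": pair.pair_id,
                        "condition": cond,
                        "events_per_min": summary.frequency,
                        "mean_amp_mV": summary.mean_amplitude,
                        "n_events": summary.n_events,
                    }
                )
            except ValueError as exc:
                tables["errors"].append(
                    {"pair_id": pair.pair_id, "stage": "epsp", "error": str(exc)}
                )
        crec = pair.cell_recordings.get(("iv_steps", cond))
        if crec is not None:
            try:
                fic = fi_curve(crec, cfg.dvdt_threshold)
                passive = input_resistance(crec, dvdt_threshold=cfg.dvdt_threshold)
                thr = firing_threshold_60pA(crec, cfg.dvdt_threshold)
                qc = qc_recording(crec)
                tables["intrinsic"].append(
                    {
                        "cell_id": crec.cell_id,
                        "pair_id": pair.pair_id,
                        "condition": cond,
                        "rm_Mohm": passive.input_resistance,
                        "vrest_mV": passive.resting_potential,
                        "threshold_mV": thr.value if thr.value is not None else float("nan"),
                        "rheobase_pA": fic.rheobase if fic.rheobase is not None else float("nan"),
                        "mean_spikes_per_step": float(np.mean(fic.spike_counts)),
                        "mean_if_Hz": float(np.nanmean(fic.mean_inst_freq))
                        if np.any(np.isfinite(fic.mean_inst_freq))
                        else float("nan"),
                        "first2_Hz": float(np.nanmean(fic.first_two_freq))
                        if np.any(np.isfinite(fic.first_two_freq))
                        else float("nan"),
                        "qc_pass": qc.passed,
                    }
                )
            except ValueError as exc:
                tables["errors"].append(
                    {"pair_id": pair.pair_id, "stage": "intrinsic", "error": str(exc)}
                )
    # The connection call for the pair is made on the baseline condition.
    base_call = calls.get("before") or (next(iter(calls.values())) if calls else None)
    if base_call is not None:
        tables["connections"].append(
            {
                "pair_id": pair.pair_id,
                "connected_call": base_call.connected,
                "connected_truth": pair.connected,
                "mean_epsc1_pA": base_call.mean_epsc1,
                "threshold_pA": base_call.threshold_used,
                "latency_ms": base_call.latency,
            }
        )


def _paired_contrast(df, value, cond_a, cond_b, key="pair_id"):
    wide = df.pivot_table(index=key, columns="condition", values=value, aggfunc="first")
    if cond_a not in wide.columns or cond_b not in wide.columns:
        return None
    both = wide[[cond_a, cond_b]].dropna()
    if len(both) < 2:
        return None
    return compare_groups(
        both[cond_a].to_numpy(),
        both[cond_b].to_numpy(),
        labels=(cond_a, cond_b),
        paired=True,
    )


def _group_rows(tables: dict) -> list[dict]:
    rows = []

    def add(measure, gc):
        if gc is None:
            return
        rows.append(
            {
                "measure": measure,
                "group_a": gc.labels[0],
                "group_b": gc.labels[1],
                "median_a": gc.medians[0],
                "sem_a": gc.sems[0],
                "median_b": gc.medians[1],
                "sem_b": gc.sems[1],
                "n_a": gc.ns[0],
                "n_b": gc.ns[1],
                "test": gc.test,
                "p_value": gc.p_value,
            }
        )

    if tables["pairs"]:
        pairs = pd.DataFrame(tables["pairs"])
        conn = pd.DataFrame(tables["connections"]) if tables["connections"] else None
        if conn is not None:
            connected_ids = set(conn.loc[conn["connected_call"], "pair_id"])
            sub = pairs[pairs["pair_id"].isin(connected_ids)]
            add("epsc1", _paired_contrast(sub, "mean_epsc1_pA", "before", "after_stim"))
            add("epsc1_rest", _paired_contrast(sub, "mean_epsc1_pA", "before", "rest_post"))
            add("ppr", _paired_contrast(sub, "ppr", "before", "after_stim"))
    if tables["correlations"]:
        corr = pd.DataFrame(tables["correlations"])
        add("correlation", _paired_contrast(corr, "coefficient", "before", "after_stim"))
        conn = pd.DataFrame(tables["connections"]) if tables["connections"] else None
        if conn is not None and conn["connected_call"].nunique() == 2:
            before = corr[corr["condition"] == "before"].set_index("pair_id")["coefficient"]
            is_conn = conn.set_index("pair_id")["connected_call"]
            joined = before.to_frame().join(is_conn, how="inner")
            a = joined.loc[joined["connected_call"], "coefficient"]
            b = joined.loc[~joined["connected_call"], "coefficient"]
            if len(a) >= 2 and len(b) >= 2:
                add(
                    "correlation_by_connectivity",
                    compare_groups(a, b, labels=("connected", "unconnected")),
                )
    if tables["epsp"]:
        ep = pd.DataFrame(tables["epsp"])
        add("epsp_frequency", _paired_contrast(ep, "events_per_min", "before", "after_stim"))
        add("epsp_amplitude", _paired_contrast(ep, "mean_amp_mV", "before", "after_stim"))
    if tables["intrinsic"]:
        intr = pd.DataFrame(tables["intrinsic"])
        for measure, col in [
            ("input_resistance", "rm_Mohm"),
            ("threshold", "threshold_mV"),
            ("rheobase", "rheobase_pA"),
            ("mean_spikes", "mean_spikes_per_step"),
        ]:
            add(measure, _paired_contrast(intr, col, "before", "after_stim"))
    return rows


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every analysis stage and write the report bundle to ``out_dir``.

    Identical config + seed produce byte-identical outputs.  Per-pair stage
    failures are logged to ``errors.csv`` and do not abort the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.input_root is not None:
        source: Iterator[CohortPair] = _load_cohort(Path(config.input_root))
    else:
        source = iter_cohort(config.cohort, config.seed)
    tables: dict[str, list] = {
        k: [] for k in ("pairs", "connections", "correlations", "epsp", "intrinsic", "errors")
    }
    n_pairs = 0
    for pair in source:
        _analyze_pair(pair, config, tables)
        n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no input pairs")
    columns = {
        "pairs": ["pair_id", "condition", "mean_epsc1_pA", "mean_epsc2_pA", "ppr",
                  "latency_ms", "failure_rate", "connected", "noise_sd_pA"],
        "connections": ["pair_id", "connected_call", "connected_truth",
                        "mean_epsc1_pA", "threshold_pA", "latency_ms"],
        "correlations": ["pair_id", "condition", "method", "window_s", "coefficient"],
        "epsp": ["cell_id", "pair_id", "condition", "events_per_min", "mean_amp_mV", "n_events"],
        "intrinsic": ["cell_id", "pair_id", "condition", "rm_Mohm", "vrest_mV",
                      "threshold_mV", "rheobase_pA", "mean_spikes_per_step",
                      "mean_if_Hz", "first2_Hz", "qc_pass"],
        "errors": ["pair_id", "stage", "error"],
    }
    for name, rows in tables.items():
        df = pd.DataFrame(rows, columns=columns[name])
        df.to_csv(out / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
    group_df = pd.DataFrame(
        _group_rows(tables),
        columns=["measure", "group_a", "group_b", "median_a", "sem_a", "median_b",
                 "sem_b", "n_a", "n_b", "test", "p_value"],
    )
    group_df.to_csv(out / "group_stats.csv", index=False, float_format=_FLOAT_FMT)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_pairs": n_pairs,
        "config": _config_dict(config),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    return out


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("out_dir", None)  # keep the manifest independent of the location
    return d


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")
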