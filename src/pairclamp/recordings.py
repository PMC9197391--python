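"""Domain types for traces, sweeps, recordings and pairs, plus file I/O and QC.

Units are fixed throughout the package: millivolts (voltage), picoamperes
(current), milliseconds (time), megaohms (resistance), picofarads
(capacitance).  All time windows are half-open ``[start, end)``; sample ``i``
of a trace covers ``[t0 + i*dt, t0 + (i+1)*dt)``.

On-disk format
--------------
A recording is a directory holding one columnar CSV per sweep
(``time_ms,voltage_mV,command_pA`` -- in voltage clamp the measured middle
column is a current in pA; the sidecar's ``clamp_mode`` disambiguates) plus a
JSON sidecar ``sidecar.json`` with keys ``cell_id``, ``clamp_mode``,
``condition``, ``dt_ms``, ``opsin``, ``leak_pA``, ``seal_Gohm`` and
``sweeps`` (ordered list of per-sweep entries).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Trace",
    "Sweep",
    "Recording",
    "PairRecording",
    "QCReport",
    "FormatError",
    "ConsistencyError",
    "DataError",
    "read_recording",
    "write_recording",
    "read_pair",
    "write_pair",
    "qc_recording",
    "extract_window",
]

CLAMP_MODES = ("current_clamp", "voltage_clamp")
CONDITIONS = ("before", "after_stim", "rest_post", "drug", "unstim_control")
PROTOCOL_TAGS = ("iv_step", "presyn_train", "spontaneous", "stim_train")
SIGNAL_KINDS = ("voltage", "current")

SIDECAR_NAME = "sidecar.json"
PAIR_META_NAME = "pair.json"
CSV_HEADER = "time_ms,voltage_mV,command_pA"
_FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """Raised for malformed on-disk layouts (missing sidecar, bad header)."""


class ConsistencyError(ValueError):
    """Raised when metadata and data disagree (e.g. dt mismatch)."""


class DataError(ValueError):
    """Raised for invalid sample values (non-finite entries, bad ranges)."""


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled signal.

    Parameters
    ----------
    samples : ndarray
        Measurements in mV (voltage) or pA (current).
    dt : float
        Sampling interval in ms.
    signal_kind : str
        ``"voltage"`` or ``"current"``.
    t0 : float
        Time of the first sample in ms.
    """

    samples: np.ndarray
    dt: float
    signal_kind: str = "voltage"
    t0: float = 0.0

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise DataError(f"non-finite sample at index {bad}")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"unknown signal_kind {self.signal_kind!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in ms (``len(samples) * dt``)."""
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) * self.dt


@dataclass(frozen=True)
class Sweep:
    """One acquisition sweep: a measured channel plus the command current.

    ``signal`` holds the measured channel -- membrane voltage in current
    clamp, membrane current in voltage clamp.  ``voltage`` is an alias kept
    for the common current-clamp case.
    """

    signal: Trace
    command: Trace
    protocol_tag: str = "spontaneous"
    step_amplitude: Optional[float] = None

    def __post_init__(self):
        if self.protocol_tag not in PROTOCOL_TAGS:
            raise ValueError(f"unknown protocol_tag {self.protocol_tag!r}")
        if self.command.signal_kind != "current":
            raise ValueError("command channel must be a current trace")
        if self.signal.n != self.command.n or not math.isclose(
            self.signal.dt, self.command.dt, rel_tol=1e-12
        ):
            raise ConsistencyError("signal and command must share dt and length")

    @property
    def voltage(self) -> Trace:
        return self.signal

    @property
    def dt(self) -> float:
        return self.signal.dt


@dataclass
class Recording:
    """An ordered collection of sweeps from one cell under one condition."""

    cell_id: str
    clamp_mode: str
    condition: str
    sweeps: list[Sweep]
    opsin_expressing: bool = False
    leak_pA: Optional[float] = None
    seal_Gohm: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.clamp_mode not in CLAMP_MODES:
            raise ValueError(f"unknown clamp_mode {self.clamp_mode!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not self.sweeps:
            raise ValueError("a Recording must contain at least one sweep")
        dts = {round(s.dt, 12) for s in self.sweeps}
        if len(dts) != 1:
            raise ConsistencyError(f"sweeps disagree on dt: {sorted(dts)}")

    @property
    def dt(self) -> float:
        return self.sweeps[0].dt


@dataclass
class PairRecording:
    """Simultaneously recorded pre- and postsynaptic cells."""

    pre: Recording
    post: Recording
    alignment_offset: float = 0.0

    def __post_init__(self):
        if not math.isclose(self.pre.dt, self.post.dt, rel_tol=1e-12):
            raise ConsistencyError("pre and post recordings must share dt")


@dataclass(frozen=True)
class QCReport:
    """Pass/fail verdict on recording quality.

    A recording passes when leak current does not exceed ``leak_max`` and
    seal resistance is not below ``seal_min`` (both boundaries inclusive:
    the exclusion criteria are strict inequalities).
    """

    leak_current: Optional[float]
    seal_resistance: Optional[float]
    passed: bool
    reasons: tuple[str, ...]


def qc_recording(
    rec: Recording, leak_max: float = 25.0, seal_min: float = 1.0
) -> QCReport:
    """Flag a recording whose leak current or seal resistance is out of spec.

    Defaults: recordings are rejected when leak is strictly greater than
    25 pA or seal is strictly below 1 GOhm; boundary values pass.  Missing
    measurements pass with reason ``"not_measured"``.
    """
    reasons: list[str] = []
    leak, seal = rec.leak_pA, rec.seal_Gohm
    if seal is not None and seal < 0:
        raise DataError(f"negative seal resistance: {seal}")
    if leak is None or seal is None:
        reasons.append("not_measured")
    if leak is not None and leak > leak_max:
        reasons.append("leak")
    if seal is not None and seal < seal_min:
        reasons.append("seal")
    passed = "leak" not in reasons and "seal" not in reasons
    return QCReport(leak, seal, passed, tuple(reasons))


def extract_window(trace: Trace, t_start: float, t_end: float) -> Trace:
    """Return the sub-trace covering the half-open interval [t_start, t_end)."""
    if not (trace.t0 <= t_start < t_end <= trace.t0 + trace.duration + 1e-9):
        raise ValueError(
            f"window [{t_start}, {t_end}) outside trace span "
            f"[{trace.t0}, {trace.t0 + trace.duration})"
        )
    i0 = int(math.ceil((t_start - trace.t0) / trace.dt - 1e-9))
    i1 = int(math.ceil((t_end - trace.t0) / trace.dt - 1e-9))
    i1 = min(i1, trace.n)
    return Trace(
        trace.samples[i0:i1],
        trace.dt,
        trace.signal_kind,
        t0=trace.t0 + i0 * trace.dt,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _sweep_filename(i: int) -> str:
    return f"sweep_{i:04d}.csv"


def write_recording(rec: Recording, path) -> Path:
    """Serialize a recording to a sweep directory readable by read_recording.

    Floats are written with enough digits that read-back round-trips within
    1e-9 relative.  Returns the directory path.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sweep_entries = []
    for i, sw in enumerate(rec.sweeps):
        fname = _sweep_filename(i)
        data = np.column_stack(
            [sw.signal.times, sw.signal.samples, sw.command.samples]
        )
        np.savetxt(
            path / fname,
            data,
            fmt=_FLOAT_FMT,
            delimiter=",",
            header=CSV_HEADER,
            comments="",
        )
        sweep_entries.append(
            {
                "file": fname,
                "protocol_tag": sw.protocol_tag,
                "step_amplitude": sw.step_amplitude,
                "t0": sw.signal.t0,
            }
        )
    sidecar = {
        "cell_id": rec.cell_id,
        "clamp_mode": rec.clamp_mode,
        "condition": rec.condition,
        "dt_ms": rec.dt,
        "opsin": rec.opsin_expressing,
        "leak_pA": rec.leak_pA,
        "seal_Gohm": rec.seal_Gohm,
        "meta": rec.meta,
        "sweeps": sweep_entries,
    }
    with open(path / SIDECAR_NAME, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def read_recording(path) -> Recording:
    """Load a recording from a sweep directory written by write_recording."""
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.is_file():
        raise FormatError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    dt = float(sidecar["dt_ms"])
    clamp_mode = sidecar["clamp_mode"]
    measured_kind = "current" if clamp_mode == "voltage_clamp" else "voltage"
    sweeps = []
    for entry in sidecar["sweeps"]:
        fpath = path / entry["file"]
        if not fpath.is_file():
            raise FormatError(f"missing sweep file {fpath}")
        data = np.loadtxt(fpath, delimiter=",", skiprows=1, ndmin=2)
        if data.shape[1] != 3:
            raise FormatError(f"{fpath}: expected 3 columns, got {data.shape[1]}")
        if not np.all(np.isfinite(data)):
            row = int(np.flatnonzero(~np.all(np.isfinite(data), axis=1))[0])
            raise DataError(f"{fpath}: non-finite value at data row {row}")
        t = data[:, 0]
        if t.size > 1:
            file_dt = float(np.median(np.diff(t)))
            if not math.isclose(file_dt, dt, rel_tol=1e-6, abs_tol=1e-9):
                raise ConsistencyError(
                    f"{fpath}: sampled at dt={file_dt} ms but sidecar declares {dt} ms"
                )
        t0 = float(entry.get("t0", t[0]))
        sig = Trace(data[:, 1], dt, measured_kind, t0=t0)
        cmd = Trace(data[:, 2], dt, "current", t0=t0)
        step = entry.get("step_amplitude")
        sweeps.append(
            Sweep(
                sig,
                cmd,
                protocol_tag=entry.get("protocol_tag", "spontaneous"),
                step_amplitude=None if step is None else float(step),
            )
        )
    return Recording(
        cell_id=sidecar["cell_id"],
        clamp_mode=clamp_mode,
        condition=sidecar["condition"],
        sweeps=sweeps,
        opsin_expressing=bool(sidecar.get("opsin", False)),
        leak_pA=sidecar.get("leak_pA"),
        seal_Gohm=sidecar.get("seal_Gohm"),
        meta=sidecar.get("meta", {}),
    )


def write_pair(pair: PairRecording, path) -> Path:
    """Serialize a PairRecording as pre/ and post/ subdirectories."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_recording(pair.pre, path / "pre")
    write_recording(pair.post, path / "post")
    with open(path / PAIR_META_NAME, "w") as fh:
        json.dump({"alignment_offset": pair.alignment_offset}, fh, sort_keys=True)
        fh.write("\n")
    return path


def read_pair(path) -> PairRecording:
    path = Path(path)
    meta_path = path / PAIR_META_NAME
    if not meta_path.is_file():
        raise FormatError(f"missing pair metadata {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    return PairRecording(
        pre=read_recording(path / "pre"),
        post=read_recording(path / "post"),
        alignment_offset=float(meta.get("alignment_offset", 0.0)),
    )
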