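"""Core data containers: raw and cleaned pupil traces and the window scheme.

A raw trace holds both eyes as recorded by the tracker (diameter in mm, one
validity flag per eye per sample); a cleaned trace holds a single normalized
series in [0, 1] with residual missing samples encoded as NaN.  The window
scheme turns a trace into overlapping fixed-length analysis windows, either
over the full series or right-aligned over the last N seconds.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, InvalidSpecError

__all__ = [
    "PupilTraceRaw",
    "PupilTraceClean",
    "WindowScheme",
    "read_trace_tsv",
    "write_trace_tsv",
    "read_clean_tsv",
    "write_clean_tsv",
    "write_table",
    "read_table",
]


@dataclass
class PupilTraceRaw:
    """One subject's binocular pupil record.

    Missing diameters are NaN; a sample contributes to an eye only when its
    validity flag is set and the diameter is finite.
    """

    subject_id: str
    fs: float
    timestamps_ms: np.ndarray
    left_mm: np.ndarray
    right_mm: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray
    group: str | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        self.left_mm = np.asarray(self.left_mm, dtype=float)
        self.right_mm = np.asarray(self.right_mm, dtype=float)
        self.valid_left = np.asarray(self.valid_left, dtype=bool)
        self.valid_right = np.asarray(self.valid_right, dtype=bool)
        n = len(self.timestamps_ms)
        for arr in (self.left_mm, self.right_mm, self.valid_left, self.valid_right):
            if len(arr) != n:
                raise InvalidSpecError("all per-sample columns must share one length")
        if n >= 2:
            dt = np.diff(self.timestamps_ms)
            if np.any(dt <= 0):
                raise InvalidSpecError("timestamps must be strictly increasing")
            med_dt = float(np.median(dt))
            if self.fs <= 0 or abs(med_dt - 1000.0 / self.fs) > 0.1 * (1000.0 / self.fs):
                raise InvalidSpecError(
                    f"fs={self.fs} inconsistent with median sample spacing {med_dt} ms"
                )

    def __len__(self) -> int:
        return len(self.timestamps_ms)


@dataclass
class PupilTraceClean:
    """Filtered, interpolated, min-max normalized single-eye series.

    ``values`` lie in [0, 1] where present and are NaN where the residual
    missing mask is set.  ``provenance`` counts what the preprocessing did:
    outliers removed, samples interpolated, samples left missing ("deleted").
    """

    subject_id: str
    fs: float
    values: np.ndarray
    provenance: dict = field(default_factory=dict)
    group: str | None = None
    age: float | None = None
    eye: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise InvalidSpecError("cleaned values must lie in [0, 1]")

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class WindowScheme:
    """Sliding-window layout: ``window`` samples moved in steps of ``step``.

    With ``span='last_n_seconds'`` the windows cover only the trailing
    ``last_n_seconds`` of the trace and are right-aligned so the final window
    ends exactly at the trace end; at 50 Hz the default (120 s, 500/100)
    yields 56 windows.  Window indices are 1-based with the last window
    carrying the highest index.
    """

    window: int = 500
    step: int = 100
    span: str = "last_n_seconds"
    last_n_seconds: float = 120.0

    def __post_init__(self) -> None:
        if not (self.window > self.step > 0):
            raise InvalidSpecError("require window > step > 0")
        if self.span not in ("last_n_seconds", "full"):
            raise InvalidSpecError(f"unknown span {self.span!r}")

    def starts(self, n_samples: int, fs: float) -> np.ndarray:
        """Start indices of each analysis window for a trace of given length."""
        if self.span == "last_n_seconds":
            seg = min(int(round(self.last_n_seconds * fs)), n_samples)
        else:
            seg = n_samples
        if seg < self.window:
            raise InsufficientDataError(
                f"trace segment of {seg} samples shorter than one window ({self.window})"
            )
        count = (seg - self.window) // self.step + 1
        last_start = n_samples - self.window
        return last_start - self.step * np.arange(count - 1, -1, -1)

    def n_windows(self, n_samples: int, fs: float) -> int:
        return len(self.starts(n_samples, fs))


# ---------------------------------------------------------------------------
# Delimited-text I/O.  All tables are UTF-8 TSV with "NA" for missing and a
# leading block of "# key: value" header lines carrying run metadata.
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    meta: dict = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines(keepends=True)
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition(":")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep="\t", na_values=["NA"])
    return df, meta


_RAW_COLS = ["timestamp_ms", "pupil_left_mm", "pupil_right_mm", "validity_left", "validity_right"]


def write_trace_tsv(trace: PupilTraceRaw, path: str | Path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "timestamp_ms": trace.timestamps_ms,
            "pupil_left_mm": trace.left_mm,
            "pupil_right_mm": trace.right_mm,
            "validity_left": trace.valid_left.astype(int),
            "validity_right": trace.valid_right.astype(int),
        }
    )
    header = {"subject_id": trace.subject_id, "fs": trace.fs}
    if trace.group is not None:
        header["group"] = trace.group
    if trace.age is not None:
        header["age"] = trace.age
    header.update(meta or {})
    write_table(df, path, header)


def read_trace_tsv(path: str | Path) -> PupilTraceRaw:
    df, meta = read_table(path)
    missing = [c for c in _RAW_COLS if c not in df.columns]
    if missing:
        raise InvalidSpecError(f"trace file {path} lacks columns {missing}")
    return PupilTraceRaw(
        subject_id=meta.get("subject_id", Path(path).stem),
        fs=float(meta.get("fs", 50.0)),
        timestamps_ms=df["timestamp_ms"].to_numpy(),
        left_mm=df["pupil_left_mm"].to_numpy(),
        right_mm=df["pupil_right_mm"].to_numpy(),
        valid_left=df["validity_left"].to_numpy().astype(bool),
        valid_right=df["validity_right"].to_numpy().astype(bool),
        group=meta.get("group"),
        age=float(meta["age"]) if "age" in meta else None,
    )


def write_clean_tsv(clean: PupilTraceClean, path: str | Path, meta: dict | None = None) -> None:
    n = len(clean)
    df = pd.DataFrame(
        {
            "timestamp_ms": np.arange(n) * 1000.0 / clean.fs,
            "value": clean.values,
            "missing": clean.missing_mask.astype(int),
        }
    )
    header = {"subject_id": clean.subject_id, "fs": clean.fs}
    if clean.group is not None:
        header["group"] = clean.group
    if clean.age is not None:
        header["age"] = clean.age
    for key, val in clean.provenance.items():
        header[f"provenance_{key}"] = val
    header.update(meta or {})
    write_table(df, path, header)


def read_clean_tsv(path: str | Path) -> PupilTraceClean:
    df, meta = read_table(path)
    provenance = {
        k[len("provenance_"):]: int(v) for k, v in meta.items() if k.startswith("provenance_")
    }
    return PupilTraceClean(
        subject_id=meta.get("subject_id", Path(path).stem),
        fs=float(meta.get("fs", 50.0)),
        values=df["value"].to_numpy(),
        provenance=provenance,
        group=meta.get("group"),
        age=float(meta["age"]) if "age" in meta else None,
    )
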