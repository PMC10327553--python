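"""Recurrence quantification: embedding, recurrence matrix, diagonal-line
measures (RR, DET, ENT), windowed application and radius calibration.

Conventions
-----------
* The Theiler parameter is the half-width of the band excluded around the
  line of identity (LOI): pairs with |i - j| < theiler are ineligible.  The
  default ``theiler=1`` excludes exactly the LOI — with a 25-sample minimum
  diagonal length the LOI would otherwise dominate DET in every window —
  while ``theiler=0`` keeps it for strict replication attempts.
* Diagonal lines are counted on the upper triangle only (the matrix is
  symmetric, so each line appears mirrored below the LOI; using one triangle
  keeps every recurrent point in exactly one maximal line).  DET and ENT
  depend only on the line-length histogram, so the choice of triangle is
  immaterial.
* ENT is the Shannon entropy, in nats, of the length distribution of
  diagonal lines of at least ``min_diag`` points.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .exceptions import (
    CalibrationError,
    InsufficientDataError,
    InvalidSpecError,
    MissingDataError,
)
from .traces import PupilTraceClean, WindowScheme

__all__ = [
    "RQAParams",
    "RQAMeasures",
    "embed",
    "recurrence_matrix",
    "rr",
    "diagonal_lines",
    "det",
    "ent",
    "rqa_measures",
    "windowed_rqa",
    "calibrate_radius",
]


@dataclass(frozen=True)
class RQAParams:
    """Recurrence analysis parameters.

    ``radius`` is in units of the (normalized) signal; ``min_vert`` is stored
    for completeness but no vertical-line measure is reported.
    """

    delay: int = 6
    dimension: int = 6
    radius: float = 0.02
    min_diag: int = 25
    min_vert: int = 25
    norm: str = "euclidean"
    theiler: int = 1

    def __post_init__(self) -> None:
        if self.delay < 1 or self.dimension < 1:
            raise InvalidSpecError("delay and dimension must be >= 1")
        if self.radius <= 0:
            raise InvalidSpecError("radius must be positive")
        if self.min_diag < 2:
            raise InvalidSpecError("min_diag must be >= 2")
        if self.theiler < 0:
            raise InvalidSpecError("theiler must be >= 0")
        if self.norm not in ("euclidean", "maximum"):
            raise InvalidSpecError(f"norm must be 'euclidean' or 'maximum', got {self.norm!r}")


@dataclass
class RQAMeasures:
    rr: float
    det: float
    ent: float
    n_recurrent_points: int
    diag_histogram: dict[int, int] = field(default_factory=dict)


def embed(series: np.ndarray, delay: int, dimension: int) -> np.ndarray:
    """Time-delay embedding: rows v_i = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})."""
    x = np.asarray(series, dtype=float)
    if np.any(~np.isfinite(x)):
        raise MissingDataError("embedding requires a gap-free series")
    n_vec = len(x) - (dimension - 1) * delay
    if n_vec < 1:
        raise InsufficientDataError(
            f"series of {len(x)} samples too short for dimension={dimension}, delay={delay}"
        )
    return np.column_stack([x[i * delay : i * delay + n_vec] for i in range(dimension)])


def _distance_matrix(states: np.ndarray, norm: str) -> np.ndarray:
    metric = "euclidean" if norm == "euclidean" else "chebyshev"
    return cdist(states, states, metric=metric)


def recurrence_matrix(
    states: np.ndarray, radius: float, norm: str = "euclidean", theiler: int = 1
) -> np.ndarray:
    """Symmetric boolean recurrence matrix with the Theiler band zeroed.

    R[i, j] is True iff the state distance is <= radius and |i - j| >= theiler
    (theiler=0 keeps the LOI; theiler=1 removes exactly the LOI).
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if states.shape[0] < 2:
        raise InsufficientDataError("need at least 2 states")
    dist = _distance_matrix(states, norm)
    rec = dist <= radius
    if theiler > 0:
        n = len(states)
        i, j = np.indices((n, n), sparse=True)
        rec &= np.abs(i - j) >= theiler
    return rec


def _n_eligible(n: int, theiler: int) -> int:
    """Cells outside the excluded Theiler band, counting both triangles."""
    if theiler <= 0:
        return n * n
    band = sum(n - k for k in range(min(theiler, n)))  # upper-triangle cells with j-i < theiler
    return n * n - (2 * band - n)


def rr(matrix: np.ndarray, theiler: int = 1) -> float:
    """Recurrence rate in percent of eligible (non-Theiler-band) cells."""
    n = matrix.shape[0]
    eligible = _n_eligible(n, theiler)
    if eligible == 0:
        return 0.0
    return 100.0 * float(np.count_nonzero(matrix)) / eligible


def diagonal_lines(matrix: np.ndarray, theiler: int = 1) -> dict[int, int]:
    """Histogram {length: count} of maximal diagonal runs (upper triangle).

    Off-diagonals at offset k >= max(theiler, 0) are scanned; with theiler=0
    the LOI itself contributes one line of length n.
    """
    n = matrix.shape[0]
    k0 = max(theiler, 0)
    chunks = []
    for k in range(k0, n):
        chunks.append(np.diagonal(matrix, offset=k).astype(np.int8))
        chunks.append(np.zeros(1, dtype=np.int8))
    if not chunks:
        return {}
    flat = np.concatenate(chunks)
    # run-length encode the concatenated diagonals (separated by zeros)
    padded = np.concatenate([[0], flat, [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    lengths = ends - starts
    hist = Counter(lengths.tolist())
    return dict(hist)


def det(histogram: dict[int, int], min_diag: int = 25) -> float:
    """Percent of recurrent points on diagonal lines of length >= min_diag."""
    total = sum(length * count for length, count in histogram.items())
    if total == 0:
        return 0.0
    on_lines = sum(length * count for length, count in histogram.items() if length >= min_diag)
    return 100.0 * on_lines / total


def ent(histogram: dict[int, int], min_diag: int = 25) -> float:
    """Shannon entropy (nats) of the length distribution of qualifying lines."""
    counts = np.array([c for length, c in histogram.items() if length >= min_diag], dtype=float)
    if counts.size <= 1:
        return 0.0
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def rqa_measures(series: np.ndarray, params: RQAParams) -> RQAMeasures:
    """All reported measures for one gap-free series."""
    states = embed(series, params.delay, params.dimension)
    matrix = recurrence_matrix(states, params.radius, params.norm, params.theiler)
    hist = diagonal_lines(matrix, params.theiler)
    return RQAMeasures(
        rr=rr(matrix, params.theiler),
        det=det(hist, params.min_diag),
        ent=ent(hist, params.min_diag),
        n_recurrent_points=int(np.count_nonzero(matrix)),
        diag_histogram=hist,
    )


def windowed_rqa(
    trace: PupilTraceClean, scheme: WindowScheme, params: RQAParams
) -> pd.DataFrame:
    """Per-window RR/DET/ENT for one cleaned trace.

    Windows containing any residual missing sample are flagged and their
    measures set to NaN rather than dropped, so the window grid stays
    aligned across subjects.  Window indices run 1..W with W the final
    (trace-end) window.
    """
    starts = scheme.starts(len(trace), trace.fs)
    rows = []
    for w_idx, start in enumerate(starts, start=1):
        chunk = trace.values[start : start + scheme.window]
        if np.any(~np.isfinite(chunk)):
            rows.append({"window_index": w_idx, "start": int(start),
                         "rr": np.nan, "det": np.nan, "ent": np.nan, "missing": True})
            continue
        m = rqa_measures(chunk, params)
        rows.append({"window_index": w_idx, "start": int(start),
                     "rr": m.rr, "det": m.det, "ent": m.ent, "missing": False})
    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", trace.subject_id)
    df.insert(1, "group", trace.group)
    df.insert(2, "age", trace.age)
    return df


def _window_embeddings(
    traces: list[PupilTraceClean], scheme: WindowScheme, params: RQAParams
) -> list[np.ndarray]:
    """Embedded state arrays for every complete window of every trace."""
    embs = []
    for trace in traces:
        for start in scheme.starts(len(trace), trace.fs):
            chunk = trace.values[start : start + scheme.window]
            if np.all(np.isfinite(chunk)):
                embs.append(embed(chunk, params.delay, params.dimension))
    return embs


def _mean_rr_exact(embs: list[np.ndarray], radius: float, norm: str, theiler: int) -> float:
    vals = []
    for states in embs:
        matrix = recurrence_matrix(states, radius, norm, theiler)
        vals.append(rr(matrix, theiler))
    return float(np.mean(vals))


def calibrate_radius(
    traces: list[PupilTraceClean],
    scheme: WindowScheme,
    params: RQAParams,
    target_rr_percent: float = 10.0,
    tolerance: float = 0.5,
    max_iter: int = 60,
    subsample_pairs: int | None = 5000,
    seed: int = 0,
) -> tuple[float, float]:
    """Bisect the radius until the grand-mean windowed RR hits the target.

    Returns (radius, achieved_mean_rr).  The bisection evaluates the mean RR
    on per-window subsamples of eligible pairwise distances (``subsample_pairs``
    per window; None = all pairs) for speed; the achieved value reported is
    recomputed exactly at the returned radius.
    """
    if not (0 < target_rr_percent < 100) and target_rr_percent != 100:
        raise InvalidSpecError("target recurrence percent must be in (0, 100]")
    embs = _window_embeddings(traces, scheme, params)
    if not embs:
        raise CalibrationError("no complete windows available for calibration")

    rng = np.random.default_rng(seed)
    sorted_dists = []
    for states in embs:
        n = len(states)
        iu, ju = np.triu_indices(n, k=max(params.theiler, 1))
        if params.theiler == 0:
            # LOI pairs all have distance 0; include them in the pool
            iu = np.concatenate([iu, np.arange(n)])
            ju = np.concatenate([ju, np.arange(n)])
        if subsample_pairs is not None and iu.size > subsample_pairs:
            pick = rng.choice(iu.size, size=subsample_pairs, replace=False)
            iu, ju = iu[pick], ju[pick]
        diff = states[iu] - states[ju]
        if params.norm == "euclidean":
            dvals = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        else:
            dvals = np.abs(diff).max(axis=1)
        sorted_dists.append(np.sort(dvals))

    def mean_rr(radius: float) -> float:
        fracs = [100.0 * np.searchsorted(d, radius, side="right") / d.size for d in sorted_dists]
        return float(np.mean(fracs))

    if target_rr_percent >= 100.0:
        hi = max(float(_distance_matrix(states, params.norm).max()) for states in embs)
        return hi, _mean_rr_exact(embs, hi, params.norm, params.theiler)
    lo = 0.0
    hi = max(d[-1] for d in sorted_dists)
    if mean_rr(hi) < target_rr_percent - tolerance:
        raise CalibrationError("search range does not bracket the target recurrence rate")
    radius = hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        achieved = mean_rr(mid)
        if abs(achieved - target_rr_percent) <= 0.25 * tolerance:
            radius = mid
            break
        if achieved < target_rr_percent:
            lo = mid
        else:
            hi = mid
        radius = mid
    exact = _mean_rr_exact(embs, radius, params.norm, params.theiler)
    return radius, exact


def with_radius(params: RQAParams, radius: float) -> RQAParams:
    """Copy of ``params`` with a new radius."""
    return replace(params, radius=radius)
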