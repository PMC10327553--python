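"""Time-delay embedding parameter estimation.

The delay is chosen from the average mutual information (AMI) curve at the
first lag where AMI drops to 1/e of its lag-zero value; the embedding
dimension from the false-nearest-neighbor (FNN) fraction curve (Kennel
criterion).  Per-window estimates across a cohort are aggregated by mode,
mirroring a single cohort-wide parameter choice.

The MI estimator is a plain equal-width 2-D histogram in nats with
n_bins = ceil(sqrt(n/5)) capped at 16 by default — robust at the 500-sample
windows this package analyses.  No kernel or k-NN MI estimators and no Cao's
method are provided.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import InsufficientDataError, InvalidSpecError

__all__ = [
    "EmbeddingParams",
    "AMICurve",
    "ami_curve",
    "select_delay",
    "fnn_fractions",
    "select_dimension",
    "aggregate_mode",
    "estimate_window_params",
]


@dataclass(frozen=True)
class EmbeddingParams:
    delay: int
    dimension: int
    source: str = "estimated"

    def __post_init__(self) -> None:
        if self.delay < 1 or self.dimension < 1:
            raise InvalidSpecError("delay and dimension must be >= 1")


@dataclass(frozen=True)
class AMICurve:
    lags: np.ndarray
    ami: np.ndarray


def default_n_bins(n: int) -> int:
    return min(16, max(2, int(np.ceil(np.sqrt(n / 5)))))


def ami_curve(series: np.ndarray, max_lag: int, n_bins: int | None = None) -> AMICurve:
    """Average mutual information (nats) between x(t) and x(t+tau), tau = 0..max_lag.

    Uses an equal-width 2-D histogram over the overlapping pairs; the bin
    grid spans the full series range at every lag so curves are comparable
    across lags.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n <= max_lag + 10:
        raise InsufficientDataError(f"series of {n} samples too short for max_lag={max_lag}")
    if not np.all(np.isfinite(x)):
        raise InsufficientDataError("ami_curve requires a gap-free series")
    if n_bins is None:
        n_bins = default_n_bins(n)
    if n_bins < 2:
        raise InvalidSpecError("n_bins must be >= 2")
    lo, hi = x.min(), x.max()
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    amis = np.empty(max_lag + 1)
    for tau in range(max_lag + 1):
        a = x[: n - tau] if tau else x
        b = x[tau:] if tau else x
        joint, _, _ = np.histogram2d(a, b, bins=[edges, edges])
        p = joint / joint.sum()
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        nz = p > 0
        amis[tau] = float(np.sum(p[nz] * (np.log(p[nz]) - np.log(np.outer(px, py)[nz]))))
    return AMICurve(lags=np.arange(max_lag + 1), ami=amis)


def select_delay(curve: AMICurve) -> tuple[int, bool]:
    """First lag where AMI <= AMI(0)/e; returns (delay, crossed).

    If the curve never crosses the 1/e level within its range the maximum
    lag is returned with ``crossed=False`` as a warning flag.
    """
    if len(curve.lags) < 2:
        raise InvalidSpecError("AMI curve needs at least 2 lags")
    threshold = curve.ami[0] / np.e
    for tau in range(1, len(curve.lags)):
        if curve.ami[tau] <= threshold:
            return int(curve.lags[tau]), True
    return int(curve.lags[-1]), False


def _delay_embed(x: np.ndarray, delay: int, dim: int) -> np.ndarray:
    n_vec = len(x) - (dim - 1) * delay
    return np.column_stack([x[i * delay : i * delay + n_vec] for i in range(dim)])


def fnn_fractions(
    series: np.ndarray,
    delay: int,
    max_dim: int,
    rtol: float = 10.0,
    atol: float = 2.0,
) -> np.ndarray:
    """Fraction of false nearest neighbors for dimensions 1..max_dim.

    Kennel criterion: the nearest neighbor of point i in dimension m is false
    when the extra-coordinate separation grows by more than ``rtol`` relative
    to the m-dimensional distance, or when the (m+1)-dimensional distance
    exceeds ``atol`` times the series SD.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n <= (max_dim) * delay + 2:
        raise InsufficientDataError(
            f"series of {n} samples too short for max_dim={max_dim}, delay={delay}"
        )
    sd = float(np.std(x)) or 1e-12
    fractions = np.empty(max_dim)
    for m in range(1, max_dim + 1):
        n_vec = n - m * delay  # vectors that also exist in dimension m+1
        emb = _delay_embed(x, delay, m)[:n_vec]
        tree = cKDTree(emb)
        dist, nbr = tree.query(emb, k=2)
        d_m = dist[:, 1]
        j = nbr[:, 1]
        extra = np.abs(x[np.arange(n_vec) + m * delay] - x[j + m * delay])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d_m > 0, extra / d_m, np.inf)
        d_m1 = np.sqrt(d_m**2 + extra**2)
        false = (ratio > rtol) | (d_m1 > atol * sd)
        # numerically identical states (periodic data) are true neighbors;
        # without the floor, rounding-error ratios blow past rtol
        false &= d_m1 > 1e-8 * sd
        fractions[m - 1] = false.mean()
    return fractions


def select_dimension(fractions: np.ndarray, drop_threshold: float | None = None) -> int:
    """Smallest dimension attaining the minimum FNN fraction.

    With ``drop_threshold`` given, the smallest dimension whose fraction is
    at or below the threshold is used instead (falling back to the argmin
    rule if none qualifies).
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size == 0:
        raise InvalidSpecError("fractions must be non-empty")
    if drop_threshold is not None:
        below = np.flatnonzero(fractions <= drop_threshold)
        if below.size:
            return int(below[0]) + 1
    return int(np.argmin(fractions)) + 1


def aggregate_mode(values: list[int]) -> int:
    """Most frequent value; ties break toward the smaller value."""
    if not values:
        raise InvalidSpecError("cannot take the mode of an empty list")
    counts = Counter(int(v) for v in values)
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def estimate_window_params(
    window_values: np.ndarray,
    max_lag: int = 25,
    max_dim: int = 10,
    rtol: float = 10.0,
    atol: float = 2.0,
) -> tuple[int, int, bool]:
    """Delay and dimension estimate for one analysis window.

    Returns (delay, dimension, delay_crossed).
    """
    curve = ami_curve(window_values, max_lag=max_lag)
    delay, crossed = select_delay(curve)
    fractions = fnn_fractions(window_values, delay=delay, max_dim=max_dim, rtol=rtol, atol=atol)
    dim = select_dimension(fractions)
    return delay, dim, crossed
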