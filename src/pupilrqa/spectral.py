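"""Windowed Welch PSD estimation and log-log spectral slope (beta) fitting.

The scaling exponent beta is the OLS slope of log10(power) on log10(freq).
By default the fit uses the Welch grid from the first non-DC bin up to half
the Nyquist frequency: the discrete integrator underlying Brownian-like
signals has spectrum 1/(2 sin(omega/2))^2, which flattens relative to the
f^-2 law toward Nyquist, and including that upper octave biases the fitted
exponent shallow by ~0.2.  Capping the band at fs/4 recovers 0 / -1 / -2
for white / pink / Brownian noise within sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch
from scipy.stats import linregress

from .exceptions import InsufficientDataError, InvalidSpecError, MissingDataError
from .traces import PupilTraceClean, WindowScheme

__all__ = [
    "PSDConfig",
    "SpectralEstimate",
    "welch_psd",
    "loglog_slope",
    "beta_for_series",
    "windowed_beta",
]


@dataclass(frozen=True)
class PSDConfig:
    """Welch estimation and slope-fit settings.

    ``nperseg`` defaults to 256 for the 500-sample analysis windows; use 512
    for 2048-sample reference-noise series.  ``fit_fmax_frac`` is the upper
    fit limit as a fraction of fs (0.25 = half the Nyquist frequency); the
    DC bin is always excluded.
    """

    nperseg: int = 256
    overlap_frac: float = 0.5
    taper: str = "hann"
    detrend: str = "linear"
    fit_fmax_frac: float = 0.25

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_frac < 1):
            raise InvalidSpecError("overlap_frac must be in [0, 1)")
        if not (0 < self.fit_fmax_frac <= 0.5):
            raise InvalidSpecError("fit_fmax_frac must be in (0, 0.5]")


@dataclass(frozen=True)
class SpectralEstimate:
    freqs: np.ndarray
    power: np.ndarray
    beta: float
    fit_range: tuple[float, float]
    r_squared: float


def welch_psd(
    series: np.ndarray,
    fs: float,
    seg_len: int = 256,
    overlap_frac: float = 0.5,
    taper: str = "hann",
    detrend: str = "linear",
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density."""
    x = np.asarray(series, dtype=float)
    if np.any(~np.isfinite(x)):
        raise MissingDataError("welch_psd requires a gap-free series")
    if len(x) < seg_len:
        raise InsufficientDataError(f"series of {len(x)} samples shorter than seg_len={seg_len}")
    noverlap = int(round(seg_len * overlap_frac))
    freqs, power = welch(
        x, fs=fs, window=taper, nperseg=seg_len, noverlap=noverlap, detrend=detrend
    )
    return freqs, power


def loglog_slope(
    freqs: np.ndarray,
    power: np.ndarray,
    fit_range: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """OLS slope of log10(power) vs log10(freq); returns (beta, r_squared).

    Bins with nonpositive frequency or power are excluded; at least 3 usable
    bins are required.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    mask = (freqs > 0) & (power > 0)
    if fit_range is not None:
        f_lo, f_hi = fit_range
        mask &= (freqs >= f_lo) & (freqs <= f_hi)
    if mask.sum() < 3:
        raise InsufficientDataError("fewer than 3 usable frequency bins in the fit range")
    fit = linregress(np.log10(freqs[mask]), np.log10(power[mask]))
    return float(fit.slope), float(fit.rvalue**2)


def beta_for_series(series: np.ndarray, fs: float, config: PSDConfig | None = None) -> SpectralEstimate:
    """Welch PSD plus slope fit over the configured band for one series."""
    config = config or PSDConfig()
    freqs, power = welch_psd(
        series, fs, config.nperseg, config.overlap_frac, config.taper, config.detrend
    )
    f_hi = config.fit_fmax_frac * fs
    f_lo = freqs[freqs > 0].min()
    beta, r2 = loglog_slope(freqs, power, fit_range=(f_lo, f_hi))
    return SpectralEstimate(freqs=freqs, power=power, beta=beta, fit_range=(f_lo, f_hi), r_squared=r2)


def windowed_beta(
    trace: PupilTraceClean, scheme: WindowScheme, config: PSDConfig | None = None
) -> pd.DataFrame:
    """Per-window beta for one cleaned trace (NaN for windows with gaps)."""
    config = config or PSDConfig()
    starts = scheme.starts(len(trace), trace.fs)
    rows = []
    for w_idx, start in enumerate(starts, start=1):
        chunk = trace.values[start : start + scheme.window]
        if np.any(~np.isfinite(chunk)):
            rows.append({"window_index": w_idx, "start": int(start),
                         "beta": np.nan, "r_squared": np.nan, "missing": True})
            continue
        est = beta_for_series(chunk, trace.fs, config)
        rows.append({"window_index": w_idx, "start": int(start),
                     "beta": est.beta, "r_squared": est.r_squared, "missing": False})
    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", trace.subject_id)
    df.insert(1, "group", trace.group)
    df.insert(2, "age", trace.age)
    return df
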