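"""Seeded generators for reference noises and a synthetic pupil cohort.

Two families of signals are produced:

* the three canonical noise colors — white (flat spectrum, beta 0), pink
  (1/f, beta -1) and Brownian (random walk, beta -2) — used to validate the
  spectral-slope and recurrence estimators against known scaling exponents;

* a two-group cohort of eye-tracker-like pupil recordings (50 Hz, mm units,
  blink gaps, outlier spikes) in which the "solver" group carries an epoch of
  injected white noise near the end of the trace.  The injection is zero-mean,
  so it erodes the deterministic (diagonal-line) structure of the local
  dynamics and inflates the within-window SD without shifting the windowed
  mean — the contrast the group analysis is designed to detect.

Every generator is a pure function of its spec: identical specs give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidSpecError
from .traces import PupilTraceRaw, read_trace_tsv, write_table, write_trace_tsv

__all__ = [
    "NoiseSpec",
    "CohortSpec",
    "gen_white",
    "gen_pink",
    "gen_brownian",
    "gen_noise",
    "gen_pupil_trace",
    "gen_cohort",
    "write_cohort",
    "read_cohort",
]

_KINDS = ("white", "pink", "brownian")


@dataclass(frozen=True)
class NoiseSpec:
    """Specification of one reference-noise realization."""

    kind: str
    n_samples: int = 2048
    seed: int = 0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidSpecError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.n_samples < 16:
            raise InvalidSpecError("n_samples must be >= 16")
        if self.amplitude <= 0:
            raise InvalidSpecError("amplitude must be positive")


def gen_white(spec: NoiseSpec) -> np.ndarray:
    """Zero-mean Gaussian i.i.d. samples scaled by ``amplitude``."""
    if spec.kind != "white":
        raise InvalidSpecError(f"gen_white requires kind='white', got {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    return spec.amplitude * rng.standard_normal(spec.n_samples)


def gen_pink(spec: NoiseSpec) -> np.ndarray:
    """1/f noise by spectral synthesis.

    Fourier coefficients of seeded white noise are rescaled by f^(-1/2) so the
    power spectrum follows f^(-1) exactly in expectation; the DC component is
    zeroed and the mean removed.
    """
    if spec.kind != "pink":
        raise InvalidSpecError(f"gen_pink requires kind='pink', got {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(spec.n_samples)
    coeffs = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(spec.n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** -0.5
    series = np.fft.irfft(coeffs * scale, spec.n_samples)
    series -= series.mean()
    return spec.amplitude * series


def gen_brownian(spec: NoiseSpec) -> np.ndarray:
    """Random walk: cumulative sum of seeded Gaussian white increments."""
    if spec.kind != "brownian":
        raise InvalidSpecError(f"gen_brownian requires kind='brownian', got {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    return np.cumsum(spec.amplitude * rng.standard_normal(spec.n_samples))


def gen_noise(spec: NoiseSpec) -> np.ndarray:
    """Dispatch on ``spec.kind``."""
    return {"white": gen_white, "pink": gen_pink, "brownian": gen_brownian}[spec.kind](spec)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for the synthetic two-group pupil cohort.

    ``solver_epoch`` is (start, end) in seconds counted back from the trace
    end; the default (92, 20) places the injected epoch 92 s to 20 s before
    the end of the recording.  ``solver_noise_gain`` scales the injected white
    noise relative to the SD of the Brownian base increments; 0 makes the two
    groups exchangeable.  Rates are expected events per minute.  Two gap
    components are superimposed: blink gaps (``gap_rate``, short lengths
    from ``gap_len_range``) that the 2-s rule interpolates, and rare long
    tracking dropouts (``dropout_rate``, ``dropout_len_range``) that remain
    masked.
    """

    n_solvers: int = 24
    n_nonsolvers: int = 43
    duration_s: float = 180.0
    fs: float = 50.0
    gap_rate: float = 6.0
    gap_len_range: tuple[int, int] = (5, 80)
    dropout_rate: float = 0.1
    dropout_len_range: tuple[int, int] = (110, 250)
    outlier_rate: float = 4.0
    solver_epoch: tuple[float, float] = (92.0, 20.0)
    solver_noise_gain: float = 1.0
    seed: int = 0
    age_range: tuple[float, float] = (6.0, 12.0)
    diameter_range: tuple[float, float] = (2.0, 8.0)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise InvalidSpecError("fs must be positive")
        if self.duration_s <= 0:
            raise InvalidSpecError("duration_s must be positive")
        start, end = self.solver_epoch
        if not (0 <= end < start <= self.duration_s):
            raise InvalidSpecError(
                "solver_epoch must satisfy 0 <= end < start <= duration_s "
                "(seconds before trace end)"
            )
        if self.gap_rate < 0 or self.outlier_rate < 0 or self.dropout_rate < 0:
            raise InvalidSpecError("rates must be >= 0")
        if self.solver_noise_gain < 0:
            raise InvalidSpecError("solver_noise_gain must be >= 0")
        lo, hi = self.gap_len_range
        if not (1 <= lo <= hi):
            raise InvalidSpecError("gap_len_range must be 1 <= min <= max")


def _epoch_slice(spec: CohortSpec, n: int) -> slice:
    start_s, end_s = spec.solver_epoch
    i0 = n - int(round(start_s * spec.fs))
    i1 = n - int(round(end_s * spec.fs))
    return slice(max(i0, 0), min(i1, n))


def gen_pupil_trace(subject_id: str, group: str, spec: CohortSpec, seed: int | None = None) -> PupilTraceRaw:
    """Simulate one subject's binocular 50 Hz pupil recording.

    The base dynamic is a Brownian walk mapped affinely into the plausible
    diameter range; for solvers, zero-mean white noise (``solver_noise_gain``
    times the increment SD) is added inside the solver epoch before the
    mapping.  Blink gaps (binocular, invalid samples) and outlier spikes are
    superimposed afterwards.
    """
    if group not in ("solver", "nonsolver"):
        raise InvalidSpecError(f"group must be 'solver' or 'nonsolver', got {group!r}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = int(round(spec.duration_s * spec.fs))

    base = np.cumsum(rng.standard_normal(n))
    if group == "solver" and spec.solver_noise_gain > 0:
        sl = _epoch_slice(spec, n)
        base[sl] = base[sl] + spec.solver_noise_gain * rng.standard_normal(sl.stop - sl.start)

    # affine map into the physiological diameter band (margin keeps spikes visible)
    lo_mm, hi_mm = spec.diameter_range
    margin = 0.1 * (hi_mm - lo_mm)
    rng_base = base.max() - base.min()
    if rng_base == 0:
        rng_base = 1.0
    mapped = lo_mm + margin + (base - base.min()) * (hi_mm - lo_mm - 2 * margin) / rng_base
    incr_sd = float(np.std(np.diff(mapped))) or 1e-6

    # per-eye measurement jitter, small relative to the dynamics' increments
    jitter = 0.3 * incr_sd
    left = mapped + jitter * rng.standard_normal(n)
    right = mapped + jitter * rng.standard_normal(n)
    valid_left = np.ones(n, dtype=bool)
    valid_right = np.ones(n, dtype=bool)

    minutes = spec.duration_s / 60.0

    # outlier spikes (tracking glitches), applied to both eyes
    n_spikes = rng.poisson(spec.outlier_rate * minutes)
    if n_spikes:
        idx = rng.integers(0, n, size=n_spikes)
        mag = rng.uniform(0.3, 1.0, size=n_spikes) * rng.choice([-1.0, 1.0], size=n_spikes)
        left[idx] += mag
        right[idx] += mag

    # binocular blink gaps (short, typically interpolatable) plus rare long
    # tracking dropouts (left as residual missing by the 2-s gap rule)
    for rate, (lo, hi) in (
        (spec.gap_rate, spec.gap_len_range),
        (spec.dropout_rate, spec.dropout_len_range),
    ):
        n_gaps = rng.poisson(rate * minutes)
        for _ in range(n_gaps):
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, max(n - length, 1)))
            valid_left[start:start + length] = False
            valid_right[start:start + length] = False
    lo, hi = spec.gap_len_range

    # occasional monocular dropout on the right eye, so eye selection matters
    n_mono = rng.poisson(0.2 * spec.gap_rate * minutes)
    for _ in range(n_mono):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, max(n - length, 1)))
        valid_right[start:start + length] = False

    left = np.where(valid_left, left, np.nan)
    right = np.where(valid_right, right, np.nan)
    return PupilTraceRaw(
        subject_id=subject_id,
        fs=spec.fs,
        timestamps_ms=np.arange(n) * 1000.0 / spec.fs,
        left_mm=left,
        right_mm=right,
        valid_left=valid_left,
        valid_right=valid_right,
        group=group,
    )


def gen_cohort(spec: CohortSpec) -> list[PupilTraceRaw]:
    """Generate the full labeled cohort with per-subject seeds and ages."""
    if spec.n_solvers < 1 or spec.n_nonsolvers < 1:
        raise InvalidSpecError("both groups need at least one subject")
    n_total = spec.n_solvers + spec.n_nonsolvers
    ss = np.random.SeedSequence(spec.seed)
    subject_seeds = ss.generate_state(n_total, dtype=np.uint32)
    age_rng = np.random.default_rng(ss.spawn(1)[0])
    ages = np.round(age_rng.uniform(*spec.age_range, size=n_total), 1)

    traces = []
    for i in range(n_total):
        group = "solver" if i < spec.n_solvers else "nonsolver"
        sid = f"{'S' if group == 'solver' else 'N'}{i + 1:03d}"
        trace = gen_pupil_trace(sid, group, spec, seed=int(subject_seeds[i]))
        trace.age = float(ages[i])
        traces.append(trace)
    return traces


def write_cohort(traces: list[PupilTraceRaw], out_dir: str | Path, spec: CohortSpec | None = None) -> Path:
    """Write one TSV per subject plus a cohort manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trace in traces:
        write_trace_tsv(trace, out_dir / f"{trace.subject_id}.tsv")
        rows.append(
            {"subject_id": trace.subject_id, "group": trace.group, "age": trace.age,
             "n_samples": len(trace), "fs": trace.fs}
        )
    meta = {"master_seed": spec.seed} if spec is not None else {}
    write_table(pd.DataFrame(rows), out_dir / "manifest.tsv", meta)
    return out_dir


def read_cohort(cohort_dir: str | Path) -> list[PupilTraceRaw]:
    """Read a cohort written by :func:`write_cohort`."""
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "manifest.tsv"
    if not manifest_path.exists():
        raise InvalidSpecError(f"no manifest.tsv in {cohort_dir}")
    from .traces import read_table

    manifest, _ = read_table(manifest_path)
    traces = []
    for row in manifest.itertuples():
        trace = read_trace_tsv(cohort_dir / f"{row.subject_id}.tsv")
        trace.group = row.group
        trace.age = float(row.age)
        traces.append(trace)
    return traces
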