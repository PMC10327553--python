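# Methods

This note records the models, numerical choices and limitations behind
`pupilrqa`. Everything stated here is computed by the package's tests or
examples; nothing is quoted from external data.

## Signal model and synthetic cohort

Pupil diameter at rest drifts slowly; its windowed spectral slope sits in
the Brownian band (β near −2). The generator therefore models the base
dynamic of each subject as a Gaussian random walk, mapped affinely into a
physiological diameter band (default 2–8 mm, with a 10% margin so spikes
remain visible). Physiological realism of the absolute level is cosmetic:
the pipeline min-max normalizes per subject, so only the *relative*
structure matters.

Two-group structure: "solver" subjects receive zero-mean white noise inside
a late-trace epoch (default 92 s to 20 s before the end, the span where the
group analysis expects differences). The injection erodes diagonal-line
structure in the recurrence plot — lowering ENT and DET — and inflates
within-window SD, while leaving the windowed mean unchanged in expectation.
`solver_noise_gain` scales the injected SD relative to the SD of the base
increments. The default of 1.0 was fixed once during generator design: a
pilot run showed it yields an epoch-localized ENT deficit with a clearly
significant group × window interaction and a null windowed-mean effect at
moderate cohort sizes, i.e. exactly the qualitative contrast the cohort is
meant to embody; a gain of 2 produced implausibly large effects (η_p² ≈ 0.9).

Artifacts:

* **Blink gaps** — Poisson events (default 6/min) with uniform lengths of
  5–80 samples (0.1–1.6 s), marked invalid in both eyes. These fall under
  the 2-s interpolation rule.
* **Tracking dropouts** — a second, rare Poisson component (default
  0.1/min, 110–250 samples) that exceeds the 2-s rule and therefore remains
  masked. Splitting gaps into these two components keeps both interpolation
  branches exercised while matching the empirical fact that blinks are
  frequent-but-short and long losses rare; a single uniform length
  distribution wide enough to cover both would make >2-s gaps ~35% of all
  gaps and decimate the complete-case ANOVA.
* **Outlier spikes** — Poisson events (default 4/min), ±0.3–1.0 mm in both
  eyes, targets for the Hampel filter.
* **Monocular dropouts** — occasional right-eye-only gaps so eye selection
  is non-trivial.

Ages are drawn uniformly on [6, 12] years independently of group, so the
age covariate is exercised under a true null. Per-subject seeds derive from
the master seed through a `SeedSequence`; every generator is a pure function
of its spec.

What the generator does **not** emulate: the pupillary light reflex,
luminance or gaze-angle coupling, task events, autocorrelated measurement
noise, or any true relation between age and pupil dynamics. Passing tests
show the pipeline recovers structure *of the kind injected*; they do not
certify sensitivity to the subtler dynamics of real recordings.

## Preprocessing

Stage order is fixed: eye selection → outlier removal → gap classification →
interpolation → normalization.

* **Eye selection**: the eye with the greater count of valid samples; ties
  go to the left eye (deterministic, documented).
* **Outlier removal**: sliding Hampel filter, half-width 50 samples (1 s at
  50 Hz), threshold 3 × 1.4826 × MAD of the window. A bare "±3 SD" rule is
  ambiguous between this and a global z-score cut, so a `global` mode exists
  behind a config switch for sensitivity checks. Zero-MAD windows remove a
  sample only if it differs from the window median, which leaves constant
  series untouched. Note an honest Hampel filter flags ~0.3% of clean
  Gaussian-ish samples by chance; these become 1-sample gaps and are
  immediately re-interpolated.
* **Gap rule**: maximal missing runs of ≤ 2 s (100 samples at 50 Hz) that
  are *interior* (valid data on both sides) are interpolated with a global
  Akima piecewise cubic built on all valid samples (linear fallback when
  fewer than 5 valid anchors exist). Edge gaps and longer gaps are never
  filled; they stay masked rather than being physically deleted, so window
  indices remain aligned to time — deleting would silently concatenate
  non-adjacent dynamics. Akima overshoot inside filled gaps is clipped to
  [0, 1] after normalization.
* **Normalization**: min-max over the whole per-subject cleaned series (not
  per window), so observed extrema map exactly to 0 and 1. Constant series
  raise a degenerate-normalization error.

Idempotence holds in the relevant sense: re-running the chain on its own
output changes nothing apart from the Hampel filter's chance-level flags.

## Embedding parameters

* AMI uses an equal-width 2-D histogram (nats), n_bins = ⌈√(n/5)⌉ capped at
  16 — robust at 500-sample windows. The delay is the first lag with
  AMI ≤ AMI(0)/e; if no crossing occurs within `max_lag` the maximum lag is
  returned with a warning flag.
* FNN uses the Kennel criterion with classical thresholds rtol = 10,
  atol = 2 (in units of the series SD). The dimension is the smallest one
  attaining the minimum FNN fraction (a drop-below-threshold variant is
  available). Numerically identical states (periodic data) are forced to
  count as true neighbors; without that floor, ratios of rounding errors
  explode past rtol.
* Cohort-level parameters are the mode of per-window estimates across
  subjects, ties toward the smaller value. The pipeline defaults to the
  fixed pair (delay 6, dimension 6) typical for these signals; `auto`
  re-estimates from the data.

## Recurrence engine

* **Norm**: Euclidean by default; maximum norm available.
* **Theiler convention**: `theiler` is the half-width of the band excluded
  around the line of identity — pairs with |i−j| < theiler are ineligible.
  Default 1 (exactly the LOI excluded): with a 25-sample minimum line
  length, the LOI would otherwise contribute a dominant "deterministic"
  line to every window. Setting 0 restores the LOI for strict replication.
* **Diagonal lines** are counted on the upper triangle only; the matrix is
  symmetric, so DET/ENT (which depend only on the length histogram) are
  unaffected by the choice of triangle. RR counts both triangles over
  eligible cells.
* **ENT** is in natural log over lines of length ≥ min_diag (default 25);
  0 or 1 distinct lengths give ENT 0. DET is 0 when there are no recurrent
  points.
* Windows containing any residual missing sample yield missing measures
  (kept, flagged) instead of being skipped, preserving cross-subject window
  alignment; subjects with > 20% incomplete windows are excluded with a
  warning.
* **Radius calibration** bisects ε until the grand-mean RR over all
  windows and subjects reaches the target (default 10%, tolerance 0.5 pp).
  Inside the bisection each window is represented by a sorted random
  subsample of its eligible pairwise distances (default 5000 pairs; the
  per-window ECDF error ~0.5 pp averages out across thousands of windows);
  the achieved RR is then recomputed exactly at the returned radius.
  The engine itself is validated against a naive double-loop implementation
  with exact equality on random series.

## Spectral slope

Welch PSD with Hann taper, 50% overlap, linear per-segment detrending;
segment length 256 for 500-sample analysis windows and 512 for 2048-sample
reference noises. The slope fit runs over the Welch grid from the first
non-DC bin up to **half the Nyquist frequency** (fs/4). The cap matters: a
discrete random walk's spectrum is 1/(2 sin(ω/2))², which flattens relative
to the f⁻² law toward Nyquist; fitting the full band biases β shallow by
about 0.2 for Brownian input, while the capped band recovers 0 / −1 / −2
for the three reference colors within sampling error. β is invariant to
amplitude scaling and to the log base.

## Group statistics

The mixed (split-plot) ANCOVA is fitted as two OLS strata:

* **Between stratum**: subject means on intercept + effect-coded group +
  centered age; error df = n − 3 (e.g. 67 − 3 = 64).
* **Within stratum**: deviations from subject means on window effects,
  window × group, window × age; error df = (W−1)(n−3) (e.g. 55 × 64 = 3520).

Sums of squares are partial (Type III by model comparison), so results are
well-defined for unbalanced groups; with balanced groups and no covariate
the decomposition reduces exactly to the classical split-plot formulas
(verified against both a hand-computed decomposition and pingouin). No
installed library offers this design with a covariate, which is why the
strata are fitted directly. No sphericity correction is applied by default
(a Greenhouse–Geisser option adjusts the within dfs). Effect sizes are
partial eta-squared, η_p² = F·df₁/(F·df₁+df₂).

Missing-window policy is complete-case per measure (subjects with any
missing window are dropped, with a warning). Post hocs are per-window
two-sided pooled t-tests at the Bonferroni threshold α/W.

## Problem sizes used by the test suite

The acceptance-level checks run at: 2048 samples × 20 seeds for the
reference-noise benchmark; the full default cohort (24 + 43 subjects,
180 s) for radius calibration; 10 master seeds of that cohort (radius
calibrated once and reused, as a study would fix one threshold) for
parameter recovery; and 200 replicates of a reduced null cohort (8 + 8
subjects, 20 windows, zero injection) for type-I calibration, judged by a
binomial test against α = 0.05.

## Known limitations

* The AMI estimator is a binned plug-in; it inherits the usual positive
  bias at short windows (the 1/e criterion is insensitive to this level
  shift in practice).
* Radius calibration assumes RR is monotone in ε (true) and that the
  subsampled ECDF is adequate; pass `subsample_pairs=None` for exact
  bisection on small cohorts.
* The ANCOVA's covariate enters linearly in both strata; no subject-level
  random slopes (a mixed-effects reformulation is out of scope).
* Laminarity, trapping time, L_max and cross/joint RQA are deliberately
  not implemented; `min_vert` is stored for interface completeness only.
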