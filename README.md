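# pupilrqa

Nonlinear analysis of pupil-diameter fluctuations for two-group
(solver / non-solver) insight-task studies, built around windowed
Recurrence Quantification Analysis (RQA) and spectral scaling exponents.

Pupil diameter recorded at 50 Hz during problem solving is a noisy,
nonstationary physiological signal. Conventional descriptives (windowed mean
and SD) often miss group differences that show up in the signal's *temporal
structure*. This package implements the full chain needed to test for such
differences:

1. **Preprocessing** — per-subject eye selection (most valid samples),
   sliding Hampel outlier removal (median ± 3·1.4826·MAD in a 2-s window),
   Akima interpolation of missing-data gaps ≤ 2 s (100 samples), min-max
   normalization to [0, 1]. Longer gaps stay masked.
2. **Embedding parameters** — delay from average mutual information (first
   lag with AMI ≤ AMI(0)/e), dimension from false nearest neighbors,
   aggregated across windows and subjects by mode.
3. **Windowed RQA** — time-delay embedding
   v_i = (x_i, x_{i+τ}, …, x_{i+(m−1)τ}), recurrence matrix
   R_ij = Θ(ε − ‖v_i − v_j‖), and diagonal-line measures per 500-sample
   window stepped by 100 over the last 120 s (56 windows):
   - **RR** = 100 · Σ R_ij / N_eligible (recurrence rate, %)
   - **DET** = 100 · Σ_{ℓ≥ℓ_min} ℓ·P(ℓ) / Σ_ℓ ℓ·P(ℓ) (determinism, %,
     ℓ_min = 25)
   - **ENT** = −Σ_{ℓ≥ℓ_min} p(ℓ) ln p(ℓ) (Shannon entropy of diagonal-line
     lengths, nats)

   The radius ε is calibrated by bisection so the grand-mean RR across all
   windows and subjects hits a target (default 10%).
4. **Spectral slope** — Welch PSD per window and the scaling exponent β as
   the OLS slope of log₁₀ power vs log₁₀ frequency (β ≈ 0 white, −1 pink,
   −2 Brownian noise).
5. **Group statistics** — two-way mixed ANOVA/ANCOVA per measure
   (between = group, within = 56 windows, covariate = age), partial
   eta-squared η_p² = F·df₁/(F·df₁ + df₂), Bonferroni per-window post hocs.

Because raw recordings of this kind are rarely shareable, the package ships
a first-class synthetic-cohort generator (`pupilrqa.synth`): seeded 50 Hz
binocular traces with Brownian-like drift, blink gaps, outlier spikes, and a
solver-group epoch of injected white noise that lowers ENT/DET without
shifting the windowed mean — so the whole pipeline is testable end to end.

## Worked example

```bash
python examples/cohort_group_analysis.py
```

simulates 8 solvers and 12 non-solvers, calibrates the radius and runs the
mixed ANCOVA per measure. Output from one run:

```
analyzed 20 subjects; calibrated radius 0.0432 (grand-mean RR 9.99%)

 ent:  group F(1, 13) = 3.147, p = 0.099, eta_p2 = 0.195 | interaction F(55, 715) = 2.708, p = 0.0000, eta_p2 = 0.172
 det:  group F(1, 13) = 5.920, p = 0.030, eta_p2 = 0.313 | interaction F(55, 715) = 2.766, p = 0.0000, eta_p2 = 0.175
mean:  group F(1, 13) = 1.085, p = 0.317, eta_p2 = 0.077 | interaction F(55, 715) = 0.164, p = 1.0000, eta_p2 = 0.012
  sd:  group F(1, 13) = 0.386, p = 0.545, eta_p2 = 0.029 | interaction F(55, 715) = 1.684, p = 0.0019, eta_p2 = 0.115
```

The group × window interaction for ENT and DET is strongly significant — the
solver group's injected late-trace epoch of reduced deterministic structure
is detected — while the windowed mean shows nothing, illustrating why the
recurrence measures are worth the extra machinery.

Other examples: `examples/reference_noises.py` (white/pink/Brownian
benchmark: β ≈ 0 / −1 / −2 and ENT/RR/DET ordered lowest→highest),
`examples/preprocess_one_trace.py` (cleaning provenance for one trace),
`examples/windowed_measures.py` (per-window measures for one solver).

A thin CLI mirrors the library: `pupilrqa simulate | preprocess | rqa |
psd | stats | run-all | benchmark` (see `pupilrqa --help`).

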