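"""Full group analysis on a reduced synthetic cohort.

Simulates 8 solvers and 12 non-solvers, calibrates the recurrence radius to
a 10% mean recurrence rate, computes windowed ENT/DET/RR/beta/mean/SD, and
runs the mixed ANCOVA (between = group, within = window, covariate = age)
per measure.  The solver group carries an epoch of injected white noise, so
the ENT group x window interaction should be significant while the windowed
mean shows nothing.
"""

import warnings

from pupilrqa import CohortSpec, RunConfig, run_pipeline

config = RunConfig(
    cohort=CohortSpec(n_solvers=8, n_nonsolvers=12),
    seed=42,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(config)

print(f"analyzed {result.manifest['n_subjects_analyzed']} subjects; "
      f"calibrated radius {result.radius:.4f} "
      f"(grand-mean RR {result.achieved_rr:.2f}%)\n")

for measure in ("ent", "det", "mean", "sd"):
    table = result.anova[measure].set_index("effect")
    g = table.loc["group"]
    i = table.loc["window:group"]
    print(f"{measure:>4}:  group F({g.df1:.0f}, {g.df2:.0f}) = {g.F:.3f}, p = {g.p:.3f}, "
          f"eta_p2 = {g.eta_p2:.3f} | interaction F({i.df1:.0f}, {i.df2:.0f}) = {i.F:.3f}, "
          f"p = {i.p:.4f}, eta_p2 = {i.eta_p2:.3f}")

if "ent" in result.posthoc:
    sig = result.posthoc["ent"]
    windows = sig.loc[sig.significant, "window_index"].tolist()
    print(f"\nBonferroni post hoc (ENT): significant windows {windows}")
print(
    "\nExpected pattern: a clear ENT (and usually DET) group x window "
    "interaction from the solver epoch; a null group effect for the "
    "windowed mean."
)
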