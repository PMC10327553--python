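"""Mixed-design (split-plot) group statistics on per-window measures.

The design mirrors a two-group repeated-measures study: between-subjects
factor = group (solver vs nonsolver), within-subjects factor = analysis
window (1..W), optional covariate = age.  The model is fitted as two OLS
strata:

* between stratum — subject means regressed on group (effect-coded) and
  centered age; error df = n - 2 - (1 if covariate), e.g. 67 - 3 = 64;
* within stratum — deviations from subject means regressed on window
  effects, window x group and window x age; error df = (W-1)(n - 3) with the
  covariate, e.g. 55 * 64 = 3520.

Sums of squares are partial (Type III by model comparison), F-ratios use the
stratum error term, and effect sizes are partial eta-squared
SS_effect / (SS_effect + SS_error) = F df1 / (F df1 + df2).  No sphericity
correction is applied by default (a Greenhouse-Geisser option adjusts the
within-stratum dfs).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import IncompleteDesignError, InvalidSpecError
from .traces import PupilTraceClean, WindowScheme

__all__ = [
    "windowed_descriptives",
    "mixed_anova",
    "bonferroni_posthoc",
    "partial_eta_squared",
    "MEASURES",
]

MEASURES = ("ent", "det", "rr", "beta", "mean", "sd")


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """Partial eta-squared from an F-ratio and its degrees of freedom."""
    if F < 0:
        raise InvalidSpecError("F must be >= 0")
    return (F * df1) / (F * df1 + df2)


def windowed_descriptives(
    traces: list[PupilTraceClean], scheme: WindowScheme
) -> pd.DataFrame:
    """Per-subject per-window mean and SD of the normalized signal.

    Windows containing residual missing samples yield NaN.  Group-level
    aggregation (the group average of the per-subject window means/SDs) is a
    plain groupby on the returned frame.
    """
    rows = []
    for trace in traces:
        starts = scheme.starts(len(trace), trace.fs)
        for w_idx, start in enumerate(starts, start=1):
            chunk = trace.values[start : start + scheme.window]
            complete = bool(np.all(np.isfinite(chunk)))
            rows.append(
                {
                    "subject_id": trace.subject_id,
                    "group": trace.group,
                    "age": trace.age,
                    "window_index": w_idx,
                    "mean": float(np.mean(chunk)) if complete else np.nan,
                    "sd": float(np.std(chunk, ddof=1)) if complete else np.nan,
                    "missing": not complete,
                }
            )
    return pd.DataFrame(rows)


def _complete_case_grid(
    df: pd.DataFrame, dv: str, subject: str, within: str
) -> pd.DataFrame:
    """Wide subject x window grid, dropping subjects with any missing cell."""
    wide = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="first", dropna=False)
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} subject(s) with missing windows for {dv!r}: "
            f"{list(incomplete)[:5]}{'...' if len(incomplete) > 5 else ''}",
            stacklevel=3,
        )
        wide = wide.drop(index=incomplete)
    if wide.shape[0] < 3 or wide.shape[1] < 2:
        raise IncompleteDesignError(
            f"grid too small after complete-case filtering: {wide.shape}"
        )
    return wide


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject_id",
    within: str = "window_index",
    between: str = "group",
    covariate: str | None = "age",
    gg_correction: bool = False,
) -> pd.DataFrame:
    """Two-way mixed ANOVA/ANCOVA on a long per-window measure table.

    Returns one row per effect: between-stratum ``group`` (and ``age``),
    within-stratum ``window``, ``window:group`` (and ``window:age``), with
    columns effect, SS, df1, df2, F, p, eta_p2.  Subjects with any missing
    window value are dropped (complete-case) with a warning.
    """
    cols = [subject, within, between, dv] + ([covariate] if covariate else [])
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise IncompleteDesignError(f"table lacks columns {missing_cols}")

    wide = _complete_case_grid(table, dv, subject, within)
    subj_info = (
        table.drop_duplicates(subject).set_index(subject).loc[wide.index]
    )
    groups = subj_info[between].to_numpy()
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise IncompleteDesignError(f"need exactly 2 groups, got {levels}")
    g = np.where(groups == levels[0], 1.0, -1.0)
    n, W = wide.shape
    if min((g == 1).sum(), (g == -1).sum()) < 2:
        raise IncompleteDesignError("each group needs >= 2 complete-case subjects")
    Y = wide.to_numpy(dtype=float)

    use_cov = covariate is not None
    if use_cov:
        a = subj_info[covariate].to_numpy(dtype=float)
        if np.any(~np.isfinite(a)):
            raise IncompleteDesignError("covariate contains missing values")
        a = a - a.mean()

    results = []

    # ----- between-subjects stratum: subject means ------------------------
    B = Y.mean(axis=1)
    ones = np.ones(n)
    blocks_b: dict[str, np.ndarray] = {"group": g[:, None]}
    if use_cov:
        blocks_b[covariate] = a[:, None]
    X_full_b = np.column_stack([ones] + [blocks_b[k].ravel() for k in blocks_b])
    sse_full_b = _sse(X_full_b, B)
    df_err_b = n - X_full_b.shape[1]
    mse_b = sse_full_b / df_err_b
    for name in blocks_b:
        X_red = np.column_stack(
            [ones] + [blocks_b[k].ravel() for k in blocks_b if k != name]
        )
        ss = max(_sse(X_red, B) - sse_full_b, 0.0) * W  # rescale to cell level
        F = (ss / 1) / (mse_b * W)
        p = float(sps.f.sf(F, 1, df_err_b))
        results.append(
            {"effect": name, "SS": ss, "df1": 1, "df2": df_err_b,
             "F": F, "p": p, "eta_p2": partial_eta_squared(F, 1, df_err_b)}
        )

    # ----- within-subjects stratum: deviations from subject means ---------
    D = (Y - B[:, None]).ravel()  # subject-major order
    # window effect coding: W-1 columns, last level = -1
    C = np.zeros((W, W - 1))
    C[np.arange(W - 1), np.arange(W - 1)] = 1.0
    C[W - 1, :] = -1.0
    C_rep = np.tile(C, (n, 1))
    blocks_w: dict[str, np.ndarray] = {
        "window": C_rep,
        "window:group": C_rep * np.repeat(g, W)[:, None],
    }
    if use_cov:
        blocks_w[f"window:{covariate}"] = C_rep * np.repeat(a, W)[:, None]
    X_full_w = np.column_stack([blocks_w[k] for k in blocks_w])
    sse_full_w = _sse(X_full_w, D)
    n_betas = n - 2 - (1 if use_cov else 0)
    df_err_w = (W - 1) * n_betas
    eps = 1.0
    if gg_correction:
        eps = _greenhouse_geisser_epsilon(Y - Y.mean(axis=0))
    mse_w = sse_full_w / df_err_w
    for name in blocks_w:
        X_red = np.column_stack([blocks_w[k] for k in blocks_w if k != name])
        ss = max(_sse(X_red, D) - sse_full_w, 0.0)
        df1 = W - 1
        F = (ss / df1) / mse_w
        p = float(sps.f.sf(F, df1 * eps, df_err_w * eps))
        results.append(
            {"effect": name, "SS": ss, "df1": df1, "df2": df_err_w,
             "F": F, "p": p, "eta_p2": partial_eta_squared(F, df1, df_err_w)}
        )

    out = pd.DataFrame(results)
    out.attrs["n_subjects"] = n
    out.attrs["n_windows"] = W
    out.attrs["within_error_ss"] = sse_full_w
    out.attrs["between_error_ss"] = sse_full_b * W
    return out


def _greenhouse_geisser_epsilon(Yc: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from centered within-subject data."""
    S = np.cov(Yc, rowvar=False)
    k = S.shape[0]
    num = (k * (np.trace(S) / k - S.mean())) ** 2
    den = (k - 1) * (
        np.sum(S**2) - 2 * k * np.sum(S.mean(axis=0) ** 2) + k**2 * S.mean() ** 2
    )
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def bonferroni_posthoc(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "window_index",
    between: str = "group",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-window two-sample t-tests with a Bonferroni-corrected threshold.

    Intended as the follow-up to a significant group x window interaction;
    each window's two-sided Welch-free pooled t-test is declared significant
    at alpha / W.  Returns per-window statistics and the corrected threshold
    in ``attrs['threshold']``.
    """
    levels = sorted(pd.unique(table[between].dropna()))
    if len(levels) != 2:
        raise IncompleteDesignError(f"need exactly 2 groups, got {levels}")
    windows = sorted(pd.unique(table[within]))
    threshold = alpha / len(windows)
    rows = []
    for w in windows:
        sub = table[table[within] == w]
        x = sub.loc[sub[between] == levels[0], dv].dropna().to_numpy()
        y = sub.loc[sub[between] == levels[1], dv].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            rows.append({"window_index": w, "mean_diff": np.nan, "t": np.nan,
                         "p": np.nan, "significant": False})
            continue
        t, p = sps.ttest_ind(x, y)
        rows.append(
            {"window_index": w, "mean_diff": float(x.mean() - y.mean()),
             "t": float(t), "p": float(p), "significant": bool(p < threshold)}
        )
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = threshold
    out.attrs["groups"] = levels
    return out
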