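"""Shared statistics: Benjamini-Hochberg FDR control, fixed-effects two-way
ANOVA (group x time), and one-way repeated-measures ANOVA with paired
baseline contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import BASELINE_TIME_POINTS


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{k >= i} (m/k) p_(k), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class AnovaResult:
    """F and p for the two main effects and their interaction."""

    f_group: float
    p_group: float
    f_time: float
    p_time: float
    f_interaction: float
    p_interaction: float
    table: pd.DataFrame  # full sequential-SS decomposition


def _f_and_p(ss_effect, df_effect, ss_resid, df_resid, tol: float = 0.0
             ) -> tuple[float, float]:
    # constant data: no effect and no residual variance -> F = 0, p = 1
    if ss_effect <= tol or df_effect == 0:
        return 0.0, 1.0
    if ss_resid <= tol or df_resid == 0:
        return float("inf"), 0.0
    f = (ss_effect / df_effect) / (ss_resid / df_resid)
    return f, float(sps.f.sf(f, df_effect, df_resid))


def two_way_anova(values, factor_a, factor_b) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction.

    Unbalanced designs are handled by type-I sequential sums of squares in
    the order (factor_a, factor_b, interaction).  Every factor-level cell
    must contain at least one observation.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "a": pd.Categorical(factor_a),
            "b": pd.Categorical(factor_b),
        }
    ).dropna(subset=["value"])
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("two_way_anova needs >= 2 levels per factor")
    cells = df.groupby(["a", "b"], observed=False).size()
    empty = cells[cells == 0]
    if len(empty):
        raise ValueError(f"empty design cells: {list(empty.index)}")

    y = df["value"].to_numpy()
    ss_total = float(np.square(y - y.mean()).sum())
    if ss_total <= 1e-20 * len(y) * max(1.0, float(np.square(y).mean())):
        # constant responses: every decomposition term is zero
        table = pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": 0.0, "PR(>F)": 1.0},
            index=["C(a)", "C(b)", "C(a):C(b)", "Residual"],
        )
        return AnovaResult(0.0, 1.0, 0.0, 1.0, 0.0, 1.0, table)

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    model = smf.ols("value ~ C(a) * C(b)", data=df).fit()
    # anova_lm divides by residual MS, which is 0 for constant data; take the
    # sums of squares and form the F ratios ourselves so degenerate inputs
    # return the conventional F = 0, p = 1.
    with np.errstate(divide="ignore", invalid="ignore"):
        table = anova_lm(model, typ=1)
    ss = table["sum_sq"]
    dfree = table["df"]
    # numerical zero relative to the data's own spread
    tol = 1e-12 * ss_total
    fa, pa = _f_and_p(ss["C(a)"], dfree["C(a)"], ss["Residual"],
                      dfree["Residual"], tol)
    fb, pb = _f_and_p(ss["C(b)"], dfree["C(b)"], ss["Residual"],
                      dfree["Residual"], tol)
    fab, pab = _f_and_p(
        ss["C(a):C(b)"], dfree["C(a):C(b)"], ss["Residual"],
        dfree["Residual"], tol
    )
    return AnovaResult(fa, pa, fb, pb, fab, pab, table)


@dataclass
class RMAnovaResult:
    """One-way repeated-measures ANOVA plus paired baseline contrasts."""

    f: float
    p: float
    df_time: int
    df_error: int
    n_subjects: int
    contrasts: pd.DataFrame  # time_point, t, p, padj


def rm_anova_timepoints(
    wide: pd.DataFrame, baseline: tuple[str, ...] = BASELINE_TIME_POINTS
) -> RMAnovaResult:
    """Repeated-measures ANOVA over time on a subjects x time-points table.

    Subjects with any missing cell are dropped (listwise; missing values are
    never imputed).  The omnibus F removes the subject effect and tests the
    time effect against the subject x time residual.  Each non-baseline time
    point is additionally contrasted against the subject's baseline mean by
    a paired t-test, BH-adjusted across contrasts.
    """
    complete = wide.dropna(axis=0, how="any")
    n, t = complete.shape
    if n < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 complete subjects")
    if t < 2:
        raise ValueError("need >= 2 time points")
    x = complete.to_numpy(dtype=float)
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    ss_subj = t * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_time = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_time
    df_time, df_err = t - 1, (t - 1) * (n - 1)
    f, p = _f_and_p(ss_time, df_time, ss_err, df_err)

    base_cols = [c for c in complete.columns if c in baseline]
    rows = []
    if base_cols:
        base_mean = complete[base_cols].mean(axis=1)
        for col in complete.columns:
            if col in base_cols:
                continue
            tstat, pval = sps.ttest_rel(complete[col], base_mean)
            rows.append({"time_point": col, "t": float(tstat), "p": float(pval)})
    contrasts = pd.DataFrame(rows, columns=["time_point", "t", "p"])
    if len(contrasts):
        contrasts["p"] = contrasts["p"].fillna(1.0)  # constant differences
        contrasts["padj"] = bh_adjust(contrasts["p"].to_numpy())
    else:
        contrasts["padj"] = []
    return RMAnovaResult(f, p, df_time, df_err, n, contrasts)
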