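"""Differential expression of miRNA counts and the biomarker funnel.

Each post-baseline time point is contrasted against the group's pooled
baseline (-9w/-8w/-7w) on size-factor-normalized counts.  The test is a
negative-binomial Wald test on the log2 ratio of condition means with a
delta-method variance, Var(log2 mean) ~ (1/mean + alpha) / (n ln^2 2), using
a method-of-moments dispersion pooled across design strata.  A miRNA is
significantly dysregulated in a contrast when |FC| > 1.5 and raw p < 0.05;
the funnel keeps miRNAs regulated in both treatment groups but not in the
control group, and promotes those with mean normalized count above 20 to
the headline set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig
from .design import CONTRAST_TIME_POINTS, GROUPS, StudyDesign
from .stats import bh_adjust

LN2_SQ = np.log(2.0) ** 2
DISPERSION_FLOOR = 1e-8


def prevalence_filter(counts: pd.DataFrame, min_fraction: float = 0.75) -> pd.DataFrame:
    """Keep miRNAs detected (>= 1 read) in at least `min_fraction` of samples."""
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must lie in [0, 1]")
    detected = (counts.to_numpy() >= 1).mean(axis=1)
    return counts.loc[detected >= min_fraction]


def estimate_dispersion(values, strata) -> float:
    """Method-of-moments NB dispersion for one miRNA, pooled across strata.

    Within each stratum with n >= 2 samples, alpha_s = (s^2 - m) / m^2 from
    the stratum mean and variance of normalized counts; strata are pooled by
    degrees of freedom and the estimate floored at a small positive value.
    An all-zero miRNA returns 0 with a warning.
    """
    values = np.asarray(values, dtype=float)
    strata = np.asarray(strata)
    if np.all(values == 0):
        warnings.warn("all-zero miRNA: dispersion set to 0", stacklevel=2)
        return 0.0
    num = 0.0
    den = 0
    for s in np.unique(strata):
        v = values[strata == s]
        if v.size < 2:
            continue
        m = v.mean()
        if m <= 0:
            continue
        var = v.var(ddof=1)
        num += (var - m) / m**2 * (v.size - 1)
        den += v.size - 1
    if den == 0:
        raise ValueError("need at least one stratum with >= 2 samples")
    return max(DISPERSION_FLOOR, num / den)


def estimate_dispersions(
    normalized: pd.DataFrame, strata: pd.Series
) -> pd.Series:
    """Vectorized per-miRNA dispersion over all design strata."""
    x = normalized.to_numpy(dtype=float)
    labels = strata.reindex(normalized.columns).to_numpy()
    num = np.zeros(x.shape[0])
    den = 0
    for s in pd.unique(labels):
        v = x[:, labels == s]
        if v.shape[1] < 2:
            continue
        m = v.mean(axis=1)
        var = v.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (var - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        num += a * (v.shape[1] - 1)
        den += v.shape[1] - 1
    if den == 0:
        raise ValueError("no stratum with >= 2 samples")
    alpha = np.maximum(DISPERSION_FLOOR, num / den)
    alpha[(x == 0).all(axis=1)] = 0.0
    return pd.Series(alpha, index=normalized.index, name="dispersion")


def _wald(mu_b, mu_t, alpha, n_b, n_t, pseudo_mean: float = 0.5):
    """Vectorized NB Wald test on log2(mu_t / mu_b).

    Returns (log2fc, p).  A pseudo-mean is added to both means only when
    either is zero; a miRNA with both means zero gets log2fc 0, p 1.
    """
    mu_b = np.asarray(mu_b, dtype=float)
    mu_t = np.asarray(mu_t, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    both_zero = (mu_b == 0) & (mu_t == 0)
    any_zero = (mu_b == 0) | (mu_t == 0)
    b = mu_b + np.where(any_zero, pseudo_mean, 0.0)
    t = mu_t + np.where(any_zero, pseudo_mean, 0.0)
    log2fc = np.where(both_zero, 0.0, np.log2(t / b))
    var = (1.0 / b + alpha) / (n_b * LN2_SQ) + (1.0 / t + alpha) / (n_t * LN2_SQ)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / np.sqrt(var)
    p = np.where(both_zero, 1.0, 2.0 * sps.norm.sf(np.abs(z)))
    return log2fc, p


def nb_wald_test(baseline, timepoint, alpha: float) -> tuple[float, float]:
    """NB Wald contrast of one time point vs pooled baseline for one miRNA.

    `baseline` and `timepoint` are normalized counts; returns (log2fc, p).
    """
    baseline = np.asarray(baseline, dtype=float)
    timepoint = np.asarray(timepoint, dtype=float)
    if baseline.size < 2:
        raise ValueError("need >= 2 baseline samples")
    if timepoint.size < 1:
        raise ValueError("need >= 1 time-point sample")
    lfc, p = _wald(
        baseline.mean(), timepoint.mean(), alpha, baseline.size, timepoint.size
    )
    return float(lfc), float(p)


def run_contrasts(
    normalized: pd.DataFrame,
    design: StudyDesign,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """All per-group, per-time-point contrasts vs pooled baseline.

    Returns one row per (miRNA, group, time point) with log2fc, p, padj (BH
    across miRNAs within each contrast family) and the significance call
    |FC| > fc_threshold and raw p < p_threshold.  BH-adjusted values are
    reported but do not gate the funnel.
    """
    config = config or PipelineConfig()
    meta = design.to_frame().set_index("sample_id")
    missing_groups = [g for g in GROUPS if g not in design.groups_present]
    if missing_groups:
        raise ValueError(f"groups absent from design: {missing_groups}")
    strata = meta["group"].astype(str) + "/" + meta["time_point"].astype(str)
    alpha = estimate_dispersions(normalized, strata)
    lfc_cut = np.log2(config.fc_threshold)
    contrast_tps = [
        tp for tp in CONTRAST_TIME_POINTS
        if config.include_t0_contrast or tp != "t0"
    ]
    frames = []
    for group in GROUPS:
        base_ids = [s for s in design.select(group=group, phase="baseline")
                    if s in normalized.columns]
        if len(base_ids) < 2:
            raise ValueError(f"group {group}: need >= 2 baseline samples")
        mu_b = normalized[base_ids].mean(axis=1).to_numpy()
        for tp in contrast_tps:
            tp_ids = [s for s in design.select(group=group, time_point=tp)
                      if s in normalized.columns]
            if not tp_ids:
                continue
            mu_t = normalized[tp_ids].mean(axis=1).to_numpy()
            lfc, p = _wald(
                mu_b, mu_t, alpha.to_numpy(), len(base_ids), len(tp_ids)
            )
            frames.append(
                pd.DataFrame(
                    {
                        "mirna_id": normalized.index,
                        "group": group,
                        "time_point": tp,
                        "log2fc": lfc,
                        "p": p,
                        "padj": bh_adjust(p),
                        "significant": (np.abs(lfc) > lfc_cut)
                        & (p < config.p_threshold),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


@dataclass
class FunnelReport:
    """Venn funnel over per-group regulated miRNA sets."""

    regulated: dict[str, set[str]]
    candidates: list[str]
    headline: list[str]
    set_sizes: dict[str, int] = field(default_factory=dict)
    venn: dict[str, int] = field(default_factory=dict)
    mean_normalized: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "set_sizes": self.set_sizes,
            "venn": self.venn,
            "candidates": sorted(self.candidates),
            "headline": sorted(self.headline),
            "mean_normalized": self.mean_normalized,
        }


def _regulated_sets(
    results: pd.DataFrame, config: PipelineConfig
) -> dict[str, set[str]]:
    sig = results[results["significant"]]
    out: dict[str, set[str]] = {g: set() for g in GROUPS}
    for (group, mirna), sub in sig.groupby(["group", "mirna_id"], observed=True):
        n_sig = len(sub)
        if config.require_same_direction:
            n_sig = max((sub["log2fc"] > 0).sum(), (sub["log2fc"] < 0).sum())
        if n_sig >= config.min_sig_timepoints:
            out[str(group)].add(str(mirna))
    return out


def biomarker_funnel(
    results: pd.DataFrame,
    normalized: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> FunnelReport:
    """Treatment-intersection-minus-control candidate selection.

    candidates = (regulated in group1) & (regulated in group2) - (regulated
    in control); the headline set keeps candidates whose overall mean
    normalized count exceeds `config.abundance`.
    """
    config = config or PipelineConfig()
    groups_seen = set(results["group"].unique())
    if not set(GROUPS) <= groups_seen:
        raise ValueError(f"results must cover all of {GROUPS}, got {groups_seen}")
    reg = _regulated_sets(results, config)
    candidates = (reg["group1"] & reg["group2"]) - reg["control"]
    mean_norm = normalized.mean(axis=1)
    headline = {m for m in candidates if mean_norm.get(m, 0.0) > config.abundance}
    venn = {
        "control": len(reg["control"]),
        "group1": len(reg["group1"]),
        "group2": len(reg["group2"]),
        "group1&group2": len(reg["group1"] & reg["group2"]),
        "group1&control": len(reg["group1"] & reg["control"]),
        "group2&control": len(reg["group2"] & reg["control"]),
        "all_three": len(reg["group1"] & reg["group2"] & reg["control"]),
    }
    return FunnelReport(
        regulated=reg,
        candidates=sorted(candidates),
        headline=sorted(headline),
        set_sizes={g: len(reg[g]) for g in GROUPS},
        venn=venn,
        mean_normalized={m: float(mean_norm.get(m, 0.0)) for m in sorted(candidates)},
    )
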