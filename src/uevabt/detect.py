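"""Longitudinal static-model doping detection.

A biomarker value is declared unphysiological when its z-score against the
baseline distribution (-9w/-8w/-7w visits) exceeds |2| (~95% two-sided
normal coverage) or |3| (~99.7%).  Flags are compared to ground-truth doped
status (post-transfusion samples of the two treatment groups) to yield
per-miRNA sensitivity and specificity, the anti-doping figure of merit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import StudyDesign, TREATMENT_GROUPS


def threshold_coverage(z: float) -> float:
    """Two-sided standard-normal coverage of [-z, z], in percent."""
    if z < 0:
        raise ValueError("threshold must be >= 0")
    return 100.0 * (2.0 * sps.norm.cdf(z) - 1.0)


def fit_baseline(
    normalized: pd.DataFrame,
    design: StudyDesign,
    scope: str = "population",
) -> pd.DataFrame:
    """Baseline mean/SD per miRNA from the -9w/-8w/-7w visits.

    scope "population" pools all baseline samples; "per_subject" fits each
    subject's own baseline (rows indexed by (mirna_id, subject_id)).  SD is
    the sample SD (ddof=1); a zero-SD miRNA is marked unflaggable.
    """
    if scope == "population":
        ids = [s for s in design.select(phase="baseline")
               if s in normalized.columns]
        if len(ids) < 2:
            raise ValueError("need >= 2 baseline samples")
        sub = normalized[ids]
        out = pd.DataFrame(
            {
                "mu": sub.mean(axis=1),
                "sigma": sub.std(axis=1, ddof=1),
                "n_baseline": len(ids),
            }
        )
        out.index.name = "mirna_id"
    elif scope == "per_subject":
        rows = []
        for subj in design.subjects:
            ids = [s for s in design.select(subject_id=subj, phase="baseline")
                   if s in normalized.columns]
            if len(ids) < 2:
                warnings.warn(
                    f"subject {subj}: {len(ids)} baseline visit(s), skipped",
                    stacklevel=2,
                )
                continue
            sub = normalized[ids]
            rows.append(
                pd.DataFrame(
                    {
                        "mirna_id": normalized.index,
                        "subject_id": subj,
                        "mu": sub.mean(axis=1).to_numpy(),
                        "sigma": sub.std(axis=1, ddof=1).to_numpy(),
                        "n_baseline": len(ids),
                    }
                )
            )
        if not rows:
            raise ValueError("no subject with >= 2 baseline visits")
        out = pd.concat(rows).set_index(["mirna_id", "subject_id"])
    else:
        raise ValueError(f"unknown scope {scope!r}")
    n_flat = (out["sigma"] == 0).sum()
    if n_flat:
        warnings.warn(f"{n_flat} baseline fit(s) with sigma = 0 are unflaggable",
                      stacklevel=2)
    return out


def flag_samples(
    normalized: pd.DataFrame,
    baseline: pd.DataFrame,
    design: StudyDesign,
    z_thresholds: tuple[float, float] = (2.0, 3.0),
    t0_truth: str = "clean",
) -> pd.DataFrame:
    """z-scores and flags for every sample of every fitted miRNA.

    Flags use strict inequality |z| > threshold.  Truth labels: a sample is
    "doped" when its subject is in a treatment group and its phase is post
    (the t=0 visit follows `t0_truth`); all other samples, including the
    baseline visits the model was fitted on, are "clean", so baseline
    exceedances of treatment subjects count as false positives.
    """
    if t0_truth not in ("clean", "doped", "excluded"):
        raise ValueError(f"unknown t0 policy {t0_truth!r}")
    z95, z997 = sorted(z_thresholds)
    per_subject = isinstance(baseline.index, pd.MultiIndex)
    rows = []
    for s in design.samples:
        if s.group in TREATMENT_GROUPS and s.phase != "baseline":
            truth = t0_truth if s.phase == "pre" else "doped"
        else:
            # baseline visits (all groups) are clean: their exceedances
            # count as false positives
            truth = "clean"
        if s.sample_id not in normalized.columns:
            continue
        values = normalized[s.sample_id]
        if per_subject:
            try:
                stats = baseline.xs(s.subject_id, level="subject_id")
            except KeyError:
                continue
        else:
            stats = baseline
        common = stats.index.intersection(values.index)
        st = stats.loc[common]
        v = values.loc[common].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (v - st["mu"].to_numpy()) / st["sigma"].to_numpy()
        df = pd.DataFrame(
            {
                "sample_id": s.sample_id,
                "subject_id": s.subject_id,
                "group": s.group,
                "time_point": s.time_point,
                "mirna_id": common,
                "z": z,
                "truth_label": truth,
            }
        )
        rows.append(df)
    flags = pd.concat(rows, ignore_index=True)
    flags = flags[np.isfinite(flags["z"])].reset_index(drop=True)
    flags["flag95"] = flags["z"].abs() > z95
    flags["flag997"] = flags["z"].abs() > z997
    return flags


@dataclass
class ConfusionMatrix:
    """Sample-level detection counts and rates."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return None if denom == 0 else 100.0 * self.tp / denom

    @property
    def specificity(self) -> float | None:
        denom = self.tn + self.fp
        return None if denom == 0 else 100.0 * self.tn / denom

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


def evaluate_detection(
    flags: pd.DataFrame, threshold: float | str = 95
) -> dict[str, ConfusionMatrix]:
    """Per-miRNA confusion matrices at the 95% or 99.7% threshold.

    Samples labelled "excluded" are ignored.  Raises when no labelled
    sample remains.
    """
    col = {95: "flag95", "95": "flag95", 99.7: "flag997", "99.7": "flag997"}.get(
        threshold
    )
    if col is None:
        raise ValueError("threshold must be 95 or 99.7")
    usable = flags[flags["truth_label"].isin(["doped", "clean"])]
    if usable.empty:
        raise ValueError("no doped or clean samples to evaluate")
    out = {}
    for mirna, sub in usable.groupby("mirna_id", observed=True):
        doped = sub["truth_label"] == "doped"
        flagged = sub[col].astype(bool)
        out[str(mirna)] = ConfusionMatrix(
            tp=int((doped & flagged).sum()),
            fp=int((~doped & flagged).sum()),
            tn=int((~doped & ~flagged).sum()),
            fn=int((doped & ~flagged).sum()),
        )
    return out


def threshold_sweep(flags: pd.DataFrame, grid) -> pd.DataFrame:
    """Sensitivity/specificity over a grid of |z| thresholds, pooled over
    miRNAs.  Sensitivity is non-increasing and specificity non-decreasing in
    the threshold."""
    usable = flags[flags["truth_label"].isin(["doped", "clean"])]
    doped = (usable["truth_label"] == "doped").to_numpy()
    if doped.sum() == 0 or (~doped).sum() == 0:
        raise ValueError("sweep needs >= 1 doped and >= 1 clean sample")
    absz = usable["z"].abs().to_numpy()
    rows = []
    for thr in np.asarray(grid, dtype=float):
        flagged = absz > thr
        rows.append(
            {
                "threshold": thr,
                "sensitivity": 100.0 * (flagged & doped).sum() / doped.sum(),
                "specificity": 100.0 * (~flagged & ~doped).sum() / (~doped).sum(),
            }
        )
    return pd.DataFrame(rows)
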