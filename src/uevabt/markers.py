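"""Bead-based surface-marker pipeline.

Raw median fluorescence intensities pass through a fixed order of steps:
buffer-background subtraction, isotype-control validity gating, creatinine
normalization (rMFI per U_Crea), then per-subject baseline-relative log2
fold changes.  Sample profiles are compared by hierarchical clustering on
pairwise-complete Pearson correlation distance, scored against group labels
with the adjusted Rand index; missing values are never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .design import StudyDesign
from .io import MFIMatrix
from .stats import bh_adjust, two_way_anova


def subtract_background(
    mfi: pd.DataFrame, background: pd.Series
) -> pd.DataFrame:
    """Per-marker buffer background subtraction, clamped at zero."""
    missing = [m for m in mfi.index if m not in background.index]
    if missing:
        raise ValueError(f"no background value for markers: {missing}")
    corrected = mfi.sub(background.reindex(mfi.index), axis=0)
    return corrected.clip(lower=0.0).where(mfi.notna())


def apply_isotype_threshold(
    corrected: pd.DataFrame, isotype: pd.Series
) -> pd.DataFrame:
    """Keep only signals strictly above the sample's corrected isotype value.

    `isotype` is one background-corrected value per sample (for a multi-
    control panel, the maximum of the corrected controls).  Samples with a
    missing isotype value lose all their markers, with a warning.
    """
    iso = isotype.reindex(corrected.columns)
    bad = iso.index[iso.isna()].tolist()
    if bad:
        warnings.warn(
            f"missing isotype control for samples {bad}: all markers dropped",
            stacklevel=2,
        )
    out = corrected.where(corrected.gt(iso, axis=1))
    out.loc[:, bad] = np.nan
    return out


def isotype_reference(mfi: MFIMatrix) -> pd.Series:
    """Background-corrected per-sample isotype threshold (max over controls)."""
    corrected = subtract_background(mfi.isotype, mfi.background)
    return corrected.max(axis=0, skipna=True)


def normalize_rmfi(thresholded: pd.DataFrame, u_crea: pd.Series) -> pd.DataFrame:
    """Relative MFI per unit urinary creatinine; missing propagates."""
    crea = u_crea.reindex(thresholded.columns)
    if (crea <= 0).any():
        bad = crea.index[crea <= 0].tolist()
        raise ValueError(f"u_crea must be > 0, offending samples: {bad}")
    return thresholded.div(crea, axis=1)


def detection_frequency(thresholded: pd.DataFrame) -> pd.Series:
    """Percent of samples in which each marker survives the isotype gate."""
    return 100.0 * thresholded.notna().mean(axis=1)


def process_mfi(
    mfi: MFIMatrix,
    design: StudyDesign,
    isotype_before_background: bool = False,
) -> pd.DataFrame:
    """Full raw-MFI -> rMFI pipeline in the documented order.

    The default order is background subtraction first, then the isotype
    gate (both sides background-corrected); the alternative order gates raw
    signals on raw isotype values before subtracting background.
    """
    if isotype_before_background:
        iso_raw = mfi.isotype.max(axis=0, skipna=True)
        gated = mfi.panel.where(mfi.panel.gt(iso_raw, axis=1))
        thresholded = subtract_background(gated, mfi.background)
    else:
        corrected = subtract_background(mfi.panel, mfi.background)
        thresholded = apply_isotype_threshold(corrected, isotype_reference(mfi))
    return normalize_rmfi(thresholded, design.u_crea_series())


def marker_log2fc(rmfi: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """log2 fold change vs the subject's own baseline mean, per marker.

    Baseline reference = mean of the subject's non-missing -9w/-8w/-7w
    values; result is missing when the value or the reference is missing,
    or when the reference is zero (warned).
    """
    out = pd.DataFrame(np.nan, index=rmfi.index, columns=rmfi.columns)
    zero_refs = 0
    for subj in design.subjects:
        base_ids = [s for s in design.select(subject_id=subj, phase="baseline")
                    if s in rmfi.columns]
        subj_ids = [s for s in design.select(subject_id=subj) if s in rmfi.columns]
        if not subj_ids:
            continue
        if not base_ids:
            continue
        ref = rmfi[base_ids].mean(axis=1, skipna=True)
        zero = ref == 0
        zero_refs += int(zero.sum())
        ref = ref.where(~zero)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[subj_ids] = np.log2(rmfi[subj_ids].div(ref, axis=0))
    if zero_refs:
        warnings.warn(
            f"{zero_refs} zero baseline reference(s) produced missing log2FC",
            stacklevel=2,
        )
    return out


def _row_scale(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each marker row to zero mean / unit variance over non-missing
    entries; constant rows are dropped (they carry no contrast)."""
    mu = table.mean(axis=1, skipna=True)
    sd = table.std(axis=1, ddof=1, skipna=True)
    keep = sd > 0
    return table.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)


def _pairwise_pearson_distance(
    scaled: pd.DataFrame, min_shared: int
) -> pd.DataFrame:
    cols = scaled.columns
    x = scaled.to_numpy(dtype=float)
    n = len(cols)
    d = np.full((n, n), np.nan)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.isfinite(x[:, i]) & np.isfinite(x[:, j])
            if mask.sum() < min_shared:
                continue
            xi, xj = x[mask, i], x[mask, j]
            if xi.std() == 0 or xj.std() == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            d[i, j] = d[j, i] = 1.0 - r
    return pd.DataFrame(d, index=cols, columns=cols)


@dataclass
class ClusterResult:
    """Hierarchical clustering of sample log2FC profiles vs group labels."""

    labels: pd.Series  # cluster assignment per sample
    ari: float
    linkage_matrix: np.ndarray
    excluded: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ari": self.ari,
            "labels": {str(k): int(v) for k, v in self.labels.items()},
            "excluded": self.excluded,
            "linkage": self.linkage_matrix.tolist(),
        }


def cluster_separation(
    log2fc: pd.DataFrame,
    group_labels: pd.Series,
    k: int = 2,
    method: str = "average",
    min_shared_markers: int = 3,
) -> ClusterResult:
    """Cluster sample columns on Pearson-correlation distance and score the
    separation of the given group labels with the adjusted Rand index.

    Rows are scaled to zero mean/unit variance (as for heatmap display);
    distances are pairwise-complete over >= `min_shared_markers` shared
    markers.  Samples that cannot be placed (too few shared markers with
    the rest) are excluded and reported.
    """
    if k < 2:
        raise ValueError("need k >= 2 clusters for a separation score")
    cols = [c for c in log2fc.columns if c in group_labels.index]
    table = log2fc[cols].dropna(axis=1, how="all")
    if table.shape[1] < max(k, 2):
        raise ValueError("need at least k samples with data")
    scaled = _row_scale(table)
    dist = _pairwise_pearson_distance(scaled, min_shared_markers)
    excluded: list[str] = []
    # greedily drop the sample with the most undefined distances until the
    # matrix is complete
    while np.isnan(dist.to_numpy()).any():
        n_missing = dist.isna().sum(axis=1)
        worst = n_missing.idxmax()
        excluded.append(str(worst))
        dist = dist.drop(index=worst, columns=worst)
    if dist.shape[0] < max(k, 2):
        raise ValueError(
            f"only {dist.shape[0]} clusterable samples left after exclusions "
            f"{excluded}"
        )
    condensed = squareform(np.maximum(dist.to_numpy(), 0.0), checks=False)
    lm = scipy_linkage(condensed, method=method)
    assignment = fcluster(lm, t=k, criterion="maxclust")
    labels = pd.Series(assignment, index=dist.index, name="cluster")
    truth = group_labels.reindex(dist.index)
    ari = float(adjusted_rand_score(truth.to_numpy(), assignment))
    return ClusterResult(labels=labels, ari=ari, linkage_matrix=lm,
                         excluded=excluded)


def compare_markers_over_time(
    log2fc: pd.DataFrame, design: StudyDesign
) -> pd.DataFrame:
    """Per-marker fixed-effects two-way ANOVA (group x time) on log2FC.

    Markers without at least one observation in every group x time cell are
    skipped and listed with reason "incomplete cells".  p-values are BH-
    adjusted across analysable markers.
    """
    meta = design.to_frame().set_index("sample_id")
    rows = []
    skipped = []
    for marker in log2fc.index:
        vals = log2fc.loc[marker].dropna()
        vals = vals[[s for s in vals.index if s in meta.index]]
        if vals.empty:
            skipped.append(marker)
            continue
        sub = meta.loc[vals.index]
        cells = (
            pd.DataFrame({"g": sub["group"], "t": sub["time_point"]})
            .groupby(["g", "t"], observed=True)
            .size()
        )
        if sub["group"].nunique() < 2 or sub["time_point"].nunique() < 2 or (
            len(cells) < sub["group"].nunique() * sub["time_point"].nunique()
        ):
            skipped.append(marker)
            continue
        res = two_way_anova(vals.to_numpy(), sub["group"], sub["time_point"])
        rows.append(
            {
                "marker_id": marker,
                "f_group": res.f_group, "p_group": res.p_group,
                "f_time": res.f_time, "p_time": res.p_time,
                "f_interaction": res.f_interaction,
                "p_interaction": res.p_interaction,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["marker_id", "f_group", "p_group", "f_time", "p_time",
                 "f_interaction", "p_interaction"],
    )
    if len(out):
        for eff in ("group", "time", "interaction"):
            out[f"padj_{eff}"] = bh_adjust(out[f"p_{eff}"].to_numpy())
    out.attrs["skipped"] = [str(m) for m in skipped]
    return out
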