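"""Count and particle normalization.

Counts are made comparable across libraries with the median-of-ratios size
factor estimator: a miRNA enters the reference set only when it has a
non-zero count in every sample; each sample's factor is the median ratio of
its counts to the per-miRNA geometric means.  Particle concentrations from
nanoparticle tracking are recalculated from the diluted measurement back to
total recovered particles and expressed per gram of urinary creatinine.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import StudyDesign
from .stats import rm_anova_timepoints  # noqa: F401  (re-export; see module docs)


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample (column).

    Raises when no miRNA has all-positive counts; the usual remedy is to
    apply the prevalence filter first.
    """
    x = counts.to_numpy(dtype=float)
    eligible = (x > 0).all(axis=1)
    if not eligible.any():
        raise ValueError(
            "no reference-eligible miRNA (every row has a zero count); "
            "apply a prevalence filter before computing size factors"
        )
    ref = x[eligible]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    s = np.exp(np.median(ratios, axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    missing = [c for c in counts.columns if c not in size_factors.index]
    if missing:
        raise ValueError(f"no size factor for samples: {missing}")
    s = size_factors.reindex(counts.columns)
    if not (s > 0).all():
        raise ValueError("size factors must be strictly positive")
    return counts / s


def log_transform(normalized: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(value + pseudocount), elementwise."""
    if not pseudocount > 0:
        raise ValueError("pseudocount must be > 0")
    return np.log2(normalized + pseudocount)


def screen_outliers(log_matrix: pd.DataFrame, k: float = 5.0) -> list[str]:
    """Flag outlier samples in the space of the first two principal axes.

    Samples (columns) are projected onto the top two right singular vectors
    of the row-centred matrix; a sample is flagged when its Euclidean
    distance from the component-space medoid exceeds the median distance by
    more than k times the median absolute deviation (the usual robust
    outlier rule; distances from a medoid have a positive median, so the
    deviation is measured from it).
    """
    if log_matrix.shape[1] < 3:
        raise ValueError("outlier screening needs >= 3 samples")
    x = log_matrix.to_numpy(dtype=float)
    centred = x - x.mean(axis=1, keepdims=True)
    # columns are samples: project them on the top-2 left basis of centred^T
    _, sv, vt = np.linalg.svd(centred, full_matrices=False)
    scores = vt[:2].T * sv[:2]  # samples x 2 component scores
    pair_d = np.linalg.norm(scores[:, None, :] - scores[None, :, :], axis=2)
    medoid = int(np.argmin(pair_d.sum(axis=1)))
    dist = pair_d[medoid]
    med = np.median(dist)
    mad = np.median(np.abs(dist - med))
    flagged = dist > med + k * mad
    return [str(c) for c, f in zip(log_matrix.columns, flagged) if f]


def normalize_particle_concentration(
    measured_conc, dilution, eluate_volume_ml, urine_input_ml, u_crea
):
    """Particles per gram of urinary creatinine.

    total particles = measured_conc [/mL] x dilution x eluate volume [mL];
    grams creatinine = u_crea [g/L] x urine input [mL] / 1000.
    Accepts scalars or aligned array-likes.
    """
    total_particles = (
        np.asarray(measured_conc, dtype=float)
        * np.asarray(dilution, dtype=float)
        * np.asarray(eluate_volume_ml, dtype=float)
    )
    grams_crea = np.asarray(u_crea, dtype=float) * np.asarray(
        urine_input_ml, dtype=float
    ) / 1000.0
    return total_particles / grams_crea


def normalize_particle_table(
    particles: pd.DataFrame, design: StudyDesign
) -> pd.DataFrame:
    """Apply the particle recalculation to a measurement table.

    Returns one row per sample with the creatinine-normalized concentration
    and the design annotation needed for the repeated-measures comparison.
    """
    meta = design.to_frame().set_index("sample_id")
    missing = [s for s in particles.index if s not in meta.index]
    if missing:
        raise ValueError(f"particle samples absent from design: {missing}")
    u_crea = meta.loc[particles.index, "u_crea"]
    conc = normalize_particle_concentration(
        particles["measured_conc"],
        particles["dilution"],
        particles["eluate_volume_ml"],
        particles["urine_input_ml"],
        u_crea,
    )
    out = meta.loc[particles.index, ["subject_id", "group", "time_point", "phase"]].copy()
    out["particles_per_g_crea"] = np.asarray(conc, dtype=float)
    return out
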