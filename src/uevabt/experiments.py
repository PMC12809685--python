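"""Calibration and parameter-recovery experiments.

These drive the simulator through the analysis stages and measure
operating characteristics: type-I error of the NB Wald contrast, static-
model null flag rates, biomarker-funnel recall/precision against planted
truth, marker cluster separation, and particle-effect recovery.  They are
shared by the test suite, the acceptance script and the analysis drivers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import detect as detect_mod
from . import dge as dge_mod
from . import markers as markers_mod
from . import normalize as norm_mod
from .config import PipelineConfig
from .design import SampleRecord, StudyDesign, TIME_POINTS
from .dge import _wald
from .simulate import SimulationConfig, simulate_cohort, _nb_draw


def wald_null_type1(
    n_reps: int = 10_000,
    alpha: float = 0.4,
    n_b: int = 30,
    n_t: int = 10,
    mean: float = 100.0,
    level: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the NB Wald contrast under equal means.

    Each replicate draws NB(mean, alpha) baseline and time-point samples,
    estimates the dispersion by the pooled method of moments over the two
    strata (exactly as the pipeline does) and tests at `level`.
    """
    rng = np.random.default_rng(seed)
    base = _nb_draw(rng, np.full((n_reps, n_b), mean), alpha).astype(float)
    tp = _nb_draw(rng, np.full((n_reps, n_t), mean), alpha).astype(float)

    def _mom(x):
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        return a

    df_b, df_t = n_b - 1, n_t - 1
    alpha_hat = np.maximum(
        dge_mod.DISPERSION_FLOOR,
        (_mom(base) * df_b + _mom(tp) * df_t) / (df_b + df_t),
    )
    _, p = _wald(base.mean(axis=1), tp.mean(axis=1), alpha_hat, n_b, n_t)
    return float((p < level).mean())


def wald_power(
    fold: float = 2.5,
    n_reps: int = 2_000,
    alpha: float = 0.4,
    n_b: int = 30,
    n_t: int = 10,
    mean: float = 100.0,
    level: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """(median estimated log2FC, power at `level`) for a planted fold."""
    rng = np.random.default_rng(seed)
    base = _nb_draw(rng, np.full((n_reps, n_b), mean), alpha).astype(float)
    tp = _nb_draw(rng, np.full((n_reps, n_t), mean * fold), alpha).astype(float)
    lfc, p = _wald(base.mean(axis=1), tp.mean(axis=1), alpha, n_b, n_t)
    return float(np.median(lfc)), float((p < level).mean())


def funnel_recovery(
    n_seeds: int = 25,
    base_seed: int = 0,
    sim_config: SimulationConfig | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Recall and precision of the biomarker funnel against planted truth.

    One cohort per seed; recall = |candidates & planted| / |planted|,
    precision = |candidates & planted| / |candidates| (1.0 when the funnel
    returns nothing, there being no false claims).
    """
    config = config or PipelineConfig()
    rows = []
    for k in range(n_seeds):
        sc = sim_config or SimulationConfig()
        sc = SimulationConfig(**{**sc.__dict__, "seed": base_seed + k})
        design, counts, _, _, truth = simulate_cohort(sc)
        prevalent = dge_mod.prevalence_filter(counts, config.prevalence)
        size = norm_mod.compute_size_factors(prevalent)
        normalized = norm_mod.normalize_counts(prevalent, size)
        results = dge_mod.run_contrasts(normalized, design, config)
        funnel = dge_mod.biomarker_funnel(results, normalized, config)
        planted = set(truth.planted_mirnas)
        hits = planted & set(funnel.candidates)
        rows.append(
            {
                "seed": sc.seed,
                "n_candidates": len(funnel.candidates),
                "n_headline": len(funnel.headline),
                "recall": len(hits) / len(planted),
                "precision": (
                    len(hits) / len(funnel.candidates) if funnel.candidates else 1.0
                ),
                **{f"n_{g}": n for g, n in funnel.set_sizes.items()},
            }
        )
    return pd.DataFrame(rows)


def _flat_design(n_subjects: int, groups=("control", "group1", "group2")):
    records = []
    for g in groups:
        for i in range(n_subjects):
            subj = f"{g}_{i + 1:02d}"
            for tp in TIME_POINTS:
                records.append(
                    SampleRecord(f"{subj}_{tp}", subj, g, tp, u_crea=1.0)
                )
    return StudyDesign(records)


def detection_null_calibration(
    n_mirna: int = 35, n_subjects: int = 120, seed: int = 0
) -> dict[str, float]:
    """Static-model flag rates when values are i.i.d. normal (no doping).

    Uses the population baseline; rates are measured over non-baseline
    samples and should sit near the nominal two-sided exceedance
    probabilities (4.55% at |z| > 2, 0.27% at |z| > 3).  The default grid
    (3 x 120 subjects, 35 markers, ~10^5 scored pairs) keeps the pooled
    baseline large (~1080 samples) so that sigma-estimation noise, which
    convexly inflates the far tail at small baselines, is negligible; see
    the methods note for the study-scale behaviour.
    """
    rng = np.random.default_rng(seed)
    design = _flat_design(n_subjects)
    values = pd.DataFrame(
        rng.normal(100.0, 10.0, size=(n_mirna, len(design.samples))),
        index=[f"miR-{i:04d}" for i in range(n_mirna)],
        columns=design.sample_ids,
    )
    baseline = detect_mod.fit_baseline(values, design, scope="population")
    flags = detect_mod.flag_samples(values, baseline, design)
    nonbase = flags[~flags["time_point"].isin(["-9w", "-8w", "-7w"])]
    return {
        "rate95": float(100.0 * nonbase["flag95"].mean()),
        "rate997": float(100.0 * nonbase["flag997"].mean()),
        "n_pairs": int(len(nonbase)),
        "nested": bool((~nonbase["flag997"] | nonbase["flag95"]).all()),
    }


def marker_separation_experiment(
    n_seeds: int = 25, base_seed: int = 0,
    sim_config: SimulationConfig | None = None,
) -> list[float]:
    """ARI of control-vs-group2 post-sample clustering across seeds."""
    aris = []
    for k in range(n_seeds):
        sc = sim_config or SimulationConfig()
        sc = SimulationConfig(**{**sc.__dict__, "seed": base_seed + k})
        design, _, mfi, _, _ = simulate_cohort(sc)
        rmfi = markers_mod.process_mfi(mfi, design)
        l2fc = markers_mod.marker_log2fc(rmfi, design)
        meta = design.to_frame().set_index("sample_id")
        post = meta.loc[design.select(phase="post")]
        post = post[post["group"].isin(["control", "group2"])]
        res = markers_mod.cluster_separation(
            l2fc[post.index.tolist()], post["group"], k=2
        )
        aris.append(res.ari)
    return aris


def particle_recovery(seed: int = 0) -> dict[str, float]:
    """Generator/normalizer round trip for the particle-concentration effect."""
    sc = SimulationConfig(seed=seed)
    design, _, _, particles, truth = simulate_cohort(sc)
    table = norm_mod.normalize_particle_table(particles, design)
    base = table[table["phase"] == "baseline"]
    window = table[
        table["time_point"].isin(truth.particle_effect_window)
        & table["group"].isin(["group1", "group2"])
    ]
    return {
        "baseline_mean": float(base["particles_per_g_crea"].mean()),
        "window_fold": float(
            window["particles_per_g_crea"].mean()
            / base["particles_per_g_crea"].mean()
        ),
    }
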