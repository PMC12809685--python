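"""End-to-end orchestration: simulate -> normalize -> dge -> detect -> markers.

One configuration drives the whole chain and every stage writes its
declared output files, so a single call reproduces the full analysis on a
synthetic cohort (or, stage by stage, on user-supplied tables).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import detect as detect_mod
from . import dge as dge_mod
from . import markers as markers_mod
from . import normalize as norm_mod
from .config import PipelineConfig
from .design import StudyDesign, validate_against_design
from .io import (
    MFIMatrix,
    write_count_table,
    write_marker_table,
    write_metadata,
    write_particle_table,
)
from .simulate import SimulationConfig, Truth, simulate_cohort

log = logging.getLogger("uevabt")


@dataclass
class PipelineResult:
    design: StudyDesign
    counts: pd.DataFrame
    size_factors: pd.Series
    normalized: pd.DataFrame
    outliers: list[str]
    dge_results: pd.DataFrame
    funnel: dge_mod.FunnelReport
    flags: pd.DataFrame
    confusion: dict[str, dict]
    particles_normalized: pd.DataFrame
    rmfi: pd.DataFrame
    marker_frequency: pd.Series
    marker_log2fc: pd.DataFrame
    cluster: markers_mod.ClusterResult | None
    marker_anova: pd.DataFrame
    truth: Truth | None = None


def write_simulated(outdir: Path, design, counts, mfi: MFIMatrix, particles, truth):
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_table(counts, outdir / "counts.tsv")
    write_metadata(design, outdir / "metadata.tsv")
    write_marker_table(mfi, outdir / "markers.csv")
    write_particle_table(particles, outdir / "particles.csv")
    truth.to_json(outdir / "truth.json")


def run_pipeline(
    sim_config: SimulationConfig | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    detect_mirnas: list[str] | None = None,
) -> PipelineResult:
    """Run the whole analysis on a simulated cohort and optionally write all
    stage outputs under `outdir`.

    `detect_mirnas` restricts the static model to given miRNAs; by default
    it runs on the funnel's headline set (falling back to the candidate set,
    then to the three most abundant miRNAs).
    """
    sim_config = sim_config or SimulationConfig()
    config = config or PipelineConfig()
    outdir = Path(outdir) if outdir is not None else None

    design, counts, mfi, particles, truth = simulate_cohort(sim_config)
    log.info("simulated %d samples, %d miRNAs", len(design.samples), len(counts))
    if outdir:
        write_simulated(outdir / "data", design, counts, mfi, particles, truth)

    report = validate_against_design(counts, design)
    if not report.ok:
        raise ValueError(f"counts/design mismatch: {report}")

    # normalization
    prevalent = dge_mod.prevalence_filter(counts, config.prevalence)
    size_factors = norm_mod.compute_size_factors(prevalent)
    normalized = norm_mod.normalize_counts(prevalent, size_factors)
    logmat = norm_mod.log_transform(normalized, config.pseudocount)
    outliers = norm_mod.screen_outliers(logmat, k=config.outlier_k)
    if outliers:
        log.info("outlier samples disregarded: %s", outliers)
        normalized = normalized.drop(columns=outliers)
    particles_norm = norm_mod.normalize_particle_table(particles, design)
    log.info("%d prevalent miRNAs, %d outliers", len(prevalent), len(outliers))

    # differential expression + funnel
    dge_results = dge_mod.run_contrasts(normalized, design, config)
    funnel = dge_mod.biomarker_funnel(dge_results, normalized, config)
    log.info(
        "regulated sets %s -> %d candidates, %d headline",
        funnel.set_sizes, len(funnel.candidates), len(funnel.headline),
    )

    # static model
    if detect_mirnas is None:
        detect_mirnas = funnel.headline or funnel.candidates
        if not detect_mirnas:
            detect_mirnas = list(
                normalized.mean(axis=1).sort_values(ascending=False).index[:3]
            )
    scoped = normalized.loc[[m for m in detect_mirnas if m in normalized.index]]
    baseline = detect_mod.fit_baseline(scoped, design, scope=config.baseline_scope)
    flags = detect_mod.flag_samples(
        scoped, baseline, design, z_thresholds=config.z_flags,
        t0_truth=config.t0_truth,
    )
    confusion = {
        thr: {m: cm.to_dict() for m, cm in
              detect_mod.evaluate_detection(flags, thr).items()}
        for thr in (95, 99.7)
    }

    # surface markers
    rmfi = markers_mod.process_mfi(
        mfi, design, isotype_before_background=config.isotype_before_background
    )
    frequency = markers_mod.detection_frequency(rmfi)
    mk_l2fc = markers_mod.marker_log2fc(rmfi, design)
    meta = design.to_frame().set_index("sample_id")
    post_ids = design.select(phase="post")
    compare = meta.loc[post_ids]
    compare = compare[compare["group"].isin(["control", "group2"])]
    cluster = None
    try:
        cluster = markers_mod.cluster_separation(
            mk_l2fc[compare.index.tolist()],
            compare["group"],
            k=2,
            method=config.linkage,
            min_shared_markers=config.min_shared_markers,
        )
        log.info("marker cluster separation ARI = %.3f", cluster.ari)
    except ValueError as exc:
        log.warning("marker clustering not possible: %s", exc)
    marker_anova = markers_mod.compare_markers_over_time(mk_l2fc, design)

    result = PipelineResult(
        design=design, counts=counts, size_factors=size_factors,
        normalized=normalized, outliers=outliers, dge_results=dge_results,
        funnel=funnel, flags=flags, confusion=confusion,
        particles_normalized=particles_norm, rmfi=rmfi,
        marker_frequency=frequency, marker_log2fc=mk_l2fc, cluster=cluster,
        marker_anova=marker_anova, truth=truth,
    )
    if outdir:
        _write_outputs(outdir, result)
    return result


def _write_outputs(outdir: Path, r: PipelineResult) -> None:
    norm_dir = outdir / "normalize"
    norm_dir.mkdir(parents=True, exist_ok=True)
    r.size_factors.to_csv(norm_dir / "size_factors.tsv", sep="\t")
    r.normalized.to_csv(norm_dir / "normalized.tsv", sep="\t")
    (norm_dir / "outliers.txt").write_text("\n".join(r.outliers) + "\n")
    r.particles_normalized.to_csv(norm_dir / "normalized_particles.csv")

    dge_dir = outdir / "dge"
    dge_dir.mkdir(exist_ok=True)
    r.dge_results.to_csv(dge_dir / "results.tsv", sep="\t", index=False)
    with open(dge_dir / "funnel.json", "w") as fh:
        json.dump(r.funnel.to_dict(), fh, indent=2)

    det_dir = outdir / "detect"
    det_dir.mkdir(exist_ok=True)
    r.flags.to_csv(det_dir / "flags.tsv", sep="\t", index=False)
    with open(det_dir / "confusion.json", "w") as fh:
        json.dump(r.confusion, fh, indent=2)
    grid = [x / 10.0 for x in range(0, 51, 2)]
    detect_mod.threshold_sweep(r.flags, grid).to_csv(
        det_dir / "sweep.tsv", sep="\t", index=False
    )

    mk_dir = outdir / "markers"
    mk_dir.mkdir(exist_ok=True)
    r.rmfi.to_csv(mk_dir / "rmfi.csv")
    r.marker_frequency.rename("detection_pct").to_csv(mk_dir / "frequency.csv")
    r.marker_log2fc.to_csv(mk_dir / "log2fc.csv")
    with open(mk_dir / "clusters.json", "w") as fh:
        json.dump(r.cluster.to_dict() if r.cluster else {}, fh, indent=2)
    r.marker_anova.to_csv(mk_dir / "anova.tsv", sep="\t", index=False)
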