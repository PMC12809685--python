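#!/usr/bin/env python
"""Normalize the cohort: size factors, outlier screen, and creatinine-
normalized particle concentrations with the repeated-measures time-course
test.

Reads results/data/, writes results/normalize/.
"""

from pathlib import Path

import pandas as pd

from uevabt.dge import prevalence_filter
from uevabt.io import read_count_table, read_metadata, read_particle_table
from uevabt.normalize import (
    compute_size_factors,
    log_transform,
    normalize_counts,
    normalize_particle_table,
)
from uevabt.normalize import screen_outliers
from uevabt.stats import rm_anova_timepoints

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = read_metadata(ROOT / "data" / "metadata.tsv")
    counts = read_count_table(ROOT / "data" / "counts.tsv")
    prevalent = prevalence_filter(counts, 0.75)
    print(f"{len(prevalent)} of {len(counts)} miRNAs detected in >= 75% "
          "of samples")
    size = compute_size_factors(prevalent)
    normalized = normalize_counts(prevalent, size)
    outliers = screen_outliers(log_transform(normalized))
    print(f"outlier screen flagged: {outliers or 'none'}")

    out = ROOT / "normalize"
    out.mkdir(parents=True, exist_ok=True)
    size.to_csv(out / "size_factors.tsv", sep="\t")
    normalized.to_csv(out / "normalized.tsv", sep="\t")
    (out / "outliers.txt").write_text("\n".join(outliers) + "\n")

    particles = read_particle_table(ROOT / "data" / "particles.csv")
    table = normalize_particle_table(particles, design)
    table.to_csv(out / "normalized_particles.csv")
    base = table[table["phase"] == "baseline"]["particles_per_g_crea"]
    print(f"baseline particle concentration: {base.mean():.3g} particles/g "
          "U_Crea")
    # time course within group 2, subject x time point
    g2 = table[table["group"] == "group2"]
    wide = g2.pivot_table(index="subject_id", columns="time_point",
                          values="particles_per_g_crea", observed=False)
    res = rm_anova_timepoints(wide)
    print(f"group 2 particle time course: F({res.df_time},{res.df_error}) = "
          f"{res.f:.2f}, p = {res.p:.2g} over {res.n_subjects} complete "
          "subjects")
    sig = res.contrasts[res.contrasts["padj"] < 0.05]["time_point"].tolist()
    print(f"time points departing from baseline (BH < 0.05): {sig or 'none'}")
    res.contrasts.to_csv(out / "particle_contrasts.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
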