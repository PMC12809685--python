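#!/usr/bin/env python
"""Surface-marker pipeline: rMFI, detection frequency, baseline log2FC,
cluster separation of control vs group 2, and per-marker two-way ANOVA.

Reads results/data/, writes results/markers/.
"""

import json
from pathlib import Path

from uevabt.io import read_marker_table, read_metadata
from uevabt.markers import (
    cluster_separation,
    compare_markers_over_time,
    detection_frequency,
    marker_log2fc,
    process_mfi,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = read_metadata(ROOT / "data" / "metadata.tsv")
    mfi = read_marker_table(ROOT / "data" / "markers.csv")
    rmfi = process_mfi(mfi, design)
    freq = detection_frequency(rmfi)
    l2fc = marker_log2fc(rmfi, design)

    out = ROOT / "markers"
    out.mkdir(parents=True, exist_ok=True)
    rmfi.to_csv(out / "rmfi.csv")
    freq.rename("detection_pct").to_csv(out / "frequency.csv")
    l2fc.to_csv(out / "log2fc.csv")

    common = freq[freq > 50].sort_values(ascending=False)
    print(f"{len(common)} markers detected in > 50% of samples:")
    for m, f in common.items():
        print(f"  {m}: {f:.0f}% of samples, mean rMFI "
              f"{rmfi.loc[m].mean():.0f} per U_Crea")

    meta = design.to_frame().set_index("sample_id")
    post = meta.loc[design.select(phase="post")]
    post = post[post["group"].isin(["control", "group2"])]
    cluster = cluster_separation(l2fc[post.index.tolist()], post["group"], k=2)
    (out / "clusters.json").write_text(json.dumps(cluster.to_dict(), indent=2))
    print(f"control vs group 2 cluster separation: ARI = {cluster.ari:.3f} "
          f"({len(cluster.excluded)} samples excluded)")

    anova = compare_markers_over_time(l2fc, design)
    anova.to_csv(out / "anova.tsv", sep="\t", index=False)
    n_sig = int((anova["padj_group"] < 0.05).sum()) if len(anova) else 0
    print(f"two-way ANOVA over {len(anova)} analysable markers: "
          f"{n_sig} with BH-significant group effect")


if __name__ == "__main__":
    main()
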