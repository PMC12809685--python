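#!/usr/bin/env python
"""Per-time-point contrasts vs baseline and the biomarker funnel.

Reads results/normalize/, writes results/dge/, and scores the funnel
against the generator's planted truth.
"""

import json
from pathlib import Path

import pandas as pd

from uevabt.dge import biomarker_funnel, run_contrasts
from uevabt.io import read_metadata
from uevabt.simulate import Truth

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = read_metadata(ROOT / "data" / "metadata.tsv")
    normalized = pd.read_csv(ROOT / "normalize" / "normalized.tsv", sep="\t",
                             index_col=0)
    outliers = [
        s for s in (ROOT / "normalize" / "outliers.txt").read_text().split()
        if s
    ]
    if outliers:
        normalized = normalized.drop(columns=outliers)
        print(f"dropped outliers: {outliers}")
    results = run_contrasts(normalized, design)
    funnel = biomarker_funnel(results, normalized)
    out = ROOT / "dge"
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "results.tsv", sep="\t", index=False)
    (out / "funnel.json").write_text(json.dumps(funnel.to_dict(), indent=2))

    print(f"regulated miRNAs per group: {funnel.set_sizes}")
    print(f"treatment-shared minus control candidates: "
          f"{len(funnel.candidates)}")
    print(f"headline (mean normalized count > 20): {funnel.headline}")
    truth = Truth.from_json(ROOT / "data" / "truth.json")
    planted = set(truth.planted_mirnas)
    hits = planted & set(funnel.candidates)
    precision = len(hits) / len(funnel.candidates) if funnel.candidates else 1.0
    print(f"vs planted truth: recall {len(hits)}/{len(planted)}, "
          f"precision {precision:.2f}")


if __name__ == "__main__":
    main()
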