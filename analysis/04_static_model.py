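#!/usr/bin/env python
"""Longitudinal static-model detection on the funnel's headline miRNAs.

Reads results/dge/ and results/normalize/, writes results/detect/: per-
sample z-scores, flags at |z| > 2 and |z| > 3, per-miRNA confusion matrices
and the threshold sweep.
"""

import json
from pathlib import Path

import pandas as pd

from uevabt.detect import (
    evaluate_detection,
    fit_baseline,
    flag_samples,
    threshold_sweep,
)
from uevabt.io import read_metadata

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = read_metadata(ROOT / "data" / "metadata.tsv")
    normalized = pd.read_csv(ROOT / "normalize" / "normalized.tsv", sep="\t",
                             index_col=0)
    funnel = json.loads((ROOT / "dge" / "funnel.json").read_text())
    mirnas = funnel["headline"] or funnel["candidates"]
    print(f"static model over {len(mirnas)} miRNAs: {mirnas[:5]} ...")
    scoped = normalized.loc[mirnas]
    baseline = fit_baseline(scoped, design, scope="population")
    flags = flag_samples(scoped, baseline, design)

    out = ROOT / "detect"
    out.mkdir(parents=True, exist_ok=True)
    flags.to_csv(out / "flags.tsv", sep="\t", index=False)
    confusion = {}
    for thr in (95, 99.7):
        confusion[str(thr)] = {
            m: cm.to_dict() for m, cm in evaluate_detection(flags, thr).items()
        }
    (out / "confusion.json").write_text(json.dumps(confusion, indent=2))
    grid = [x / 10.0 for x in range(0, 51, 2)]
    threshold_sweep(flags, grid).to_csv(out / "sweep.tsv", sep="\t",
                                        index=False)
    for m, cm in list(confusion["95"].items())[:5]:
        print(f"  {m}: sensitivity {cm['sensitivity']:.2f}%, "
              f"specificity {cm['specificity']:.2f}% at |z| > 2")
    sens = [c["sensitivity"] for c in confusion["95"].values()]
    spec = [c["specificity"] for c in confusion["95"].values()]
    print(f"mean over miRNAs at |z| > 2: sensitivity "
          f"{sum(sens) / len(sens):.2f}%, specificity "
          f"{sum(spec) / len(spec):.2f}%")


if __name__ == "__main__":
    main()
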