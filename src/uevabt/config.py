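"""Pipeline configuration: the analysis thresholds and policy switches.

Defaults mirror the study's decision rules: |FC| > 1.5 with raw p < 0.05 for
per-contrast significance, detection in >= 75% of samples to enter the
differential analysis, mean normalized count > 20 for the headline set, and
static-model flag thresholds at |z| = 2 and |z| = 3.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # differential-expression funnel
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    prevalence: float = 0.75
    abundance: float = 20.0
    include_t0_contrast: bool = True
    #: a miRNA counts as "regulated in a group" when significant at this many
    #: contrast time points; with require_same_direction the significant
    #: contrasts must agree in sign
    min_sig_timepoints: int = 2
    require_same_direction: bool = True
    # static model
    z_flags: tuple[float, float] = (2.0, 3.0)
    baseline_scope: str = "population"  # or "per_subject"
    t0_truth: str = "clean"  # truth label policy for the t=0 visit
    log_scale_z: bool = False
    # normalization
    pseudocount: float = 1.0
    outlier_k: float = 5.0
    # markers
    linkage: str = "average"  # single / complete / average
    min_shared_markers: int = 3
    isotype_before_background: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.prevalence <= 1:
            if self.prevalence != 0:  # 0 = keep-all degenerate case
                raise ValueError("prevalence must lie in [0, 1]")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold is a fold change, must be >= 1")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must lie in (0, 1]")
        if self.baseline_scope not in ("population", "per_subject"):
            raise ValueError(f"unknown baseline scope {self.baseline_scope!r}")
        if self.linkage not in ("single", "complete", "average"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        self.z_flags = tuple(float(z) for z in self.z_flags)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["z_flags"] = list(self.z_flags)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
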