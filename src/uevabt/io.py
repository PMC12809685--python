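"""Table I/O: miRNA count matrix (TSV), sample metadata (TSV), surface-marker
median fluorescence (CSV) and particle measurements (CSV).

Counts and metadata are tab-separated with a header row and '.' decimal
separator; the instrument-style marker and particle tables are CSV.  All
readers validate and fail with row/column context rather than propagating
malformed values downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StudyDesign

ISOTYPE_CONTROLS: tuple[str, ...] = ("mIgG1", "REA Control")
BACKGROUND_COLUMN = "background"


# -- count matrix ----------------------------------------------------------

def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a miRNA x sample read-count table.

    Rows are miRNAs (first column holds the id), columns are samples.
    Entries must be non-negative integers; duplicated ids, ragged rows and
    negative or fractional entries are rejected with cell context.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    if df.index.has_duplicates:
        dup = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate miRNA ids {dup}")
    if df.columns.has_duplicates:
        dup = sorted(df.columns[df.columns.duplicated()].unique())
        raise ValueError(f"{path}: duplicate sample ids {dup}")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                x = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric count {raw!r} at "
                    f"(miRNA {df.index[i]!r}, sample {col!r})"
                ) from None
            if not np.isfinite(x) or x != int(x):
                raise ValueError(
                    f"{path}: non-integer count {raw!r} at "
                    f"(miRNA {df.index[i]!r}, sample {col!r})"
                )
            if x < 0:
                raise ValueError(
                    f"{path}: negative count {raw!r} at "
                    f"(miRNA {df.index[i]!r}, sample {col!r})"
                )
            values[i, j] = int(x)
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    out.index.name = "mirna_id"
    return out


def write_count_table(counts: pd.DataFrame, path: str | Path) -> None:
    counts = counts.copy()
    counts.index.name = "mirna_id"
    counts.to_csv(path, sep="\t", lineterminator="\n")


# -- metadata --------------------------------------------------------------

def read_metadata(path: str | Path) -> StudyDesign:
    """Read the sample-metadata TSV and return a validated StudyDesign."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return StudyDesign.from_frame(frame)


def write_metadata(design: StudyDesign, path: str | Path) -> None:
    df = design.to_frame().drop(columns=["phase"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# -- surface markers -------------------------------------------------------

@dataclass
class MFIMatrix:
    """Median fluorescence intensities for the 37-marker capture panel.

    `panel` holds raw per-sample MFIs (markers x samples, NaN = missing),
    `background` the buffer-only value per marker (panel and isotype rows),
    `isotype` the raw isotype-control MFIs per sample (one row per control
    bead population).
    """

    panel: pd.DataFrame
    background: pd.Series
    isotype: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.background < 0).any():
            raise ValueError("background values must be >= 0")
        overlap = set(self.panel.index) & set(self.isotype.index)
        if overlap:
            raise ValueError(f"markers listed as both panel and isotype: {overlap}")
        if list(self.panel.columns) != list(self.isotype.columns):
            raise ValueError("panel and isotype sample columns differ")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.panel.columns)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.panel.index)


def read_marker_table(
    path: str | Path, isotype_controls: tuple[str, ...] = ISOTYPE_CONTROLS
) -> MFIMatrix:
    """Read the marker CSV: rows = markers plus isotype-control rows, columns
    = samples plus one buffer-background column."""
    df = pd.read_csv(path, index_col=0)
    if BACKGROUND_COLUMN not in df.columns:
        raise ValueError(f"{path}: missing {BACKGROUND_COLUMN!r} column")
    background = df[BACKGROUND_COLUMN].astype(float)
    data = df.drop(columns=[BACKGROUND_COLUMN]).astype(float)
    iso_rows = [m for m in isotype_controls if m in data.index]
    if not iso_rows:
        raise ValueError(
            f"{path}: no isotype-control rows found (expected {isotype_controls})"
        )
    return MFIMatrix(
        panel=data.drop(index=iso_rows),
        background=background,
        isotype=data.loc[iso_rows],
    )


def write_marker_table(mfi: MFIMatrix, path: str | Path) -> None:
    df = pd.concat([mfi.panel, mfi.isotype])
    df[BACKGROUND_COLUMN] = mfi.background.reindex(df.index)
    df.index.name = "marker_id"
    df.to_csv(path, lineterminator="\n")


# -- particles -------------------------------------------------------------

PARTICLE_COLUMNS = (
    "sample_id", "measured_conc", "dilution", "eluate_volume_ml", "urine_input_ml"
)


def read_particle_table(path: str | Path) -> pd.DataFrame:
    """Read per-sample particle measurements (fNTA export style).

    measured_conc is particles/mL of the diluted, stained preparation;
    volumes are in mL; dilution is a dimensionless factor >= 1.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in PARTICLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in PARTICLE_COLUMNS[1:]:
        vals = df[col].astype(float)
        if not (vals > 0).all():
            bad = df.loc[~(vals > 0), "sample_id"].tolist()
            raise ValueError(f"{path}: non-positive {col} for samples {bad}")
        df[col] = vals
    if (df["dilution"] < 1).any():
        bad = df.loc[df["dilution"] < 1, "sample_id"].tolist()
        raise ValueError(f"{path}: dilution < 1 for samples {bad}")
    return df.set_index("sample_id")


def write_particle_table(particles: pd.DataFrame, path: str | Path) -> None:
    particles.to_csv(path, index_label="sample_id", lineterminator="\n")
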