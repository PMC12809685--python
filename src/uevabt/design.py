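"""Study design: samples, subjects, groups, time points and phases.

The study layout is three groups of ten subjects sampled at eleven time
points: three baseline visits in the weeks before blood donation (-9w, -8w,
-7w), the pre-transfusion visit (t0), and seven post-transfusion visits
(+3h ... +7d).  Missing visits are represented by absent rows, never by
sentinel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

TIME_POINTS: tuple[str, ...] = (
    "-9w", "-8w", "-7w", "t0", "+3h", "+6h", "+1d", "+2d", "+3d", "+4d", "+7d"
)
BASELINE_TIME_POINTS: tuple[str, ...] = ("-9w", "-8w", "-7w")
POST_TIME_POINTS: tuple[str, ...] = ("+3h", "+6h", "+1d", "+2d", "+3d", "+4d", "+7d")
#: contrast time points: everything after the baseline block (t0 included)
CONTRAST_TIME_POINTS: tuple[str, ...] = ("t0",) + POST_TIME_POINTS

GROUPS: tuple[str, ...] = ("control", "group1", "group2")
TREATMENT_GROUPS: tuple[str, ...] = ("group1", "group2")

_PHASE = {tp: "baseline" for tp in BASELINE_TIME_POINTS}
_PHASE["t0"] = "pre"
_PHASE.update({tp: "post" for tp in POST_TIME_POINTS})


def phase_of(time_point: str) -> str:
    """Map a time-point label to its phase (baseline / pre / post)."""
    try:
        return _PHASE[time_point]
    except KeyError:
        raise ValueError(
            f"unknown time point {time_point!r}; expected one of {TIME_POINTS}"
        ) from None


@dataclass(frozen=True)
class SampleRecord:
    """One urine sample: who, when, and how concentrated the urine was."""

    sample_id: str
    subject_id: str
    group: str
    time_point: str
    u_crea: float  # urinary creatinine, g/L

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} for {self.sample_id}")
        if self.time_point not in TIME_POINTS:
            raise ValueError(
                f"unknown time point {self.time_point!r} for {self.sample_id}"
            )
        if not self.u_crea > 0:
            raise ValueError(
                f"u_crea must be > 0, got {self.u_crea} for {self.sample_id}"
            )

    @property
    def phase(self) -> str:
        return phase_of(self.time_point)


class StudyDesign:
    """Validated collection of SampleRecords with grid bookkeeping.

    Invariants enforced: unique sample ids, (subject, time point) unique,
    every subject in exactly one group, u_crea > 0.
    """

    def __init__(self, samples: list[SampleRecord]):
        if not samples:
            raise ValueError("study design needs at least one sample")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dup}")
        seen_visits: set[tuple[str, str]] = set()
        subject_group: dict[str, str] = {}
        for s in samples:
            key = (s.subject_id, s.time_point)
            if key in seen_visits:
                raise ValueError(f"duplicate visit {key}")
            seen_visits.add(key)
            prev = subject_group.setdefault(s.subject_id, s.group)
            if prev != s.group:
                raise ValueError(
                    f"subject {s.subject_id} assigned to both {prev} and {s.group}"
                )
        self.samples = list(samples)
        self._subject_group = subject_group

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StudyDesign":
        required = ["sample_id", "subject_id", "group", "time_point", "u_crea"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        records = [
            SampleRecord(
                sample_id=str(r.sample_id),
                subject_id=str(r.subject_id),
                group=str(r.group),
                time_point=str(r.time_point),
                u_crea=float(r.u_crea),
            )
            for r in frame.itertuples(index=False)
        ]
        return cls(records)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "subject_id": [s.subject_id for s in self.samples],
                "group": [s.group for s in self.samples],
                "time_point": pd.Categorical(
                    [s.time_point for s in self.samples],
                    categories=list(TIME_POINTS),
                    ordered=True,
                ),
                "u_crea": [s.u_crea for s in self.samples],
            }
        )
        df["phase"] = [s.phase for s in self.samples]
        return df

    # -- queries -----------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def subjects(self) -> list[str]:
        return sorted(self._subject_group)

    @property
    def groups_present(self) -> set[str]:
        return set(self._subject_group.values())

    def group_of(self, subject_id: str) -> str:
        return self._subject_group[subject_id]

    def u_crea_series(self) -> pd.Series:
        return pd.Series(
            {s.sample_id: s.u_crea for s in self.samples}, name="u_crea"
        )

    def select(
        self,
        group: str | None = None,
        phase: str | None = None,
        time_point: str | None = None,
        subject_id: str | None = None,
    ) -> list[str]:
        """Sample ids matching all given filters."""
        out = []
        for s in self.samples:
            if group is not None and s.group != group:
                continue
            if phase is not None and s.phase != phase:
                continue
            if time_point is not None and s.time_point != time_point:
                continue
            if subject_id is not None and s.subject_id != subject_id:
                continue
            out.append(s.sample_id)
        return out

    def expected_grid_size(self) -> int:
        return len(self.subjects) * len(TIME_POINTS)

    def missing_visits(self) -> list[tuple[str, str]]:
        present = {(s.subject_id, s.time_point) for s in self.samples}
        return [
            (subj, tp)
            for subj in self.subjects
            for tp in TIME_POINTS
            if (subj, tp) not in present
        ]


@dataclass
class ValidationReport:
    """Sample-id reconciliation between a count matrix and a design."""

    counts_only: list[str] = field(default_factory=list)
    design_only: list[str] = field(default_factory=list)
    missing_visits: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        """True when the two id sets coincide (missing visits are allowed)."""
        return not self.counts_only and not self.design_only


def validate_against_design(
    counts: pd.DataFrame, design: StudyDesign
) -> ValidationReport:
    """Report-only reconciliation of count-matrix columns vs design rows."""
    count_ids = set(map(str, counts.columns))
    design_ids = set(design.sample_ids)
    return ValidationReport(
        counts_only=sorted(count_ids - design_ids),
        design_only=sorted(design_ids - count_ids),
        missing_visits=design.missing_visits(),
    )
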