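"""Caries index components and the CPO / ceo indexes.

Per person, four tallies are taken over the examined dentition: *x*
decayed teeth, *y* filled/crowned teeth, *z* teeth lost to caries, and
*w* teeth with extraction indicated.  For the permanent dentition the
individual index is

    CPO_i = x + y + z + w

and for the deciduous dentition

    ceo_i = x + y + w        (z, exfoliated/extracted primaries, excluded)

The population index is the arithmetic mean over the N examined persons.
A per-person percentage variant (value * 100 / N) is exposed as printed
in the source forms; the conventional prevalence statistic (fraction of
persons with index > 0) is provided separately.

The crown-code -> component mapping follows the WHO Basic Methods
convention and lives in one editable table (``CROWN_COMPONENT``), so an
alternate convention is a configuration change, not a code change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .model import (
    DECIDUOUS_TEETH,
    Dentition,
    Exam,
    Odontogram,
    PERMANENT_TEETH,
    School,
    Student,
    SurveyValidationError,
    ToothRecord,
    age_at,
    dentition_of,
)

Component = Literal["decayed", "filled", "missing", "none"]

#: Crown code -> index component, per dentition.  Decayed = caries +
#: restored-with-caries; filled = restored-without-caries; missing =
#: lost-because-of-caries.  Non-caries loss, sealants, bridges, trauma,
#: unerupted and not-considered codes contribute to no component.
CROWN_COMPONENT: dict[Dentition, dict[str, Component]] = {
    "permanent": {"1": "decayed", "2": "decayed", "3": "filled", "4": "missing"},
    "deciduous": {"B": "decayed", "C": "decayed", "D": "filled", "E": "missing"},
}

#: Treatment code that marks a tooth for extraction (the w component).
EXTRACTION_INDICATED_TREATMENT = "6"

GroupBy = Literal["school", "territory", "municipality", "sex", "age"]


@dataclass(frozen=True)
class ComponentCount:
    """The x/y/z/w tallies for one mouth (or summed over a group)."""

    x: int = 0  # decayed
    y: int = 0  # filled / crowned
    z: int = 0  # missing (lost because of caries)
    w: int = 0  # extraction indicated
    dentition: Dentition = "permanent"

    def __post_init__(self) -> None:
        if min(self.x, self.y, self.z, self.w) < 0:
            raise SurveyValidationError("component counts must be >= 0")

    def __add__(self, other: "ComponentCount") -> "ComponentCount":
        if other.dentition != self.dentition:
            raise SurveyValidationError("cannot add counts across dentitions")
        return ComponentCount(
            self.x + other.x,
            self.y + other.y,
            self.z + other.z,
            self.w + other.w,
            self.dentition,
        )


def classify_tooth(record: ToothRecord) -> tuple[Component, bool]:
    """Map one tooth record to its index component.

    Returns ``(component, extraction_indicated)``: the crown code decides
    the x/y/z component; independently, treatment code '6' marks the
    tooth as extraction-indicated (the w component), reported alongside.
    """
    mapping = CROWN_COMPONENT[record.dentition]
    component: Component = mapping.get(record.crown, "none")
    return component, record.treatment == EXTRACTION_INDICATED_TREATMENT


def count_components(
    odontogram: Odontogram, dentition: Dentition = "permanent"
) -> ComponentCount:
    """Tally index components over the teeth of one dentition.

    Each tooth contributes to at most one of x/y/z and at most once to
    w.  Teeth of the other dentition in a mixed mouth are ignored.
    """
    x = y = z = w = 0
    for rec in odontogram.records.values():
        if rec.dentition != dentition:
            continue
        component, extraction = classify_tooth(rec)
        if component == "decayed":
            x += 1
        elif component == "filled":
            y += 1
        elif component == "missing":
            z += 1
        if extraction:
            w += 1
    return ComponentCount(x, y, z, w, dentition)


def cpo_individual(c: ComponentCount) -> int:
    """Individual permanent-dentition index: CPO_i = x + y + z + w."""
    if c.dentition != "permanent":
        raise SurveyValidationError(
            "CPO is defined on permanent-dentition counts; got deciduous"
        )
    return c.x + c.y + c.z + c.w


def ceo_individual(c: ComponentCount) -> int:
    """Individual deciduous-dentition index: ceo_i = x + y + w.

    The z component (primary teeth lost to caries) is excluded — primary
    tooth loss is confounded with natural exfoliation.
    """
    if c.dentition != "deciduous":
        raise SurveyValidationError(
            "ceo is defined on deciduous-dentition counts; got permanent"
        )
    return c.x + c.y + c.w


def mean_index(values: Sequence[float]) -> float:
    """Arithmetic mean of individual index values over N examined persons."""
    if len(values) == 0:
        raise SurveyValidationError("no examined persons: mean index undefined")
    return float(sum(values)) / len(values)


def index_percent(value_i: float, n_persons: int) -> float:
    """Per-person percentage variant of the index: value_i * 100 / N.

    Evaluated literally as printed on the survey forms; its meaning as a
    population statistic is debatable — for the share of persons
    affected use :func:`prevalence` instead.
    """
    if n_persons <= 0:
        raise SurveyValidationError("N must be positive")
    return value_i * 100.0 / n_persons


def prevalence(values: Sequence[float]) -> float:
    """Fraction of persons with a positive index (caries experience)."""
    if len(values) == 0:
        raise SurveyValidationError("no examined persons: prevalence undefined")
    return sum(1 for v in values if v > 0) / len(values)


@dataclass
class IndexSummary:
    """Per-group index results: components, per-person values and summaries."""

    n: int
    per_person: list[int]
    mean: float
    prevalence: float
    components: ComponentCount
    percent: list[float] = field(default_factory=list)
    group_key: Optional[tuple[str, str]] = None  # (grouping name, value)

    @classmethod
    def from_counts(
        cls,
        counts: Sequence[ComponentCount],
        group_key: Optional[tuple[str, str]] = None,
        dentition: Dentition = "permanent",
    ) -> "IndexSummary":
        individual = cpo_individual if dentition == "permanent" else ceo_individual
        values = [individual(c) for c in counts]
        total = ComponentCount(dentition=dentition)
        for c in counts:
            total = total + c
        n = len(values)
        return cls(
            n=n,
            per_person=values,
            mean=mean_index(values),
            prevalence=prevalence(values),
            components=total,
            percent=[index_percent(v, n) for v in values],
            group_key=group_key,
        )


def exam_index_table(
    exams: Sequence[Exam],
    students: Sequence[Student],
    schools: Sequence[School],
    dentition: Dentition = "permanent",
) -> pd.DataFrame:
    """One row per exam with its components, index value and grouping keys.

    Raises when an exam's student or the student's school cannot be
    resolved, listing the orphan secret codes.
    """
    student_by_code = {s.secret_code: s for s in students}
    school_by_id = {s.id: s for s in schools}
    orphan_students = sorted(
        {e.secret_code for e in exams} - set(student_by_code)
    )
    if orphan_students:
        raise SurveyValidationError(
            f"exams reference unknown student secret codes: {orphan_students}"
        )
    orphan_schools = sorted(
        {student_by_code[e.secret_code].school_ref for e in exams}
        - set(school_by_id)
    )
    if orphan_schools:
        raise SurveyValidationError(
            f"students reference unknown schools: {orphan_schools}"
        )
    individual = cpo_individual if dentition == "permanent" else ceo_individual
    rows = []
    for exam in exams:
        student = student_by_code[exam.secret_code]
        school = school_by_id[student.school_ref]
        c = count_components(exam.odontogram, dentition)
        rows.append(
            {
                "secret_code": exam.secret_code,
                "school": school.id,
                "territory": school.territory or "",
                "municipality": "all",
                "sex": student.sex,
                "age": age_at(student.birth_date, exam.date),
                "x": c.x,
                "y": c.y,
                "z": c.z,
                "w": c.w,
                "value": individual(c),
            }
        )
    return pd.DataFrame(rows)


def aggregate(
    exams: Sequence[Exam],
    students: Sequence[Student],
    schools: Sequence[School],
    group_by: GroupBy = "school",
    dentition: Dentition = "permanent",
) -> list[IndexSummary]:
    """Index summaries per group value of a grouping key.

    Each exam is counted in exactly one group, so group sizes partition
    the exam set and the overall mean is the size-weighted mean of the
    group means.
    """
    table = exam_index_table(exams, students, schools, dentition)
    if table.empty:
        raise SurveyValidationError("no exams to aggregate")
    summaries = []
    for value, sub in table.groupby(group_by, sort=True):
        counts = [
            ComponentCount(r.x, r.y, r.z, r.w, dentition)
            for r in sub.itertuples()
        ]
        summaries.append(
            IndexSummary.from_counts(
                counts, group_key=(group_by, str(value)), dentition=dentition
            )
        )
    return summaries


def summaries_to_frame(summaries: Iterable[IndexSummary]) -> pd.DataFrame:
    """Flatten summaries to one row per group (key, N, x, y, z, w, mean,
    prevalence) for CSV export."""
    rows = []
    for s in summaries:
        name, value = s.group_key if s.group_key else ("all", "all")
        rows.append(
            {
                "group_by": name,
                "group": value,
                "N": s.n,
                "x": s.components.x,
                "y": s.components.y,
                "z": s.components.z,
                "w": s.components.w,
                "mean": s.mean,
                "prevalence": s.prevalence,
            }
        )
    return pd.DataFrame(rows)


def write_summaries(
    summaries: Iterable[IndexSummary], path: str | Path, fmt: str = "csv"
) -> None:
    """Write aggregation results as CSV or JSON."""
    frame = summaries_to_frame(summaries)
    path = Path(path)
    if fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(
            json.dumps(frame.to_dict(orient="records"), indent=2) + "\n",
            encoding="utf-8",
        )
    else:
        raise SurveyValidationError(f"unknown summary format: {fmt!r}")
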