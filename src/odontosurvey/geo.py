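"""Territory assignment and the survey's report surfaces.

Schools are related to the *health territories* of the municipality —
the catchment areas of the health units that serve their students.
Assignment is either explicit (a school -> territory table, as shipped
with the enrollment fixture) or geometric (point-in-polygon over a
GeoJSON FeatureCollection of territory polygons, explicit entries
taking precedence).

Three report surfaces are produced: the three-level caries index report
(school / territory / municipality means), the per-school participation
report (questionnaires and exams as percentages of enrollment — the two
legitimately differ, since the exam day and the questionnaire day need
not coincide), and the desk summary of store-wide counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from shapely.geometry import Point, shape

from .indices import Dentition, IndexSummary, aggregate
from .model import Exam, School, Student, SurveyValidationError
from .sync import CentralStore

#: Default health-territory labels (one municipality's eight territories).
DEFAULT_TERRITORIES: tuple[str, ...] = (
    "Apinajé",
    "Javaé",
    "Kanela",
    "Karajá",
    "Krahô",
    "Xambioá",
    "Xerente",
    "Pankararu",
)

#: Spelling variants seen in the field map onto one canonical label.
TERRITORY_ALIASES: dict[str, str] = {
    "Khraô": "Krahô",
}


def canonical_territory(label: str) -> str:
    """Resolve spelling variants to the canonical territory label."""
    return TERRITORY_ALIASES.get(label, label)


@dataclass
class TerritoryMap:
    """School -> territory resolution: explicit table and/or polygons."""

    mapping: dict[str, str] = field(default_factory=dict)  # school_id -> label
    polygons: list[tuple[str, object]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mapping = {
            k: canonical_territory(v) for k, v in self.mapping.items()
        }
        for label, poly in self.polygons:
            if not label:
                raise SurveyValidationError("territory label must be non-empty")
            if not poly.is_valid:
                raise SurveyValidationError(
                    f"territory {label!r}: polygon is invalid "
                    "(self-intersecting or unclosed)"
                )

    @classmethod
    def from_geojson(cls, path: str | Path,
                     mapping: Optional[Mapping[str, str]] = None
                     ) -> "TerritoryMap":
        """Load territory polygons from a GeoJSON FeatureCollection whose
        features carry a ``territory`` property."""
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        if doc.get("type") != "FeatureCollection":
            raise SurveyValidationError(
                f"{path}: expected a GeoJSON FeatureCollection"
            )
        polygons = []
        for feat in doc.get("features", []):
            label = feat.get("properties", {}).get("territory")
            if not label:
                raise SurveyValidationError(
                    f"{path}: feature without a 'territory' property"
                )
            polygons.append(
                (canonical_territory(label), shape(feat["geometry"]))
            )
        return cls(mapping=dict(mapping or {}), polygons=polygons)


def assign_territory(school: School, tmap: TerritoryMap) -> str:
    """Territory of a school: explicit table first, then point-in-polygon.

    Boundary points go to the first-listed containing territory.  A
    school covered by neither route raises, naming the school.
    """
    if school.id in tmap.mapping:
        return tmap.mapping[school.id]
    if school.territory:
        return canonical_territory(school.territory)
    if school.latitude is not None and school.longitude is not None:
        point = Point(school.longitude, school.latitude)
        for label, poly in tmap.polygons:
            if poly.covers(point):  # covers: interior OR boundary
                return label
    raise SurveyValidationError(
        f"school {school.id} ({school.name!r}) cannot be assigned to a "
        "territory: not in the explicit mapping and in no polygon"
    )


@dataclass
class TerritoryIndexReport:
    """Three-level caries index report: school, territory, municipality."""

    by_school: list[IndexSummary]
    by_territory: list[IndexSummary]
    municipal: IndexSummary


def territory_index_report(
    exams: Sequence[Exam],
    students: Sequence[Student],
    schools: Sequence[School],
    tmap: Optional[TerritoryMap] = None,
    dentition: Dentition = "permanent",
) -> TerritoryIndexReport:
    """Caries index means at school, territory and municipal level.

    Each exam is counted exactly once per level, so the municipal mean
    equals the exam-count-weighted mean of the territory means.
    """
    if tmap is not None:
        schools = [
            s.model_copy(update={"territory": assign_territory(s, tmap)})
            for s in schools
        ]
    else:
        for s in schools:
            if not s.territory:
                raise SurveyValidationError(
                    f"school {s.id} has no territory and no territory map "
                    "was given"
                )
    by_school = aggregate(exams, students, schools, "school", dentition)
    by_territory = aggregate(exams, students, schools, "territory", dentition)
    municipal = aggregate(exams, students, schools, "municipality", dentition)
    return TerritoryIndexReport(by_school, by_territory, municipal[0])


@dataclass(frozen=True)
class ParticipationRow:
    """Per-school participation: questionnaires and exams vs enrollment."""

    school_id: str
    enrolled: int
    questionnaires: int
    exams: int
    pct_questionnaire: Optional[float]
    pct_exam: Optional[float]
    flags: tuple[str, ...] = ()


def participation_report(
    schools: Sequence[School],
    questionnaire_counts: Mapping[str, int],
    exam_counts: Mapping[str, int],
    enrollment_field: str = "enrollment_grade9",
) -> list[ParticipationRow]:
    """One participation row per school.

    Percentages are 100 * count / enrolled.  Zero-enrollment schools are
    kept with undefined (None) percentages and a flag; counts exceeding
    enrollment (possible with transfers) raise a data-quality flag, not
    an error.
    """
    rows = []
    for school in schools:
        enrolled = getattr(school, enrollment_field)
        q = int(questionnaire_counts.get(school.id, 0))
        e = int(exam_counts.get(school.id, 0))
        flags: list[str] = []
        if enrolled > 0:
            pq: Optional[float] = 100.0 * q / enrolled
            pe: Optional[float] = 100.0 * e / enrolled
            if q > enrolled or e > enrolled:
                flags.append("count_exceeds_enrollment")
        else:
            pq = pe = None
            flags.append("zero_enrollment")
        rows.append(
            ParticipationRow(
                school.id, enrolled, q, e, pq, pe, tuple(flags)
            )
        )
    return rows


@dataclass(frozen=True)
class DeskSummary:
    """Store-wide counts shown on the campaign desk."""

    campaigns: int
    schools_visited: int
    students_registered: int
    questionnaires_answered: int
    exams_performed: int


def desk_summary(store: CentralStore) -> DeskSummary:
    """Compute desk counts by full scan of the central store (read-only)."""
    counts = store.counts()
    return DeskSummary(
        campaigns=counts.get("campaign", 0),
        schools_visited=counts.get("school", 0),
        students_registered=counts.get("student", 0),
        questionnaires_answered=counts.get("response", 0),
        exams_performed=counts.get("exam", 0),
    )


def plot_territory_means(
    report: TerritoryIndexReport, path: str | Path, title: str = "Mean CPO-D by health territory"
) -> None:
    """Static bar chart of territory means with the municipal mean as a
    reference line (a local stand-in for an interactive choropleth)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [s.group_key[1] for s in report.by_territory]
    means = [s.mean for s in report.by_territory]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(labels, means, color="#4c72b0")
    ax.axhline(
        report.municipal.mean,
        color="#c44e52",
        linestyle="--",
        label=f"municipal mean = {report.municipal.mean:.2f}",
    )
    ax.set_ylabel("mean index")
    ax.set_title(title)
    ax.legend()
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
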