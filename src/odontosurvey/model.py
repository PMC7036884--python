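"""Domain types and validation for oral-health survey entities.

The data universe mirrors a WHO-style school caries survey: a *campaign*
(e.g. a state-wide inquiry) groups *actions* (municipal survey rounds),
which visit *schools*; *students* are registered anonymously under a
secret code and contribute a *questionnaire response* and a dental
*exam*.  The exam payload is an odontogram: for every tooth of the
examined dentition, a crown-condition code plus a treatment-need code.

Tooth positions use FDI two-digit notation (quadrant digit 1-4 for the
permanent dentition, 5-8 for the deciduous one).  Crown codes come from
two parallel alphabets, one per dentition; treatment codes are shared.
Null entries are banned: a normalized odontogram carries an explicit
healthy record for every unexamined tooth.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

SCHEMA_VERSION = "1.0"

Dentition = Literal["permanent", "deciduous"]

#: FDI codes for the 32 permanent teeth (quadrants 1-4, positions 1-8).
PERMANENT_TEETH: tuple[int, ...] = tuple(
    10 * q + p for q in (1, 2, 3, 4) for p in range(1, 9)
)
#: FDI codes for the 20 deciduous teeth (quadrants 5-8, positions 1-5).
DECIDUOUS_TEETH: tuple[int, ...] = tuple(
    10 * q + p for q in (5, 6, 7, 8) for p in range(1, 6)
)

#: 28-tooth permanent set (third molars excluded) for analyses that drop them.
PERMANENT_TEETH_28: tuple[int, ...] = tuple(
    t for t in PERMANENT_TEETH if t % 10 != 8
)

#: Crown alphabets in their conventional printed order, which doubles as the
#: severity ordering used for calibration tie-breaks.
PERMANENT_CROWN_CODES: tuple[str, ...] = (
    "0", "1", "2", "3", "4", "5", "6", "7", "8", "T", "9",
)
DECIDUOUS_CROWN_CODES: tuple[str, ...] = (
    "A", "B", "C", "D", "E", "F", "G", "H", "K", "T", "L",
)
TREATMENT_CODES: tuple[str, ...] = tuple(str(d) for d in range(10))

#: Treatment code meaning "no information" — legal, but flagged on validation.
TREATMENT_NO_INFORMATION = "9"

HEALTHY_CROWN: dict[str, str] = {"permanent": "0", "deciduous": "A"}
HEALTHY_TREATMENT = "0"


class SurveyValidationError(ValueError):
    """A survey entity violates a structural invariant."""


def dentition_of(tooth: int) -> Dentition:
    """Classify an FDI tooth code as permanent or deciduous.

    Quadrants 1-4 are permanent (positions 1-8), quadrants 5-8 are
    deciduous (positions 1-5); anything else is rejected.
    """
    if tooth in _PERMANENT_SET:
        return "permanent"
    if tooth in _DECIDUOUS_SET:
        return "deciduous"
    raise SurveyValidationError(f"unknown FDI tooth code: {tooth!r}")


_PERMANENT_SET = frozenset(PERMANENT_TEETH)
_DECIDUOUS_SET = frozenset(DECIDUOUS_TEETH)


def crown_alphabet(dentition: Dentition) -> tuple[str, ...]:
    """The crown-code alphabet of a dentition."""
    if dentition == "permanent":
        return PERMANENT_CROWN_CODES
    if dentition == "deciduous":
        return DECIDUOUS_CROWN_CODES
    raise SurveyValidationError(f"unknown dentition: {dentition!r}")


# ---------------------------------------------------------------------------
# Validation reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    """One problem found while validating an entity."""

    level: Literal["error", "warning"]
    code: str
    message: str


@dataclass
class ValidationReport:
    """Structured validation outcome: problems are reported, not raised.

    Field batches with sporadic errors can then be partially merged,
    quarantining only the offending records.
    """

    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.level == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.level == "warning"]

    @property
    def ok(self) -> bool:
        """True when there are no errors (warnings allowed)."""
        return not self.errors

    def error(self, code: str, message: str) -> None:
        self.issues.append(ValidationIssue("error", code, message))

    def warning(self, code: str, message: str) -> None:
        self.issues.append(ValidationIssue("warning", code, message))


# ---------------------------------------------------------------------------
# Odontogram
# ---------------------------------------------------------------------------

class ToothRecord(BaseModel):
    """Crown-condition and treatment-need codes for one tooth.

    Letter codes are parsed case-insensitively and canonicalized to
    upper case.  The crown code must belong to the alphabet of the
    tooth's own dentition.
    """

    model_config = ConfigDict(frozen=True)

    tooth: int
    crown: str
    treatment: str = HEALTHY_TREATMENT

    @field_validator("crown", "treatment", mode="before")
    @classmethod
    def _canonicalize(cls, v: object) -> object:
        if isinstance(v, str):
            return v.strip().upper()
        return v

    @model_validator(mode="after")
    def _check_codes(self) -> "ToothRecord":
        dentition = dentition_of(self.tooth)  # raises on unknown tooth
        alphabet = crown_alphabet(dentition)
        if self.crown not in alphabet:
            raise SurveyValidationError(
                f"crown code {self.crown!r} is not valid for {dentition} "
                f"tooth {self.tooth} (alphabet: {''.join(alphabet)})"
            )
        if self.treatment not in TREATMENT_CODES:
            raise SurveyValidationError(
                f"treatment code {self.treatment!r} is not valid for tooth "
                f"{self.tooth} (alphabet: 0-9)"
            )
        return self

    @property
    def dentition(self) -> Dentition:
        return dentition_of(self.tooth)

    @property
    def is_healthy_default(self) -> bool:
        return (
            self.crown == HEALTHY_CROWN[self.dentition]
            and self.treatment == HEALTHY_TREATMENT
        )


class Odontogram(BaseModel):
    """Per-tooth chart of one examined mouth.

    ``teeth`` is the dentition set the exam covers (default: the 32
    permanent teeth); ``records`` maps tooth code to its
    :class:`ToothRecord`.  Mixed dentitions are allowed — each tooth is
    validated against its own alphabet.  Use :func:`normalize_odontogram`
    to fill unexamined teeth with the healthy default; completeness is
    checked by :func:`validate_exam`, not at construction, so partially
    captured field data can still be loaded and reported on.
    """

    teeth: tuple[int, ...] = PERMANENT_TEETH
    records: dict[int, ToothRecord] = {}

    @field_validator("teeth")
    @classmethod
    def _known_teeth(cls, v: tuple[int, ...]) -> tuple[int, ...]:
        for t in v:
            dentition_of(t)
        if len(set(v)) != len(v):
            raise SurveyValidationError("duplicate tooth in dentition set")
        return v

    @model_validator(mode="after")
    def _records_match_keys(self) -> "Odontogram":
        for tooth, rec in self.records.items():
            if rec.tooth != tooth:
                raise SurveyValidationError(
                    f"odontogram key {tooth} does not match record tooth "
                    f"{rec.tooth}"
                )
        return self

    @property
    def is_complete(self) -> bool:
        return set(self.records) == set(self.teeth)

    def to_codes(self) -> dict[int, tuple[str, str]]:
        """Plain ``{tooth: (crown, treatment)}`` view."""
        return {t: (r.crown, r.treatment) for t, r in self.records.items()}


def normalize_odontogram(
    partial: Mapping[int, tuple[str, str]] | Odontogram,
    teeth: Sequence[int] = PERMANENT_TEETH,
) -> Odontogram:
    """Complete a partial odontogram over a dentition set.

    Every tooth in ``teeth`` receives a record: provided entries are kept
    verbatim, unset teeth get the healthy default ('0' crown for
    permanent, 'A' for deciduous, treatment '0').  Idempotent.

    Raises :class:`SurveyValidationError` for codes from the wrong
    dentition alphabet or entries outside the dentition set.
    """
    provided: Mapping[int, tuple[str, str]]
    if isinstance(partial, Odontogram):
        provided = partial.to_codes()
    else:
        provided = partial
    tooth_set = set(teeth)
    records: dict[int, ToothRecord] = {}
    for tooth, (crown, treatment) in provided.items():
        if tooth not in tooth_set:
            raise SurveyValidationError(
                f"tooth {tooth} is outside the examined dentition set"
            )
        records[tooth] = ToothRecord(tooth=tooth, crown=crown, treatment=treatment)
    for tooth in tooth_set - set(records):
        records[tooth] = ToothRecord(
            tooth=tooth,
            crown=HEALTHY_CROWN[dentition_of(tooth)],
            treatment=HEALTHY_TREATMENT,
        )
    return Odontogram(teeth=tuple(sorted(tooth_set)), records=records)


# ---------------------------------------------------------------------------
# Survey entities
# ---------------------------------------------------------------------------

class Student(BaseModel):
    """Anonymized student registration: no name or direct identifier is
    ever stored — the secret code is the only key."""

    secret_code: str
    birth_date: _dt.date
    sex: str
    race: str
    school_ref: str
    class_label: str = ""

    @field_validator("secret_code")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise SurveyValidationError("secret_code must be non-empty")
        return v


class School(BaseModel):
    """A school unit, geolocated so it can be related to health territories."""

    id: str
    name: str
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    territory: Optional[str] = None
    enrollment_total: int = 0
    enrollment_grade9: int = 0

    @model_validator(mode="after")
    def _check(self) -> "School":
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise SurveyValidationError(
                f"latitude {self.latitude} out of range for school {self.id}"
            )
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise SurveyValidationError(
                f"longitude {self.longitude} out of range for school {self.id}"
            )
        if self.enrollment_total < 0 or self.enrollment_grade9 < 0:
            raise SurveyValidationError(
                f"negative enrollment for school {self.id}"
            )
        return self


class Campaign(BaseModel):
    """A broad survey effort, e.g. a state-wide annual inquiry."""

    id: str
    name: str
    period_start: _dt.date
    period_end: _dt.date

    @model_validator(mode="after")
    def _ordered(self) -> "Campaign":
        if self.period_end < self.period_start:
            raise SurveyValidationError(f"campaign {self.id}: period reversed")
        return self


class Action(BaseModel):
    """A localized survey round within a campaign, visiting a set of schools."""

    id: str
    name: str
    campaign_id: str
    date_start: _dt.date
    date_end: _dt.date
    school_ids: list[str] = []

    @model_validator(mode="after")
    def _ordered(self) -> "Action":
        if self.date_end < self.date_start:
            raise SurveyValidationError(f"action {self.id}: date range reversed")
        return self


class QuestionnaireClass(BaseModel):
    """One thematic block of the questionnaire: an inclusive question range."""

    label: str
    first: int
    last: int

    @model_validator(mode="after")
    def _ordered(self) -> "QuestionnaireClass":
        if not self.label:
            raise SurveyValidationError("questionnaire class label empty")
        if self.first < 1 or self.last < self.first:
            raise SurveyValidationError(
                f"bad question range {self.first}-{self.last} "
                f"for class {self.label!r}"
            )
        return self

    @property
    def n_items(self) -> int:
        return self.last - self.first + 1


class QuestionnaireDef(BaseModel):
    """Ordered questionnaire structure: contiguous, non-overlapping classes
    starting at question 1."""

    name: str
    classes: list[QuestionnaireClass]

    @model_validator(mode="after")
    def _contiguous(self) -> "QuestionnaireDef":
        if not self.classes:
            raise SurveyValidationError("questionnaire has no classes")
        expected = 1
        for c in self.classes:
            if c.first != expected:
                raise SurveyValidationError(
                    f"questionnaire {self.name!r}: class {c.label!r} starts at "
                    f"{c.first}, expected {expected} (ranges must be "
                    f"contiguous from 1)"
                )
            expected = c.last + 1
        return self

    @property
    def n_items(self) -> int:
        return self.classes[-1].last

    def class_of(self, question: int) -> Optional[QuestionnaireClass]:
        for c in self.classes:
            if c.first <= question <= c.last:
                return c
        return None


class QuestionnaireResponse(BaseModel):
    """One student's coded answers, keyed by question number."""

    secret_code: str
    date: _dt.date
    answers: dict[int, str] = {}


class Exam(BaseModel):
    """One oral examination: odontogram plus the two-surgeon team that
    produced it (an examiner and an annotator)."""

    secret_code: str
    date: _dt.date
    odontogram: Odontogram
    examiner_id: str
    annotator_id: str


# ---------------------------------------------------------------------------
# Validation operations
# ---------------------------------------------------------------------------

def validate_exam(exam: Exam, action: Action | None = None) -> ValidationReport:
    """Validate an exam against the odontogram invariants.

    Errors: missing per-tooth entries (the null-value ban) and records
    outside the declared dentition set.  Warnings: treatment code '9'
    (no information) and an exam date outside its action's date range.
    """
    report = ValidationReport()
    declared = set(exam.odontogram.teeth)
    present = set(exam.odontogram.records)
    for tooth in sorted(declared - present):
        report.error(
            "missing_tooth",
            f"no record for tooth {tooth}: null entries are not allowed, "
            "normalize the odontogram first",
        )
    for tooth in sorted(present - declared):
        report.error(
            "unexpected_tooth",
            f"record for tooth {tooth} outside the declared dentition set",
        )
    for tooth in sorted(present):
        rec = exam.odontogram.records[tooth]
        if rec.treatment == TREATMENT_NO_INFORMATION:
            report.warning(
                "treatment_no_information",
                f"tooth {tooth}: treatment code 9 (no information)",
            )
    if action is not None and not (
        action.date_start <= exam.date <= action.date_end
    ):
        report.warning(
            "date_outside_action",
            f"exam date {exam.date.isoformat()} outside action "
            f"{action.id} range "
            f"{action.date_start.isoformat()}..{action.date_end.isoformat()}",
        )
    return report


def age_at(birth_date: _dt.date, reference_date: _dt.date) -> int:
    """Completed years of age at a reference date."""
    if birth_date > reference_date:
        raise SurveyValidationError(
            f"birth date {birth_date.isoformat()} is after reference date "
            f"{reference_date.isoformat()}"
        )
    years = reference_date.year - birth_date.year
    if (reference_date.month, reference_date.day) < (
        birth_date.month,
        birth_date.day,
    ):
        years -= 1
    return years


def validate_response(
    resp: QuestionnaireResponse,
    qdef: QuestionnaireDef,
    mandatory: Iterable[int] = (),
) -> ValidationReport:
    """Validate a questionnaire response against its definition.

    Answers to undefined question numbers are errors; questions in the
    (configurable, default empty) mandatory set that are unanswered are
    errors too.  An empty response is valid under the default config.
    """
    report = ValidationReport()
    for q in sorted(resp.answers):
        if qdef.class_of(q) is None:
            report.error(
                "undefined_question",
                f"answer to question {q}, but {qdef.name!r} defines "
                f"questions 1-{qdef.n_items}",
            )
    for q in sorted(set(mandatory)):
        if q not in resp.answers:
            report.error(
                "missing_mandatory", f"mandatory question {q} unanswered"
            )
    return report
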