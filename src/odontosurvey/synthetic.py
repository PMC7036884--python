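"""Seedable synthetic surveys with known ground-truth parameters.

The generator emulates a municipal school caries survey so the whole
pipeline (capture -> batch -> merge -> index -> report) can be exercised
offline with closed-form expectations.  Per tooth, the crown state is
drawn independently from a multinomial over (healthy, decayed, filled,
missing); among decayed teeth, extraction is indicated with a separate
probability.  Per-tooth independence keeps the index expectation in
closed form:

    E[CPO_i] = T * (p_d + p_f + p_m) + T * p_d * p_ei

for a T-tooth dentition (the last term is the w component, counted on
top of x by the printed index formula).  Real caries data cluster
within mouths; the generator deliberately does not model that, so
passing tests certify the arithmetic, not field realism.

Defaults mirror the surveyed population: the 26 municipal schools of
the bundled enrollment fixture with their real health territories and
9th-grade cohort sizes, adolescent ages 13-19, and caries state
probabilities chosen so the simulated municipal mean index sits near
2.4 — the neighbourhood reported for 12-year-olds in the municipality's
last national-survey figure.
"""

from __future__ import annotations

import datetime as _dt
import uuid
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import io_formats
from .model import (
    Action,
    Campaign,
    Exam,
    Odontogram,
    PERMANENT_TEETH,
    QuestionnaireResponse,
    School,
    Student,
    SurveyValidationError,
    ToothRecord,
    dentition_of,
)
from .sync import LocalBatch, SecretCodeGenerator, make_record, open_batch

#: Crown codes per state, by dentition.
_STATE_CROWN = {
    "permanent": {"healthy": "0", "decayed": "1", "filled": "3", "missing": "4"},
    "deciduous": {"healthy": "A", "decayed": "B", "filled": "D", "missing": "E"},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a synthetic survey.

    ``students_per_school`` may be a fixed count, an inclusive range, or
    ``None`` to use each school's real 9th-grade enrollment from the
    bundled fixture.  The per-tooth state probabilities must sum to at
    most 1 (the remainder is healthy).
    """

    n_schools: Optional[int] = None  # None: all fixture schools
    students_per_school: int | tuple[int, int] | None = None
    p_decayed: float = 0.055
    p_filled: float = 0.015
    p_missing: float = 0.005
    p_extraction_indicated: float = 0.0  # among decayed teeth
    examiner_error_rate: float = 0.05
    p_exam: float = 0.95  # exam-day attendance
    p_questionnaire: float = 0.90  # questionnaire-day attendance
    age_min: int = 13
    age_max: int = 19
    n_questions: int = 146
    answer_codes: tuple[str, ...] = ("1", "2", "3", "4", "5")
    teeth: tuple[int, ...] = PERMANENT_TEETH
    seed: int = 0

    def __post_init__(self) -> None:
        p_sum = self.p_decayed + self.p_filled + self.p_missing
        probs = (self.p_decayed, self.p_filled, self.p_missing,
                 self.p_extraction_indicated, self.p_exam,
                 self.p_questionnaire, self.examiner_error_rate)
        if any(not 0.0 <= p <= 1.0 for p in probs) or p_sum > 1.0:
            raise SurveyValidationError(
                "state probabilities must lie in [0, 1] and "
                "p_decayed + p_filled + p_missing must not exceed 1"
            )
        if self.age_min > self.age_max:
            raise SurveyValidationError("age range reversed")

    @property
    def p_healthy(self) -> float:
        return 1.0 - (self.p_decayed + self.p_filled + self.p_missing)


def expected_mean_index(config: SimulationConfig) -> float:
    """Closed-form expectation of the individual index under the model."""
    t = len(config.teeth)
    return t * (
        config.p_decayed + config.p_filled + config.p_missing
        + config.p_decayed * config.p_extraction_indicated
    )


@dataclass
class SimulatedSurvey:
    """A complete synthetic survey, both as entities and as sealed,
    mergeable local batches (one batch per school team)."""

    config: SimulationConfig
    campaign: Campaign
    action: Action
    schools: list[School]
    students: list[Student]
    exams: list[Exam]
    responses: list[QuestionnaireResponse]
    batches: list[LocalBatch] = field(default_factory=list)


def _draw_odontogram(rng: np.random.Generator,
                     config: SimulationConfig) -> Odontogram:
    probs = [config.p_healthy, config.p_decayed, config.p_filled,
             config.p_missing]
    states = rng.choice(4, size=len(config.teeth), p=probs)
    records = {}
    for tooth, state in zip(config.teeth, states):
        state_name = ("healthy", "decayed", "filled", "missing")[state]
        crown = _STATE_CROWN[dentition_of(tooth)][state_name]
        treatment = "0"
        if state_name == "decayed" and (
            rng.random() < config.p_extraction_indicated
        ):
            treatment = "6"
        records[tooth] = ToothRecord(tooth=tooth, crown=crown,
                                     treatment=treatment)
    return Odontogram(teeth=config.teeth, records=records)


def _uid(rng: np.random.Generator) -> str:
    """Deterministic uuid from the simulation stream."""
    return str(uuid.UUID(bytes=rng.bytes(16), version=4))


def simulate_survey(config: SimulationConfig | None = None) -> SimulatedSurvey:
    """Generate a full synthetic survey under a fixed seed.

    Every generated record passes domain validation, and identical
    seeds produce identical output byte-for-byte.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    codegen = SecretCodeGenerator(seed=int(rng.integers(2**31)))

    fixture_schools = io_formats.load_school_enrollment()
    if config.n_schools is not None:
        if not 1 <= config.n_schools <= len(fixture_schools):
            raise SurveyValidationError(
                f"n_schools must be in 1..{len(fixture_schools)}"
            )
        fixture_schools = fixture_schools[: config.n_schools]
    # plant schools on a small synthetic coordinate grid (one cell per
    # territory) so geometric territory assignment is exercisable
    territories = sorted({s.territory for s in fixture_schools})
    schools = []
    for i, s in enumerate(fixture_schools):
        cell = territories.index(s.territory)
        schools.append(
            s.model_copy(
                update={
                    "longitude": float(cell) + 0.3 + 0.4 * rng.random(),
                    "latitude": -10.0 + 0.3 + 0.4 * rng.random(),
                }
            )
        )

    campaign = Campaign(
        id="C1",
        name="Municipal caries survey",
        period_start=_dt.date(2018, 4, 1),
        period_end=_dt.date(2019, 11, 30),
    )
    action = Action(
        id="A1",
        name="9th-grade school round",
        campaign_id=campaign.id,
        date_start=_dt.date(2018, 9, 1),
        date_end=_dt.date(2019, 6, 30),
        school_ids=[s.id for s in schools],
    )
    action_days = (action.date_end - action.date_start).days

    students: list[Student] = []
    exams: list[Exam] = []
    responses: list[QuestionnaireResponse] = []
    batches: list[LocalBatch] = []

    admin = open_batch(
        "registry", batch_id=_uid(rng), created_at="2018-08-01T08:00:00+00:00"
    )
    admin.append(make_record("campaign", campaign, record_uid=_uid(rng),
                             created_at="2018-08-01T08:00:00+00:00"))
    admin.append(make_record("action", action, record_uid=_uid(rng),
                             created_at="2018-08-01T08:01:00+00:00"))
    for school in schools:
        admin.append(
            make_record("school", school, record_uid=_uid(rng),
                        created_at="2018-08-01T08:02:00+00:00")
        )
    batches.append(admin.seal())

    for school in schools:
        if config.students_per_school is None:
            n_students = school.enrollment_grade9
        elif isinstance(config.students_per_school, int):
            n_students = config.students_per_school
        else:
            lo, hi = config.students_per_school
            n_students = int(rng.integers(lo, hi + 1))
        visit_date = action.date_start + _dt.timedelta(
            days=int(rng.integers(0, action_days + 1))
        )
        batch = open_batch(
            f"tablet-{school.id}",
            batch_id=_uid(rng),
            created_at=f"{visit_date.isoformat()}T07:30:00+00:00",
        )
        for _ in range(n_students):
            age = int(rng.integers(config.age_min, config.age_max + 1))
            birth = visit_date - _dt.timedelta(
                days=age * 365 + int(rng.integers(0, 365))
            )
            student = Student(
                secret_code=codegen.issue(),
                birth_date=birth,
                sex=("F", "M")[int(rng.integers(0, 2))],
                race=str(int(rng.integers(1, 6))),
                school_ref=school.id,
                class_label="9A",
            )
            students.append(student)
            stamp = f"{visit_date.isoformat()}T{8 + int(rng.integers(0, 8)):02d}:{int(rng.integers(0, 60)):02d}:00+00:00"
            batch.append(make_record("student", student,
                                     record_uid=_uid(rng), created_at=stamp))
            if rng.random() < config.p_exam:
                exam = Exam(
                    secret_code=student.secret_code,
                    date=visit_date,
                    odontogram=_draw_odontogram(rng, config),
                    examiner_id=f"E{1 + int(rng.integers(0, 16))}",
                    annotator_id=f"N{1 + int(rng.integers(0, 16))}",
                )
                exams.append(exam)
                batch.append(make_record("exam", exam, record_uid=_uid(rng),
                                         created_at=stamp))
            if rng.random() < config.p_questionnaire:
                answers = {
                    q: config.answer_codes[
                        int(rng.integers(0, len(config.answer_codes)))
                    ]
                    for q in range(1, config.n_questions + 1)
                }
                response = QuestionnaireResponse(
                    secret_code=student.secret_code,
                    date=visit_date,
                    answers=answers,
                )
                responses.append(response)
                batch.append(
                    make_record("response", response, record_uid=_uid(rng),
                                created_at=stamp)
                )
        batches.append(batch.seal())

    return SimulatedSurvey(
        config=config,
        campaign=campaign,
        action=action,
        schools=schools,
        students=students,
        exams=exams,
        responses=responses,
        batches=batches,
    )


def simulate_examiner_ratings(
    true_ratings: Sequence[str],
    error_rate: float,
    categories: Sequence[str],
    seed: int = 0,
) -> list[str]:
    """Perturb consensus ratings into one examiner's ratings.

    Each rating is independently replaced by a uniformly chosen
    *different* category with probability ``error_rate``.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise SurveyValidationError("error_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for rating in true_ratings:
        if rng.random() < error_rate:
            others = [c for c in categories if c != rating]
            out.append(others[int(rng.integers(0, len(others)))])
        else:
            out.append(rating)
    return out


def with_prevalence(
    config: SimulationConfig, p_decayed: float
) -> SimulationConfig:
    """Convenience: the same config with a different decay probability."""
    return replace(config, p_decayed=p_decayed)
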