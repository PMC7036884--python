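"""Index component classification and CPO / ceo arithmetic.

The classification oracle used throughout is an independent brute-force
per-code counter built from a hand-checked (dentition, crown) ->
component table, kept deliberately separate from the implementation's
mapping."""

import numpy as np
import pytest

from conftest import random_odontogram
from odontosurvey.indices import (
    ComponentCount,
    IndexSummary,
    aggregate,
    ceo_individual,
    classify_tooth,
    count_components,
    cpo_individual,
    index_percent,
    mean_index,
    prevalence,
    summaries_to_frame,
)
from odontosurvey.model import (
    DECIDUOUS_TEETH,
    PERMANENT_TEETH,
    SurveyValidationError,
    ToothRecord,
    dentition_of,
    normalize_odontogram,
)

# Independent oracle: hand-enumerated component table per crown code.
ORACLE_COMPONENT = {
    "permanent": {"0": None, "1": "x", "2": "x", "3": "y", "4": "z",
                  "5": None, "6": None, "7": None, "8": None, "T": None,
                  "9": None},
    "deciduous": {"A": None, "B": "x", "C": "x", "D": "y", "E": "z",
                  "F": None, "G": None, "H": None, "K": None, "T": None,
                  "L": None},
}


def oracle_counts(odontogram, dentition):
    """Brute-force per-code counter, independent of count_components."""
    x = y = z = w = 0
    for rec in odontogram.records.values():
        if dentition_of(rec.tooth) != dentition:
            continue
        bucket = ORACLE_COMPONENT[dentition][rec.crown]
        x += bucket == "x"
        y += bucket == "y"
        z += bucket == "z"
        w += rec.treatment == "6"
    return (x, y, z, w)


class TestClassifyTooth:
    @pytest.mark.parametrize(
        "tooth,crown,expected",
        [(11, "1", "decayed"), (11, "2", "decayed"), (11, "3", "filled"),
         (11, "4", "missing"), (11, "0", "none"), (11, "5", "none"),
         (11, "7", "none"), (11, "T", "none"), (11, "9", "none"),
         (55, "B", "decayed"), (55, "C", "decayed"), (55, "D", "filled"),
         (55, "E", "missing"), (55, "A", "none"), (55, "F", "none"),
         (55, "L", "none")],
    )
    def test_crown_component_mapping(self, tooth, crown, expected):
        component, _ = classify_tooth(ToothRecord(tooth=tooth, crown=crown))
        assert component == expected

    def test_extraction_indicated_reported_alongside_crown_component(self):
        component, extraction = classify_tooth(
            ToothRecord(tooth=11, crown="1", treatment="6"))
        assert component == "decayed" and extraction

    def test_full_alphabet_agrees_with_oracle(self):
        for tooth, alphabet in ((11, "0123456789T"), (55, "ABCDEFGHKTL")):
            dentition = dentition_of(tooth)
            for crown in alphabet:
                for treatment in "0123456789":
                    rec = ToothRecord(tooth=tooth, crown=crown,
                                      treatment=treatment)
                    component, extraction = classify_tooth(rec)
                    bucket = ORACLE_COMPONENT[dentition][rec.crown]
                    expected = {"x": "decayed", "y": "filled",
                                "z": "missing", None: "none"}[bucket]
                    assert component == expected
                    assert extraction == (treatment == "6")


class TestCountComponents:
    def test_all_healthy_is_zero(self):
        odo = normalize_odontogram({})
        c = count_components(odo)
        assert (c.x, c.y, c.z, c.w) == (0, 0, 0, 0)

    def test_manual_mixed_case(self):
        odo = normalize_odontogram(
            {11: ("1", "0"), 12: ("2", "0"), 21: ("3", "0"), 36: ("4", "0")})
        c = count_components(odo)
        assert (c.x, c.y, c.z, c.w) == (2, 1, 1, 0)

    def test_extraction_indicated_counted_once(self):
        odo = normalize_odontogram({46: ("1", "6")})
        c = count_components(odo)
        assert (c.x, c.y, c.z, c.w) == (1, 0, 0, 1)

    def test_oracle_equivalence_on_random_odontograms(self, rng):
        for _ in range(200):
            odo = random_odontogram(rng)
            c = count_components(odo, "permanent")
            assert (c.x, c.y, c.z, c.w) == oracle_counts(odo, "permanent")

    def test_mixed_dentition_counted_separately(self, rng):
        teeth = PERMANENT_TEETH[:16] + DECIDUOUS_TEETH[:10]
        odo = random_odontogram(rng, teeth)
        for dentition in ("permanent", "deciduous"):
            c = count_components(odo, dentition)
            assert (c.x, c.y, c.z, c.w) == oracle_counts(odo, dentition)


class TestIndividualIndexes:
    def test_cpo_sums_all_four_components(self):
        assert cpo_individual(ComponentCount(0, 0, 0, 0)) == 0
        assert cpo_individual(ComponentCount(2, 1, 1, 0)) == 4
        assert cpo_individual(ComponentCount(2, 1, 0, 1)) == 4

    def test_ceo_excludes_z(self):
        assert ceo_individual(ComponentCount(0, 0, 0, 0, "deciduous")) == 0
        assert ceo_individual(ComponentCount(2, 1, 1, 0, "deciduous")) == 3
        assert ceo_individual(ComponentCount(1, 1, 5, 1, "deciduous")) == 3

    def test_dentition_mismatch_rejected(self):
        with pytest.raises(SurveyValidationError):
            cpo_individual(ComponentCount(1, 0, 0, 0, "deciduous"))
        with pytest.raises(SurveyValidationError):
            ceo_individual(ComponentCount(1, 0, 0, 0, "permanent"))

    def test_cpo_monotone_in_added_decay(self, rng):
        # flipping one healthy tooth to decayed raises CPO by exactly 1
        for _ in range(20):
            odo = random_odontogram(rng)
            healthy = [t for t, r in odo.records.items() if r.crown == "0"
                       and r.treatment != "6"]
            if not healthy:
                continue
            before = cpo_individual(count_components(odo))
            tooth = healthy[0]
            mutated = dict(odo.to_codes())
            mutated[tooth] = ("1", mutated[tooth][1])
            after = cpo_individual(
                count_components(normalize_odontogram(mutated)))
            assert after == before + 1

    def test_index_bounds(self, rng):
        # w can double-count decayed teeth marked for extraction, so the
        # ceiling is teeth + decayed, never more than 2x the dentition
        for _ in range(50):
            v = cpo_individual(count_components(random_odontogram(rng)))
            assert 0 <= v <= 2 * 32
            odo = random_odontogram(rng, DECIDUOUS_TEETH)
            v = ceo_individual(count_components(odo, "deciduous"))
            assert 0 <= v <= 2 * 20


class TestSummaryStatistics:
    def test_mean_index(self):
        assert mean_index([0, 2, 4]) == 2.0
        assert mean_index([5]) == 5.0
        with pytest.raises(SurveyValidationError, match="no examined"):
            mean_index([])

    def test_index_percent_literal_formula(self):
        assert index_percent(2, 100) == 2.0
        assert index_percent(0, 50) == 0.0
        assert index_percent(4, 4) == 100.0
        with pytest.raises(SurveyValidationError):
            index_percent(1, 0)

    def test_prevalence(self):
        assert prevalence([0, 0, 0]) == 0.0
        assert prevalence([0, 1, 3, 0]) == 0.5
        assert prevalence([1, 2, 3]) == 1.0
        with pytest.raises(SurveyValidationError):
            prevalence([])


class TestAggregate:
    def test_partition_by_school(self, small_survey):
        s = small_survey
        summaries = aggregate(s.exams, s.students, s.schools, "school")
        assert sum(g.n for g in summaries) == len(s.exams)
        assert len(summaries) == len({st.school_ref for st in s.students})

    def test_single_group_equals_overall_mean(self, small_survey):
        s = small_survey
        municipal = aggregate(s.exams, s.students, s.schools, "municipality")
        assert len(municipal) == 1
        values = [
            cpo_individual(count_components(e.odontogram)) for e in s.exams
        ]
        assert municipal[0].mean == pytest.approx(mean_index(values))

    @pytest.mark.parametrize("group_by",
                             ["school", "territory", "sex", "age"])
    def test_weighted_decomposition_identity(self, small_survey, group_by):
        s = small_survey
        groups = aggregate(s.exams, s.students, s.schools, group_by)
        overall = aggregate(s.exams, s.students, s.schools, "municipality")[0]
        weighted = sum(g.n * g.mean for g in groups) / sum(g.n for g in groups)
        assert weighted == pytest.approx(overall.mean, abs=1e-12)

    def test_orphan_exams_rejected_listing_codes(self, small_survey):
        s = small_survey
        with pytest.raises(SurveyValidationError, match=s.exams[0].secret_code):
            aggregate(s.exams, s.students[1:], s.schools, "school")

    def test_summary_invariants_and_frame(self, small_survey):
        s = small_survey
        summaries = aggregate(s.exams, s.students, s.schools, "school")
        for g in summaries:
            assert g.n == len(g.per_person) > 0
            assert g.mean == pytest.approx(sum(g.per_person) / g.n)
            assert g.components.x + g.components.y + g.components.z >= 0
        frame = summaries_to_frame(summaries)
        assert list(frame["N"]) == [g.n for g in summaries]
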