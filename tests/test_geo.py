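"""Territory assignment, index report levels and participation rows."""

import json

import pytest

from odontosurvey.geo import (
    DEFAULT_TERRITORIES,
    TerritoryMap,
    assign_territory,
    canonical_territory,
    desk_summary,
    participation_report,
    plot_territory_means,
    territory_index_report,
)
from odontosurvey.io_formats import school_territory_mapping
from odontosurvey.model import School, SurveyValidationError
from odontosurvey.sync import CentralStore
from odontosurvey.synthetic import SimulationConfig, simulate_survey

UNIT_SQUARE = {
    "type": "FeatureCollection",
    "features": [
        {
            "type": "Feature",
            "properties": {"territory": "A"},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]],
            },
        },
        {
            "type": "Feature",
            "properties": {"territory": "B"},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[[1, 0], [2, 0], [2, 1], [1, 1], [1, 0]]],
            },
        },
    ],
}


def _school(sid="X1", lat=None, lon=None, territory=None):
    return School(id=sid, name=f"school {sid}", latitude=lat, longitude=lon,
                  territory=territory)


@pytest.fixture()
def square_map(tmp_path):
    path = tmp_path / "territories.geojson"
    path.write_text(json.dumps(UNIT_SQUARE))
    return TerritoryMap.from_geojson(path)


class TestAssignTerritory:
    def test_explicit_fixture_mapping(self):
        tmap = TerritoryMap(mapping=school_territory_mapping())
        school = _school("S01")
        assert assign_territory(school, tmap) == "Krahô"

    def test_point_in_polygon(self, square_map):
        assert assign_territory(_school(lat=0.5, lon=0.5), square_map) == "A"
        assert assign_territory(_school(lat=0.5, lon=1.5), square_map) == "B"

    def test_boundary_point_goes_to_first_listed(self, square_map):
        # lon=1.0 lies on the shared edge of A and B
        assert assign_territory(_school(lat=0.5, lon=1.0), square_map) == "A"

    def test_explicit_mapping_takes_precedence(self, square_map):
        square_map.mapping["X1"] = "B"
        assert assign_territory(_school("X1", lat=0.5, lon=0.5),
                                square_map) == "B"

    def test_unassignable_school_error_names_school(self, square_map):
        with pytest.raises(SurveyValidationError, match="X9"):
            assign_territory(_school("X9", lat=5.0, lon=5.0), square_map)

    def test_spelling_alias_resolves(self):
        assert canonical_territory("Khraô") == "Krahô"
        assert canonical_territory("Krahô") == "Krahô"
        assert "Krahô" in DEFAULT_TERRITORIES

    def test_invalid_polygon_rejected(self):
        from shapely.geometry import Polygon
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(SurveyValidationError, match="invalid"):
            TerritoryMap(polygons=[("A", bowtie)])


class TestTerritoryIndexReport:
    def test_single_school_all_levels_equal(self):
        survey = simulate_survey(
            SimulationConfig(seed=3, n_schools=1, students_per_school=40))
        rep = territory_index_report(
            survey.exams, survey.students, survey.schools)
        assert len(rep.by_school) == len(rep.by_territory) == 1
        assert rep.by_school[0].mean == rep.by_territory[0].mean
        assert rep.by_territory[0].mean == rep.municipal.mean

    def test_municipal_mean_is_weighted_territory_mean(self, small_survey):
        s = small_survey
        rep = territory_index_report(s.exams, s.students, s.schools)
        weighted = sum(t.n * t.mean for t in rep.by_territory) / sum(
            t.n for t in rep.by_territory)
        assert rep.municipal.mean == pytest.approx(weighted, abs=1e-12)
        assert sum(t.n for t in rep.by_territory) == rep.municipal.n

    def test_simulated_prevalence_contrast_orders_territory_means(self):
        # schools S01/S15 are one territory, S02 another; give the first
        # a real caries load and the second none via two sub-surveys
        # per-tooth 0.011 gives person-level prevalence 1-(1-p)^32 ~ 0.3
        sick = simulate_survey(SimulationConfig(
            seed=21, n_schools=1, students_per_school=500,
            p_decayed=0.011, p_filled=0.0, p_missing=0.0))
        healthy = simulate_survey(SimulationConfig(
            seed=22, n_schools=2, students_per_school=500,
            p_decayed=0.0, p_filled=0.0, p_missing=0.0))
        # keep only the second school from the healthy run (disjoint ids)
        h_students = [st for st in healthy.students
                      if st.school_ref == "S02"]
        h_codes = {st.secret_code for st in h_students}
        h_exams = [e for e in healthy.exams if e.secret_code in h_codes]
        exams = sick.exams + h_exams
        students = sick.students + h_students
        schools = sick.schools + [s for s in healthy.schools
                                  if s.id == "S02"]
        rep = territory_index_report(exams, students, schools)
        means = {t.group_key[1]: t.mean for t in rep.by_territory}
        assert means["Krahô"] > means["Xambioá"]
        assert means["Xambioá"] == 0.0

    def test_missing_territory_without_map_rejected(self):
        survey = simulate_survey(
            SimulationConfig(seed=4, n_schools=1, students_per_school=5))
        bare = [s.model_copy(update={"territory": None})
                for s in survey.schools]
        with pytest.raises(SurveyValidationError, match="territory"):
            territory_index_report(survey.exams, survey.students, bare)

    def test_plot_written(self, small_survey, tmp_path):
        s = small_survey
        rep = territory_index_report(s.exams, s.students, s.schools)
        out = tmp_path / "territories.png"
        plot_territory_means(rep, out)
        assert out.stat().st_size > 0


class TestParticipationReport:
    def test_percentages(self):
        schools = [School(id="S1", name="a", enrollment_grade9=100),
                   School(id="S2", name="b", enrollment_grade9=70)]
        rows = participation_report(schools, {"S1": 90, "S2": 70},
                                    {"S1": 80, "S2": 60})
        by_id = {r.school_id: r for r in rows}
        assert by_id["S1"].pct_exam == pytest.approx(80.0)
        assert by_id["S1"].pct_questionnaire == pytest.approx(90.0)
        assert by_id["S2"].pct_questionnaire == pytest.approx(100.0)
        assert not by_id["S1"].flags

    def test_zero_enrollment_flagged_not_dropped(self):
        rows = participation_report(
            [School(id="S0", name="empty", enrollment_grade9=0)], {}, {})
        assert len(rows) == 1
        assert rows[0].pct_exam is None
        assert "zero_enrollment" in rows[0].flags

    def test_count_exceeding_enrollment_flagged(self):
        rows = participation_report(
            [School(id="S1", name="a", enrollment_grade9=10)],
            {"S1": 12}, {"S1": 5})
        assert "count_exceeds_enrollment" in rows[0].flags
        assert rows[0].pct_questionnaire == pytest.approx(120.0)

    def test_questionnaire_and_exam_counts_may_differ(self, small_survey):
        # exam day and questionnaire day need not coincide
        q = {}
        e = {}
        by_code = {st.secret_code: st.school_ref
                   for st in small_survey.students}
        for r in small_survey.responses:
            q[by_code[r.secret_code]] = q.get(by_code[r.secret_code], 0) + 1
        for x in small_survey.exams:
            e[by_code[x.secret_code]] = e.get(by_code[x.secret_code], 0) + 1
        rows = participation_report(small_survey.schools, q, e,
                                    enrollment_field="enrollment_grade9")
        assert any(r.questionnaires != r.exams for r in rows)


class TestDeskSummary:
    def test_empty_store_all_zero(self):
        summary = desk_summary(CentralStore())
        assert summary == type(summary)(0, 0, 0, 0, 0)

    def test_counts_match_survey(self, small_survey, small_store):
        summary = desk_summary(small_store)
        assert summary.campaigns == 1
        assert summary.schools_visited == len(small_survey.schools)
        assert summary.students_registered == len(small_survey.students)
        assert summary.questionnaires_answered == len(small_survey.responses)
        assert summary.exams_performed == len(small_survey.exams)

    def test_report_is_read_only(self, small_store):
        before = small_store.snapshot()
        desk_summary(small_store)
        assert small_store.snapshot() == before

    def test_merge_increments_exam_count_exactly(self, small_survey):
        store = CentralStore()
        store.merge_batch(small_survey.batches[0])
        before = desk_summary(store).exams_performed
        report = store.merge_batch(small_survey.batches[1])
        inserted_exams = sum(
            1 for r in small_survey.batches[1].records
            if r["kind"] == "exam")
        assert desk_summary(store).exams_performed == before + inserted_exams
        assert report.inserted == len(small_survey.batches[1].records)
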