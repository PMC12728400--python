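import math
from datetime import datetime, timezone

import pandas as pd
import pytest
from hypothesis import given, settings

from conftest import raw_profiles
from vaxcheck import errors
from vaxcheck.cohort_simulator import CohortSpec, generate_cohort
from vaxcheck.oracle import brute_force_evaluate
from vaxcheck.profile_model import validate_profile
from vaxcheck.recommendation_engine import (
    STATUS_CONTRAINDICATED,
    STATUS_RANK,
    STATUS_RECOMMENDED,
    STATUS_SEASONAL,
    find_centers,
    haversine_km,
    parse_report,
    recommend,
    render_report,
)

TS = datetime(2024, 3, 1, 12, 0, tzinfo=timezone.utc)


def _profile(**overrides):
    raw = {
        "disease": "psoriasis",
        "hand_involvement": False,
        "age_band": "18_59",
        "on_chronic_therapy": False,
        "conditions": [],
    }
    raw.update(overrides)
    return validate_profile(raw)


class TestRecommend:
    def test_age_65_untreated_gets_the_age_set(self, kb):
        report = recommend(_profile(age_band="65_plus"), kb, now=TS)
        by_id = {r.vaccine_id: r for r in report.recommendations}
        assert {"influenza", "pcv", "ppsv23", "hz", "dtpa"} <= set(by_id)
        for rec in by_id.values():
            assert {x.reason_category for x in rec.reasons} == {"age"}

    def test_suppressive_biologic_overlay(self, kb):
        """Live vaccines blocked during therapy; non-live carry the lead-time note."""
        profile = _profile(on_chronic_therapy=True, medication="adalimumab")
        report = recommend(profile, kb, now=TS)
        by_id = {r.vaccine_id: r for r in report.recommendations}
        assert by_id["mmr"].status == STATUS_CONTRAINDICATED
        assert by_id["varicella"].status == STATUS_CONTRAINDICATED
        assert by_id["influenza"].status == STATUS_SEASONAL
        assert by_id["influenza"].seasonality_note
        assert by_id["covid19"].seasonality_note
        for rec in by_id.values():
            if not kb.vaccine(rec.vaccine_id).is_live:
                assert "2 weeks before treatment initiation" in rec.timing_note

    def test_pregnancy_blocks_live_vaccines_without_therapy(self, kb, kb_doc):
        # force a live vaccine into the matched set via a condition rule
        kb_doc["rules"].append(
            {"rule_id": "preg_varicella_probe", "trigger": {"condition": "pregnancy"},
             "vaccine_id": "varicella", "reason_category": "comorbidity"}
        )
        from vaxcheck.knowledge_base import build_knowledge_base

        kb2 = build_knowledge_base(kb_doc)
        report = recommend(_profile(conditions=["pregnancy"]), kb2, now=TS)
        by_id = {r.vaccine_id: r for r in report.recommendations}
        assert by_id["varicella"].status == STATUS_CONTRAINDICATED
        assert by_id["dtpa"].status == STATUS_RECOMMENDED  # non-live unaffected

    def test_booster_note_on_dtpa(self, kb):
        report = recommend(_profile(age_band="65_plus"), kb, now=TS)
        dtpa = next(r for r in report.recommendations if r.vaccine_id == "dtpa")
        assert "every 10 years" in dtpa.booster_note

    def test_report_invariants_and_fixed_order(self, kb):
        profile = _profile(age_band="65_plus", conditions=["asplenia", "hiv_infection"])
        report = recommend(profile, kb, now=TS)
        ids = [r.vaccine_id for r in report.recommendations]
        assert len(ids) == len(set(ids))
        order = [kb.display_order(v) for v in ids]
        assert order == sorted(order)
        assert all(r.reasons for r in report.recommendations)
        assert report.disclaimer

    def test_reasons_merge_across_triggers(self, kb):
        profile = _profile(age_band="65_plus", conditions=["type2_diabetes"])
        report = recommend(profile, kb, now=TS)
        flu = next(r for r in report.recommendations if r.vaccine_id == "influenza")
        assert {x.reason_category for x in flu.reasons} == {"age", "comorbidity"}

    def test_empty_match_is_legal_output(self, kb, kb_doc):
        from vaxcheck.knowledge_base import build_knowledge_base

        # age rules only for 65_plus: an 18-59 untreated healthy patient with a
        # KB stripped of the all-ages rule yields an empty recommendation list
        kb_doc["rules"] = [r for r in kb_doc["rules"] if r["rule_id"] != "age_all_dtpa"]
        kb_doc["vaccines"] = [v for v in kb_doc["vaccines"] if v["vaccine_id"] != "dtpa"]
        kb_doc["rules"] = [r for r in kb_doc["rules"] if r["vaccine_id"] != "dtpa"]
        kb2 = build_knowledge_base(kb_doc)
        report = recommend(_profile(), kb2, now=TS)
        assert report.recommendations == ()
        md = render_report(report, "markdown")
        assert "Disclaimer" in md and report.other_vaccines_notice in md

    def test_determinism_byte_identical(self, kb):
        profile = _profile(age_band="65_plus", conditions=["msm"])
        a = render_report(recommend(profile, kb, now=TS), "markdown")
        b = render_report(recommend(profile, kb, now=TS), "markdown")
        assert a == b


class TestRendering:
    def test_json_round_trip_over_generated_cohort(self, kb):
        cohort = generate_cohort(CohortSpec(n_total=100, seed=11))
        for profile in cohort:
            report = recommend(profile, kb, now=TS)
            assert parse_report(render_report(report, "json")) == report

    def test_markdown_carries_echo_notes_and_disclaimer(self, kb):
        profile = _profile(on_chronic_therapy=True, medication="adalimumab")
        report = recommend(profile, kb, now=TS)
        md = render_report(report, "markdown")
        assert report.patient_echo in md
        assert md.count("Timing:") == sum(1 for r in report.recommendations
                                          if r.timing_note)
        assert report.disclaimer in md

    def test_unknown_format_rejected(self, kb):
        report = recommend(_profile(), kb, now=TS)
        with pytest.raises(errors.UnknownFormatError):
            render_report(report, "pdf")


class TestProperties:
    @settings(max_examples=60)
    @given(raw=raw_profiles())
    def test_live_vaccine_safety_invariant(self, kb, raw):
        """No live vaccine is unconditionally recommended under suppression
        or pregnancy."""
        from vaxcheck.recommendation_engine import effective_suppression

        profile = validate_profile(raw)
        report = recommend(profile, kb, now=TS)
        risky = (
            effective_suppression(profile, kb) == "suppressive"
            or "pregnancy" in profile.conditions
        )
        for rec in report.recommendations:
            if kb.vaccine(rec.vaccine_id).is_live and risky:
                assert rec.status not in (STATUS_RECOMMENDED, STATUS_SEASONAL)

    @settings(max_examples=60)
    @given(raw=raw_profiles())
    def test_oracle_equivalence(self, kb, raw):
        profile = validate_profile(raw)
        report = recommend(profile, kb, now=TS)
        expected = brute_force_evaluate(profile, kb)
        got = {
            r.vaccine_id: (
                r.status,
                frozenset((x.reason_category, x.description) for x in r.reasons),
            )
            for r in report.recommendations
        }
        assert got == {v: (e.status, e.reasons) for v, e in expected.items()}


class TestCenterFinder:
    @pytest.fixture()
    def registry(self):
        return pd.DataFrame(
            {
                "name": ["Alfa", "Bravo", "Charlie"],
                "address_text": ["Via A 1", "Via B 2", "Via C 3"],
                "lat": [44.41, 44.50, 44.41],
                "lon": [8.93, 8.93, 9.05],
            }
        )

    def test_query_on_a_center_is_first_at_zero_distance(self, registry):
        hits = find_centers(44.41, 8.93, registry, 10)
        assert hits[0].name == "Alfa"
        assert hits[0].distance_km == pytest.approx(0.0, abs=1e-9)

    def test_tenth_of_a_degree_on_the_equator(self):
        """0.1 deg of arc = 6371 * 0.1 * pi / 180 km, outside both radii."""
        registry = pd.DataFrame({"name": ["N"], "lat": [0.1], "lon": [0.0]})
        d = float(haversine_km(0.0, 0.0, 0.1, 0.0))
        assert d == pytest.approx(6371 * 0.1 * math.pi / 180, rel=1e-12)
        assert d == pytest.approx(11.12, abs=0.005)
        for radius in (5, 10):
            assert find_centers(0.0, 0.0, registry, radius) == []

    def test_equidistant_centers_break_ties_by_name(self):
        registry = pd.DataFrame(
            {"name": ["Zulu", "Alfa"], "lat": [0.0, 0.0], "lon": [0.01, -0.01]}
        )
        hits = find_centers(0.0, 0.0, registry, 5)
        assert [h.name for h in hits] == ["Alfa", "Zulu"]

    def test_radius_restricted_to_app_choices(self, registry):
        with pytest.raises(errors.InvalidRadiusError):
            find_centers(44.4, 8.9, registry, 7)

    def test_invalid_query_and_empty_registry(self, registry):
        with pytest.raises(errors.InvalidCoordinateError):
            find_centers(91.0, 0.0, registry, 5)
        with pytest.raises(errors.EmptyRegistryError):
            find_centers(0.0, 0.0, registry.iloc[0:0], 5)

    def test_results_sorted_ascending_within_radius(self, registry):
        hits = find_centers(44.41, 8.93, registry, 10)
        dists = [h.distance_km for h in hits]
        assert dists == sorted(dists)
        assert all(d <= 10 for d in dists)
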