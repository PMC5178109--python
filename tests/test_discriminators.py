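import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from clariped.discriminators import (
    Advisory,
    Encounter,
    default_catalog,
    evaluate_all,
    evaluate_complaints,
    evaluate_mandatory,
    max_discriminator_level,
)
from clariped.errors import IncompleteEncounterError, InvalidInputError
from clariped.levels import UrgencyLevel


def codes(triggered):
    return {t.code for t in triggered}


def levels_of(triggered):
    return {t.code: t.level for t in triggered}


class TestMandatory:
    def test_pain_strong(self, catalog):
        enc = Encounter(age_days=2000, pain_level=8, general_appearance="well")
        trig = levels_of(evaluate_mandatory(enc, catalog))
        assert trig["pain_strong"] is UrgencyLevel.ORANGE

    @pytest.mark.parametrize(
        "pain, code, level",
        [
            (7, "pain_strong", UrgencyLevel.ORANGE),
            (10, "pain_strong", UrgencyLevel.ORANGE),
            (4, "pain_moderate", UrgencyLevel.YELLOW),
            (6, "pain_moderate", UrgencyLevel.YELLOW),
            (1, "pain_mild", UrgencyLevel.GREEN),
            (3, "pain_mild", UrgencyLevel.GREEN),
        ],
    )
    def test_pain_bands(self, catalog, pain, code, level):
        enc = Encounter(age_days=2000, pain_level=pain, general_appearance="well")
        assert levels_of(evaluate_mandatory(enc, catalog))[code] is level

    def test_febrile_young_infant(self, catalog):
        enc = Encounter(
            age_days=20, pain_level=0, general_appearance="well", fever_report_max_c=38.6
        )
        trig = levels_of(evaluate_mandatory(enc, catalog))
        assert trig["fever_lt3mo_ge385"] is UrgencyLevel.ORANGE
        assert trig["newborn"] is UrgencyLevel.YELLOW

    def test_nothing_triggered(self, catalog):
        enc = Encounter(age_days=1826, pain_level=0, general_appearance="well")
        assert evaluate_mandatory(enc, catalog) == set()

    @pytest.mark.parametrize(
        "appearance, level",
        [
            ("critical", UrgencyLevel.RED),
            ("very_ill", UrgencyLevel.ORANGE),
            ("ill", UrgencyLevel.YELLOW),
            ("little_ill", UrgencyLevel.GREEN),
        ],
    )
    def test_appearance(self, catalog, appearance, level):
        enc = Encounter(age_days=2000, pain_level=0, general_appearance=appearance)
        assert level in {t.level for t in evaluate_mandatory(enc, catalog)}

    @pytest.mark.parametrize(
        "kwargs, code",
        [
            (dict(returns_24h=1), "return_1_in_24h"),
            (dict(returns_72h=2), "return_2_in_72h"),
            (dict(fever_report_max_c=39.5), "fever_any_ge395"),
        ],
    )
    def test_returns_and_fever(self, catalog, kwargs, code):
        enc = Encounter(age_days=2000, pain_level=0, general_appearance="well", **kwargs)
        assert code in codes(evaluate_mandatory(enc, catalog))

    def test_fever_under_three_years(self, catalog):
        enc = Encounter(
            age_days=800, pain_level=0, general_appearance="well", fever_report_max_c=38.7
        )
        assert "fever_lt3y_ge385" in codes(evaluate_mandatory(enc, catalog))
        older = Encounter(
            age_days=1200, pain_level=0, general_appearance="well", fever_report_max_c=38.7
        )
        assert "fever_lt3y_ge385" not in codes(evaluate_mandatory(older, catalog))

    @pytest.mark.parametrize("missing", ["pain_level", "general_appearance"])
    def test_missing_mandatory_field(self, catalog, missing):
        kwargs = dict(age_days=100, pain_level=2, general_appearance="well")
        kwargs.pop(missing)
        with pytest.raises(IncompleteEncounterError) as exc:
            evaluate_mandatory(Encounter(**kwargs), catalog)
        assert exc.value.field == missing

    @given(st.integers(min_value=0, max_value=9))
    @settings(max_examples=20)
    def test_pain_monotone(self, pain):
        catalog = default_catalog()

        def pain_level_for(p):
            enc = Encounter(age_days=2000, pain_level=p, general_appearance="well")
            trig = [t.level for t in evaluate_mandatory(enc, catalog) if "pain" in t.code]
            return max(trig) if trig else UrgencyLevel.BLUE

        assert pain_level_for(pain) <= pain_level_for(pain + 1)


class TestComplaints:
    def test_coma(self, catalog):
        enc = Encounter(age_days=2000, findings={"unconscious"})
        trig = evaluate_complaints(enc, catalog)
        assert levels_of(trig) == {"coma": UrgencyLevel.RED}

    def test_low_glucose_infant(self, catalog):
        enc = Encounter(age_days=200, cbg_mg_dl=50)
        assert levels_of(evaluate_complaints(enc, catalog)) == {
            "cbg_low_infant": UrgencyLevel.ORANGE
        }

    def test_very_low_glucose_by_age(self, catalog):
        infant = Encounter(age_days=200, cbg_mg_dl=35)
        assert "cbg_very_low_infant" in codes(evaluate_complaints(infant, catalog))
        child = Encounter(age_days=2000, cbg_mg_dl=55)
        assert "cbg_very_low_child" in codes(evaluate_complaints(child, catalog))

    def test_head_injury_timing(self, catalog):
        recent = Encounter(
            age_days=2000, findings={"tbi_no_loc_no_vomit"}, injury_age_hours=6
        )
        assert levels_of(evaluate_complaints(recent, catalog)) == {
            "tbi_lt12h": UrgencyLevel.YELLOW
        }
        old = Encounter(
            age_days=2000, findings={"tbi_no_loc_no_vomit"}, injury_age_hours=48
        )
        assert levels_of(evaluate_complaints(old, catalog)) == {
            "tbi_gt12h": UrgencyLevel.GREEN
        }

    def test_age_conditioned_findings(self, catalog):
        young = Encounter(age_days=400, findings={"hoarseness"})
        assert "hoarseness_lt2y" in codes(evaluate_complaints(young, catalog))
        older = Encounter(age_days=1000, findings={"hoarseness"})
        assert "hoarseness_lt2y" not in codes(evaluate_complaints(older, catalog))
        toddler = Encounter(age_days=400, findings={"intermittent_abdominal_pain"})
        assert levels_of(evaluate_complaints(toddler, catalog)) == {
            "abdominal_pain_intermittent_lt2y": UrgencyLevel.ORANGE
        }

    def test_combination_guards(self, catalog):
        anaphylaxis = Encounter(
            age_days=2000, findings={"urticaria", "stridor_resp_difficulty"}
        )
        assert "urticaria_stridor_resp_difficulty" in codes(
            evaluate_complaints(anaphylaxis, catalog)
        )
        urticaria_only = Encounter(age_days=2000, findings={"urticaria"})
        assert "urticaria_stridor_resp_difficulty" not in codes(
            evaluate_complaints(urticaria_only, catalog)
        )
        hypertensive = Encounter(
            age_days=2000, findings={"edema"}, bp_systolic=150, bp_diastolic=95
        )
        assert "edema_hypertension" in codes(evaluate_complaints(hypertensive, catalog))
        normotensive = Encounter(
            age_days=2000, findings={"edema"}, bp_systolic=110, bp_diastolic=70
        )
        trig = levels_of(evaluate_complaints(normotensive, catalog))
        assert "edema_hypertension" not in trig
        assert trig["edema_no_htn_systolic"] is UrgencyLevel.ORANGE

    def test_tachypnea_derived_from_score(self, catalog):
        fast = Encounter(age_days=730, rr=50, hr=100, spo2=98, axtemp_c=36.5)
        assert "tachypnea" in codes(evaluate_complaints(fast, catalog))
        normal = Encounter(age_days=730, rr=30, hr=100, spo2=98, axtemp_c=36.5)
        assert "tachypnea" not in codes(evaluate_complaints(normal, catalog))

    def test_diabetes_glucose_bands(self, catalog):
        def trig(cbg):
            enc = Encounter(age_days=3000, findings={"diabetes"}, cbg_mg_dl=cbg)
            return levels_of(evaluate_complaints(enc, catalog))

        assert trig(15)["diabetes_severe_hypoglycemia"] is UrgencyLevel.RED
        assert trig(45)["diabetes_cbg_low"] is UrgencyLevel.ORANGE
        assert trig(450)["diabetes_cbg_high"] is UrgencyLevel.ORANGE
        assert trig(300)["diabetes_cbg_250_400"] is UrgencyLevel.YELLOW

    def test_fever_dependent_combinations(self, catalog):
        hot = Encounter(age_days=2000, findings={"immunosuppression"}, axtemp_c=38.4)
        assert "immunosuppression_fever" in codes(evaluate_complaints(hot, catalog))
        cool = Encounter(age_days=2000, findings={"immunosuppression"}, axtemp_c=36.4)
        assert "immunosuppression_no_fever" in codes(evaluate_complaints(cool, catalog))
        unknown = Encounter(age_days=2000, findings={"immunosuppression"})
        trig = codes(evaluate_complaints(unknown, catalog))
        assert "immunosuppression_fever" not in trig
        assert "immunosuppression_no_fever" not in trig

    def test_burn_categories(self, catalog):
        enc = Encounter(age_days=2000, burn_category="face_inhalation")
        assert levels_of(evaluate_complaints(enc, catalog)) == {
            "burn_face_inhalation": UrgencyLevel.RED
        }

    def test_absent_measurement_is_advisory_not_trigger(self, catalog):
        advisories = []
        enc = Encounter(age_days=3000, findings={"diabetes"})  # no CBG measured
        trig = evaluate_complaints(enc, catalog, advisories=advisories)
        assert not any("diabetes" in c for c in codes(trig))
        assert Advisory("diabetes_severe_hypoglycemia", "cbg_mg_dl") in advisories

    def test_unknown_finding_rejected(self, catalog):
        with pytest.raises(InvalidInputError, match="made_up_code"):
            evaluate_complaints(Encounter(age_days=100, findings={"made_up_code"}), catalog)

    def test_blue_entries_never_reported(self, catalog):
        enc = Encounter(age_days=2000, findings={"minor_injury_no_bleeding"})
        assert evaluate_complaints(enc, catalog) == set()

    def test_every_red_finding_fires(self, catalog):
        red_findings = set()
        for e in catalog.by_level(UrgencyLevel.RED):
            if len(e.guard) == 1 and e.guard[0].finding:
                red_findings.add(e.guard[0].finding)
        enc = Encounter(age_days=2000, findings=red_findings)
        trig = evaluate_complaints(enc, catalog)
        assert max_discriminator_level(trig) is UrgencyLevel.RED


class TestMaxLevel:
    def test_max_of_set(self, catalog):
        enc = Encounter(
            age_days=2000, pain_level=5, general_appearance="very_ill"
        )
        trig = evaluate_mandatory(enc, catalog)
        assert max_discriminator_level(trig) is UrgencyLevel.ORANGE

    def test_empty_is_none(self):
        assert max_discriminator_level(set()) is None


class TestDeterminism:
    def test_pure_function(self, catalog):
        enc = Encounter(
            age_days=500,
            findings={"stridor", "cough"},
            pain_level=3,
            general_appearance="ill",
            cbg_mg_dl=70,
        )
        first = evaluate_all(enc, catalog)
        for _ in range(3):
            assert evaluate_all(enc, catalog) == first


class TestEncounterModel:
    def test_findings_coerced_from_string(self):
        enc = Encounter(age_days=10, findings="cough; stridor")
        assert enc.findings == frozenset({"cough", "stridor"})

    def test_invalid_values_rejected(self):
        with pytest.raises(ValidationError):
            Encounter(age_days=10, spo2=105)
        with pytest.raises(ValidationError):
            Encounter(age_days=10, pain_level=11)
        with pytest.raises(ValidationError):
            Encounter(age_days=-1)


class TestCatalogLint:
    def test_census_ok(self, catalog):
        report = catalog.lint()
        assert report["ok"]
        assert report["census_mismatches"] == {}
        assert report["entries_missing_provenance"] == []

    def test_anchor_totals(self, catalog):
        report = catalog.lint()
        assert report["census_observed"]["general"] == 16
        assert report["n_anchors"] == sum(catalog.census.values())

    def test_vocabulary_closed(self, catalog):
        used = {
            c.finding
            for e in catalog.entries
            for c in e.guard
            if c.finding is not None
        }
        assert used <= catalog.vocabulary
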