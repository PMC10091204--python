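"""Submodel computations: derivations, eligibility, schedules, expectancy, benefits."""

import math

import pytest
from hypothesis import given, strategies as st

from kocompose.ipp import formulas
from kocompose.ipp.catalog import ServiceDefinition, eligible_services, load_catalog, load_params
from kocompose.ipp.core import (
    MissingFeatureError,
    adjust_mortality,
    background_risk,
    derive_features,
    detection_gain,
    diet_risk,
    life_expectancy,
    life_gain,
    net_benefit,
    rank_services,
)
from kocompose.ipp.lifetable import MortalitySchedule, mortality_schedule
from kocompose.synthetic_fixtures import gen_life_table, gen_patient


@pytest.fixture(scope="module")
def params():
    return load_params()


@pytest.fixture(scope="module")
def catalog(params):
    return load_catalog(params)


@pytest.fixture(scope="module")
def table():
    return gen_life_table(0)


def _nb_service(hr: float) -> ServiceDefinition:
    return ServiceDefinition(
        code="TST", name="testService", kind="net_benefit", criteria={}, hr=hr
    )


class TestBmi:
    def test_printed_inputs(self):
        assert formulas.bmi_value(73, 220) == pytest.approx(29.0223, abs=5e-5)

    def test_unit_inputs_return_scaling_constant(self):
        assert formulas.bmi_value(1, 1) == 703.0

    def test_linear_in_weight(self):
        assert formulas.bmi_value(70, 300) == pytest.approx(2 * formulas.bmi_value(70, 150))

    def test_nonpositive_height_is_domain_error(self):
        with pytest.raises(ValueError):
            formulas.bmi_value(0, 150)


class TestDerivations:
    def test_mosteller_reference_point(self):
        assert formulas.mosteller_bsa(180, 80) == pytest.approx(2.0)

    def test_cardiac_output_product(self):
        assert formulas.cardiac_output_value(70, 60) == 4200

    def test_cockcroft_gault_female_adjustment(self):
        male = formulas.cockcroft_gault(50, 80, 1.0, False)
        female = formulas.cockcroft_gault(50, 80, 1.0, True)
        assert female == pytest.approx(0.85 * male)

    def test_full_patient_gains_all_five_derived_keys(self, params):
        derived = derive_features(gen_patient(0, "eligible_all"), params["cvd_risk_score"])
        for key in ("bmi", "bsa", "cardiac_output", "creatinine_clearance", "cvd_risk"):
            assert key in derived

    def test_missing_input_skips_that_derivation_only(self, params):
        features = dict(gen_patient(0, "eligible_all"))
        del features["stroke_volume"]
        derived = derive_features(features, params["cvd_risk_score"])
        assert "cardiac_output" not in derived
        assert "bmi" in derived and "bsa" in derived


class TestEligibility:
    def test_sex_restricted_services_excluded_for_male(self, catalog):
        features = dict(gen_patient(0, "eligible_all"))
        features["gender"] = "Male"
        codes = eligible_services(features, catalog)
        assert "BRE" not in codes and "CER" not in codes

    def test_engineered_patient_satisfies_all_21(self, catalog):
        codes = eligible_services(gen_patient(0, "eligible_all"), catalog)
        assert sorted(codes) == sorted(s.code for s in catalog)
        assert len(codes) == 21

    def test_under_18_matches_nothing(self, catalog):
        features = dict(gen_patient(0, "eligible_all"))
        features["age"] = 17
        assert eligible_services(features, catalog) == []

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            eligible_services({}, [])


class TestMortalitySchedule:
    def test_slice_length_and_closure(self, table):
        sched = mortality_schedule(table, 50, "Male", "White", 50)
        assert len(sched.rates) == 51
        assert sched.rates[-1] == 1.0

    def test_zero_horizon_returns_single_rate(self, table):
        sched = mortality_schedule(table, 50, "Male", "White", 0)
        assert sched.rates == (table.strata[("Male", "White")][50],)

    def test_rates_equal_stratum_slice_elementwise(self, table):
        sched = mortality_schedule(table, 40, "Female", "Black", 30)
        assert sched.rates == table.strata[("Female", "Black")][40:71]

    def test_missing_stratum_names_it(self, table):
        with pytest.raises(LookupError, match="Martian"):
            mortality_schedule(table, 50, "Male", "Martian", 10)


class TestMortalityAdjustment:
    def test_low_risk_profile_leaves_schedule_unchanged(self, params):
        features = {"bmi": 24.0, "drinks_per_week": 2.0, "current_smoker": False,
                    "ever_smoker": False}
        sched = MortalitySchedule(50, (0.01, 0.02, 0.03))
        assert adjust_mortality(sched, features, params["adjustments"]).rates == sched.rates

    def test_heavy_smoker_rates_capped_at_one(self, params):
        features = {"current_smoker": True, "pack_years": 50.0}
        sched = MortalitySchedule(90, (0.6, 0.9))
        adjusted = adjust_mortality(sched, features, params["adjustments"])
        assert all(q <= 1.0 for q in adjusted.rates)
        assert adjusted.rates[1] == 1.0

    def test_joint_adjustment_equals_sequential_adjustment(self, params):
        features = {"bmi": 36.0, "drinks_per_week": 20.0, "current_smoker": True,
                    "pack_years": 40.0}
        sched = MortalitySchedule(60, tuple(0.005 * (i + 1) for i in range(20)))
        adjustments = params["adjustments"]
        joint = adjust_mortality(sched, features, adjustments)
        sequential = sched
        for name in adjustments:
            sequential = adjust_mortality(sequential, features, {name: adjustments[name]})
        assert joint.rates == sequential.rates


class TestLifeExpectancy:
    @pytest.mark.parametrize("q", [round(0.05 * k, 2) for k in range(1, 20)])
    def test_constant_hazard_matches_geometric_closed_form(self, q):
        horizon = 100
        le = life_expectancy([q] * horizon)
        p = 1.0 - q
        closed = p * (1.0 - p**horizon) / q
        assert le == pytest.approx(closed, abs=1e-9)

    def test_boundary_schedules(self):
        assert life_expectancy([1.0, 0.5]) == 0.0
        assert life_expectancy([0.0] * 10) == 10.0
        assert life_expectancy([0.2] * 100) == pytest.approx(4.0, abs=1e-3)

    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            life_expectancy([0.5, 1.2])

    def test_strictly_decreases_under_pointwise_hazard_increase(self):
        base = [0.01 * (i + 1) for i in range(30)]
        le0 = life_expectancy(base)
        for i in range(0, 30, 7):
            bumped = list(base)
            bumped[i] += 0.05
            assert life_expectancy(bumped) < le0


class TestLifeGain:
    def test_difference_and_identity(self):
        assert life_gain(4.0, 3.5) == pytest.approx(0.5)
        assert life_gain(2.0, 2.0) == 0.0

    def test_antisymmetric(self):
        assert life_gain(4.0, 3.5) == -life_gain(3.5, 4.0)


class TestNetBenefit:
    def test_null_hazard_ratio_gives_exactly_zero(self):
        sched = MortalitySchedule(50, tuple(0.01 * (i + 1) for i in range(40)))
        assert net_benefit(_nb_service(1.0), sched).life_gain == 0.0

    def test_constant_hazard_closed_form(self):
        sched = MortalitySchedule(0, (0.2,) * 100)
        gain = net_benefit(_nb_service(0.5), sched).life_gain
        assert gain == pytest.approx(5.0, abs=1e-2)  # 9 - 4 from the geometric sums

    def test_monotone_nonincreasing_in_hazard_ratio(self):
        sched = MortalitySchedule(50, tuple(0.01 * (i + 1) for i in range(40)))
        gains = [
            net_benefit(_nb_service(hr / 10), sched).life_gain for hr in range(1, 11)
        ]
        assert all(a >= b for a, b in zip(gains, gains[1:]))
        assert gains[-1] == 0.0


class TestDetectionGain:
    def _service(self, p):
        return ServiceDefinition(
            code="HIV", name="hivTesting", kind="detection", criteria={},
            hr=0.6, p_undiagnosed=p,
        )

    def test_nothing_undiagnosed_means_zero(self):
        sched = MortalitySchedule(30, (0.05,) * 50)
        assert detection_gain(self._service(0.0), sched).life_gain == 0.0

    def test_full_prevalence_reduces_to_net_benefit(self):
        sched = MortalitySchedule(30, (0.05,) * 50)
        full = detection_gain(self._service(1.0), sched).life_gain
        base = net_benefit(_nb_service(0.6), sched).life_gain
        assert full == base

    def test_linear_in_undiagnosed_fraction(self):
        sched = MortalitySchedule(30, (0.05,) * 50)
        g25 = detection_gain(self._service(0.25), sched).life_gain
        g50 = detection_gain(self._service(0.5), sched).life_gain
        assert g50 == pytest.approx(2 * g25)


class TestDietRisk:
    def test_adherent_keeps_baseline(self):
        rr, absolute = diet_risk(
            {"diet_adherent": True},
            {"feature": "diet_adherent", "adherent_rr": 1.0, "nonadherent_rr": 1.5},
            baseline=0.3,
        )
        assert rr == 1.0 and absolute == pytest.approx(0.3)

    def test_absolute_risk_capped_at_one(self):
        _, absolute = diet_risk(
            {"diet_adherent": False},
            {"feature": "diet_adherent", "adherent_rr": 1.0, "nonadherent_rr": 1.5},
            baseline=0.8,
        )
        assert absolute == 1.0

    def test_rr_always_one_of_the_two_levels(self, params):
        levels = {params["diet"]["adherent_rr"], params["diet"]["nonadherent_rr"]}
        for adherent in (True, False):
            rr, _ = diet_risk({"diet_adherent": adherent}, params["diet"], 0.2)
            assert rr in levels

    def test_missing_adherence_feature_named(self, params):
        with pytest.raises(MissingFeatureError, match="diet_adherent"):
            diet_risk({}, params["diet"], 0.2)


class TestBackgroundRisk:
    def test_logistic_at_zero_is_half(self):
        assert background_risk({}, {"intercept": 0.0, "coefficients": {}}) == 0.5

    def test_output_in_open_unit_interval(self, params):
        patient = gen_patient(5, "random")
        for model in params["background_models"].values():
            p = background_risk(patient, model)
            assert 0.0 < p < 1.0

    def test_monotone_in_positive_coefficient_feature(self):
        model = {"intercept": -2.0, "coefficients": {"age": 0.05}}
        risks = [background_risk({"age": a}, model) for a in range(20, 90, 10)]
        assert all(a < b for a, b in zip(risks, risks[1:]))


class TestRanking:
    def test_descending_order(self):
        ranked = rank_services({"ASA": 0.3, "DIA": 1.6, "CRC": 0.09})
        assert [b.code for b in ranked] == ["DIA", "ASA", "CRC"]

    def test_empty_input(self):
        assert rank_services({}) == []

    def test_ties_break_lexicographically(self):
        ranked = rank_services({"B": 1.0, "A": 1.0, "C": 2.0})
        assert [b.code for b in ranked] == ["C", "A", "B"]

    @given(
        st.dictionaries(
            st.text(alphabet="ABCDEFGH", min_size=1, max_size=3),
            st.floats(min_value=0, max_value=10, allow_nan=False),
            max_size=8,
        )
    )
    def test_output_is_a_permutation_of_input(self, benefits):
        ranked = rank_services(benefits)
        assert sorted((b.code, b.life_gain) for b in ranked) == sorted(benefits.items())
        gains = [b.life_gain for b in ranked]
        assert gains == sorted(gains, reverse=True)


class TestCatalogConfig:
    def test_hazard_ratio_out_of_range_is_build_time_error(self):
        with pytest.raises(ValueError, match="hazard ratio"):
            ServiceDefinition(code="X", name="x", kind="net_benefit", criteria={}, hr=1.2)

    def test_shipped_catalog_counts_by_kind(self, catalog):
        kinds = {}
        for service in catalog:
            kinds[service.kind] = kinds.get(service.kind, 0) + 1
        assert kinds == {
            "net_benefit": 15,
            "detection": 1,
            "diet": 1,
            "inline_behavior": 3,
            "inline_hr": 1,
        }
        assert len(catalog) == 21
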