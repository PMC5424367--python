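"""The four indices and the aggregate model fit."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bongaarts.indices import (
    DomainError,
    UndefinedIndexError,
    contraceptive_summary,
    fit_index_set,
    index_abortion,
    index_contraception,
    index_marriage,
    index_postpartum,
    mean_insusceptibility,
    predicted_tfr,
)
from bongaarts.rates import AgeSchedule, compute_rates
from bongaarts.records import AnalysisConfig, WomanRecord, default_effectiveness
from bongaarts.simulate import SimulationParams, simulate_cohort

from .conftest import make_woman


def sched(vals, kind="asmfr"):
    return AgeSchedule.from_array(vals, kind)


class TestIndexMarriage:
    def test_universal_marriage_gives_one(self):
        assert index_marriage(sched([1] * 7, "proportion_married"), sched([0.1] * 7)) == pytest.approx(1.0)

    def test_constant_proportion_passes_through(self):
        g = sched([0.3, 0.4, 0.35, 0.3, 0.2, 0.1, 0.02])
        assert index_marriage(sched([0.5] * 7, "proportion_married"), g) == pytest.approx(0.5)

    def test_degenerate_weight_on_single_group(self):
        m = sched([0.1, 0.8, 0.2, 0.3, 0.4, 0.5, 0.6], "proportion_married")
        g = sched([0, 0.4, 0, 0, 0, 0, 0])
        assert index_marriage(m, g) == pytest.approx(0.8)

    def test_zero_marital_fertility_is_undefined(self):
        with pytest.raises(UndefinedIndexError, match="g\\(a\\)"):
            index_marriage(sched([0.5] * 7, "proportion_married"), sched([0] * 7))

    def test_formula_equals_ratio_when_f_is_m_times_g(self):
        # algebraic identity: if f(a) = m(a) g(a) then sum(mg)/sum(g) = TFR/TMFR
        m_vals = [0.1, 0.55, 0.75, 0.8, 0.8, 0.78, 0.7]
        g_vals = [0.35, 0.33, 0.3, 0.25, 0.18, 0.08, 0.02]
        f = [m * g for m, g in zip(m_vals, g_vals)]
        cm_formula = index_marriage(sched(m_vals, "proportion_married"), sched(g_vals))
        tfr, tmfr = 5 * sum(f), 5 * sum(g_vals)
        assert abs(cm_formula - tfr / tmfr) < 1e-9


class TestContraceptiveSummary:
    def test_forced_example(self):
        women = [
            make_woman(woman_id=f"W{i}", current_method=m)
            for i, m in enumerate(["none", "none", "pill", "sterilization"])
        ]
        u, e = contraceptive_summary(women, default_effectiveness())
        assert u == pytest.approx(0.5)
        assert e == pytest.approx(0.95)

    def test_no_users_gives_zero_zero(self):
        women = [make_woman(woman_id=f"W{i}") for i in range(3)]
        assert contraceptive_summary(women, default_effectiveness()) == (0.0, 0.0)

    def test_unmarried_women_do_not_enter(self):
        women = [
            make_woman(woman_id="A", current_method="pill"),
            make_woman(woman_id="B", marital_status="never_married", current_method="iud"),
        ]
        u, e = contraceptive_summary(women, default_effectiveness())
        assert (u, e) == (1.0, 0.90)

    def test_no_married_women_is_undefined(self):
        women = [make_woman(marital_status="never_married")]
        with pytest.raises(UndefinedIndexError):
            contraceptive_summary(women, default_effectiveness())

    def test_weighted_means(self):
        women = [
            make_woman(woman_id="A", weight=3.0, current_method="pill"),
            make_woman(woman_id="B", weight=1.0, current_method="sterilization"),
            make_woman(woman_id="C", weight=4.0, current_method="none"),
        ]
        u, e = contraceptive_summary(women, default_effectiveness())
        assert u == pytest.approx(0.5)
        assert e == pytest.approx((3 * 0.90 + 1 * 1.00) / 4)


class TestIndexContraception:
    def test_no_use_means_no_inhibition(self):
        assert index_contraception(0.0, 0.77) == 1.0

    def test_forced_arithmetic(self):
        assert index_contraception(0.5, 0.9, 1.08) == pytest.approx(0.514)

    def test_saturated_use_is_out_of_domain(self):
        with pytest.raises(DomainError):
            index_contraception(1.0, 1.0, 1.08)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        u=st.floats(0.01, 0.8),
        e=st.floats(0.01, 1.0),
        du=st.floats(0.01, 0.19),
    )
    def test_strictly_decreasing_in_prevalence_and_effectiveness(self, u, e, du):
        base = index_contraception(u, e)
        assert index_contraception(min(u + du, 0.9), e) < base
        assert index_contraception(u, min(e * 0.5, e - 1e-3)) > base


class TestMeanInsusceptibility:
    def test_prevalence_over_monthly_incidence(self):
        # one birth per month over the window, eight women currently insusceptible
        women = [
            make_woman(woman_id=f"M{k}", age_months=350, births_ago=(k,), insusceptible_now=(k <= 8))
            for k in range(1, 37)
        ]
        assert mean_insusceptibility(women, 36) == pytest.approx(8.0)

    def test_no_current_insusceptibility_gives_zero(self):
        women = [make_woman(age_months=350, births_ago=(5,))]
        assert mean_insusceptibility(women, 36) == 0.0

    def test_no_births_in_window_is_undefined(self):
        with pytest.raises(UndefinedIndexError):
            mean_insusceptibility([make_woman()], 36)

    def test_reported_duration_weighted_mean(self):
        women = [
            WomanRecord(**{**make_woman(woman_id="A", weight=1.0).__dict__, "insus_months": 6.0}),
            WomanRecord(**{**make_woman(woman_id="B", weight=3.0).__dict__, "insus_months": 12.0}),
            make_woman(woman_id="C"),
        ]
        assert mean_insusceptibility(women, 36, "reported_duration") == pytest.approx(10.5)

    def test_simulation_recovery_within_a_month(self):
        params = SimulationParams(
            n_women=2000, seed=5, marriage_schedule=(1.0,) * 7, insusceptibility_mean=10.0
        )
        i_hat = mean_insusceptibility(simulate_cohort(params), 36)
        assert abs(i_hat - 10.0) <= 1.0


class TestIndexPostpartum:
    @pytest.mark.parametrize(
        "i, expected",
        [(1.5, 1.0), (21.5, 0.5), (7.75, 0.761905)],
    )
    def test_values(self, i, expected):
        assert index_postpartum(i) == pytest.approx(expected, abs=1e-6)

    def test_negative_duration_is_out_of_domain(self):
        with pytest.raises(DomainError):
            index_postpartum(-0.1)

    def test_short_durations_exceed_one_without_clamping(self):
        assert index_postpartum(0.0) == pytest.approx(20 / 18.5)

    def test_strictly_decreasing_in_duration(self):
        vals = [index_postpartum(i) for i in (0, 3, 6, 12, 24)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestIndexAbortion:
    def test_no_abortion_means_no_inhibition(self):
        assert index_abortion(6.0, 0.0, 0.3) == 1.0

    def test_forced_arithmetic(self):
        assert index_abortion(6.0, 1.0, 0.25) == pytest.approx(6 / 6.5)

    def test_zero_fertility_with_abortion(self):
        assert index_abortion(0.0, 1.0, 0.2) == 0.0

    def test_vacuous_case_returns_one(self):
        assert index_abortion(0.0, 0.0, 0.2) == 1.0


class TestPredictedTfr:
    def test_all_ones_reach_total_fecundity(self):
        assert predicted_tfr(1, 1, 1, 1, 15.3) == 15.3

    def test_any_zero_index_kills_fertility(self):
        assert predicted_tfr(0.0, 1, 1, 1, 15.3) == 0.0

    def test_published_national_row_2006(self):
        tfr = predicted_tfr(0.722717, 0.78179, 0.73502, 1.0, 15.3)
        assert round(tfr, 1) == 6.4


class TestFitIndexSet:
    def test_defining_identity_holds_exactly(self, small_cohort):
        s = fit_index_set(small_cohort)
        assert s.tfr_predicted == s.cm * s.cc * s.ci * s.ca * s.tf

    def test_weight_doubling_leaves_indices_unchanged(self, small_cohort):
        s1 = fit_index_set(small_cohort)
        doubled = list(small_cohort) + [
            WomanRecord(**{**r.__dict__, "woman_id": r.woman_id + "dup"}) for r in small_cohort
        ]
        s2 = fit_index_set(doubled)
        for attr in ("u", "e", "i", "cm", "cc", "ci", "ca", "tfr_observed", "tfr_predicted"):
            assert getattr(s2, attr) == pytest.approx(getattr(s1, attr), rel=1e-12)

    def test_all_ones_limit(self):
        # all married, no contraception, minimal insusceptibility (1.5 months)
        params = SimulationParams(
            n_women=2000, seed=9, marriage_schedule=(1.0,) * 7, u_true=0.0,
            insusceptibility_mean=1.5,
        )
        s = fit_index_set(simulate_cohort(params))
        assert s.cm == pytest.approx(1.0)
        assert s.cc == 1.0
        assert s.ci == pytest.approx(1.0, abs=0.03)

    def test_zero_insusceptibility_reports_ci_above_one_with_warning(self):
        params = SimulationParams(
            n_women=500, seed=2, marriage_schedule=(1.0,) * 7, u_true=0.0,
            insusceptibility_mean=0.0,
        )
        s = fit_index_set(simulate_cohort(params))
        assert s.ci == pytest.approx(20 / 18.5)
        assert any("Ci" in w for w in s.warnings)

    def test_formula_and_ratio_cm_agree_on_all_married_cohort(self, married_cohort):
        f = fit_index_set(married_cohort, AnalysisConfig(cm_method="formula"))
        r = fit_index_set(married_cohort, AnalysisConfig(cm_method="ratio"))
        assert abs(f.cm - r.cm) < 1e-9
        assert f.cm == pytest.approx(1.0)

    def test_empty_table_is_undefined(self):
        with pytest.raises(UndefinedIndexError):
            fit_index_set([])
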