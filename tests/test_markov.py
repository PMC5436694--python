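"""Cohort state-transition engine: survival schedule, traces, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from rrtcea import (
    AnalysisSettings,
    HealthState,
    ParameterError,
    ParameterEstimate,
    Policy,
    SurvivalSchedule,
    cumulative_survival,
    effective_death_prob,
    run_dialysis_trace,
    run_supportive_trace,
)


class TestSurvivalSchedule:
    def test_observed_years_returned_directly(self, params):
        assert effective_death_prob(params.survival, 3) == 0.122

    @pytest.mark.parametrize("year", [7, 30, 100])
    def test_constant_hazard_extrapolation_beyond_schedule(self, params, year):
        assert effective_death_prob(params.survival, year) == 0.146

    def test_year_below_one_rejected(self, params):
        with pytest.raises(ParameterError):
            effective_death_prob(params.survival, 0)

    def test_cumulative_survival_year_zero_is_one(self, params):
        assert cumulative_survival(params.survival, 0) == 1.0

    def test_cumulative_survival_is_product_of_year_survivals(self, params):
        assert cumulative_survival(params.survival, 2) == pytest.approx(
            0.776 * 0.865, abs=1e-12
        )

    def test_six_year_survival_matches_registry_follow_up(self, params):
        # the study reports 44.3% of patients alive at six years
        assert cumulative_survival(params.survival, 6) == pytest.approx(0.443, abs=1e-3)


def _occ(trace, state):
    return trace.state_occupancy(state)


class TestDialysisTrace:
    def test_both_arms_share_the_survival_curve_and_life_years(self, params):
        pd_tr = run_dialysis_trace(params, AnalysisSettings(policy=Policy.PD_FIRST))
        hd_tr = run_dialysis_trace(params, AnalysisSettings(policy=Policy.HD_FIRST))
        np.testing.assert_allclose(pd_tr.living(), hd_tr.living(), atol=1e-12)
        assert pd_tr.ly.sum() == pytest.approx(hd_tr.ly.sum(), abs=1e-12)

    def test_living_occupancy_equals_cumulative_survival(self, params, pd_settings):
        trace = run_dialysis_trace(params, pd_settings)
        expected = [cumulative_survival(params.survival, t) for t in range(1, 23)]
        np.testing.assert_allclose(trace.living(), expected, atol=1e-9)

    def test_no_switching_or_complications_keeps_cohort_on_first_modality(self, params):
        p = params.replace(
            p_switch_pd_to_hd=ParameterEstimate(0.0),
            p_switch_hd_to_pd=ParameterEstimate(0.0),
            p_peritonitis_pd=ParameterEstimate(0.0),
            p_vascular_complication_hd=ParameterEstimate(0.0),
        )
        trace = run_dialysis_trace(p, AnalysisSettings(policy=Policy.PD_FIRST))
        for state in (HealthState.PD_COMPLICATION, HealthState.HD,
                      HealthState.HD_COMPLICATION, HealthState.SUPPORTIVE):
            assert np.all(_occ(trace, state) == 0.0)
        np.testing.assert_allclose(_occ(trace, HealthState.PD), trace.living(), atol=1e-12)

    def test_certain_switching_moves_everyone_to_hd(self, params):
        p = params.replace(
            p_switch_pd_to_hd=ParameterEstimate(1.0),
            p_switch_hd_to_pd=ParameterEstimate(0.0),
        )
        trace = run_dialysis_trace(p, AnalysisSettings(policy=Policy.PD_FIRST))
        hd_total = _occ(trace, HealthState.HD) + _occ(trace, HealthState.HD_COMPLICATION)
        np.testing.assert_allclose(hd_total[1:], trace.living()[1:], atol=1e-12)

    def test_dead_occupancy_is_monotone(self, params, hd_settings):
        trace = run_dialysis_trace(params, hd_settings)
        assert np.all(np.diff(_occ(trace, HealthState.DEAD)) >= -1e-12)

    def test_supportive_policy_rejected_by_dialysis_engine(self, params):
        with pytest.raises(ParameterError):
            run_dialysis_trace(params, AnalysisSettings(policy=Policy.SUPPORTIVE))

    def test_policy_symmetry_under_parameter_block_swap(self, params):
        """Swapping the PD and HD parameter blocks mirrors the trace."""
        swapped = params.replace(
            p_switch_pd_to_hd=params.p_switch_hd_to_pd,
            p_switch_hd_to_pd=params.p_switch_pd_to_hd,
            p_peritonitis_pd=params.p_vascular_complication_hd,
            p_vascular_complication_hd=params.p_peritonitis_pd,
            cost_initial_pd=params.cost_initial_hd,
            cost_initial_hd=params.cost_initial_pd,
            cost_maintenance_pd_annual=params.cost_maintenance_hd_annual,
            cost_maintenance_hd_annual=params.cost_maintenance_pd_annual,
            cost_complication_pd_annual=params.cost_complication_hd_annual,
            cost_complication_hd_annual=params.cost_complication_pd_annual,
            cost_nonmedical_pd_annual=params.cost_nonmedical_hd_annual,
            cost_nonmedical_hd_annual=params.cost_nonmedical_pd_annual,
            cost_indirect_pd_annual=params.cost_indirect_hd_annual,
            cost_indirect_hd_annual=params.cost_indirect_pd_annual,
            utility_pd=params.utility_hd,
            utility_hd=params.utility_pd,
            utility_pd_complication=params.utility_hd_complication,
            utility_hd_complication=params.utility_pd_complication,
        )
        orig = run_dialysis_trace(params, AnalysisSettings(policy=Policy.PD_FIRST))
        mirror = run_dialysis_trace(swapped, AnalysisSettings(policy=Policy.HD_FIRST))
        np.testing.assert_allclose(
            _occ(orig, HealthState.PD), _occ(mirror, HealthState.HD), atol=1e-12
        )
        np.testing.assert_allclose(
            _occ(orig, HealthState.PD_COMPLICATION),
            _occ(mirror, HealthState.HD_COMPLICATION),
            atol=1e-12,
        )
        assert orig.qaly.sum() == pytest.approx(mirror.qaly.sum(), abs=1e-9)
        assert orig.cost_direct_medical.sum() == pytest.approx(
            mirror.cost_direct_medical.sum(), rel=1e-12
        )


class TestSupportiveTrace:
    def test_life_expectancy_is_geometric_mean(self, params, supportive_settings):
        trace = run_supportive_trace(params, supportive_settings)
        assert trace.ly.sum() == pytest.approx(1.0 / (0.405 * 12.0), abs=1e-6)
        assert round(trace.ly.sum(), 2) == 0.21

    def test_certain_death_gives_one_month_of_life(self, params, supportive_settings):
        p = params.replace(p_death_supportive_per_month=ParameterEstimate(1.0))
        trace = run_supportive_trace(p, supportive_settings)
        assert trace.n_cycles == 1
        assert trace.ly.sum() == pytest.approx(1.0 / 12.0)
        assert trace.occupancy[0, list(HealthState).index(HealthState.DEAD)] == 1.0

    def test_qaly_is_life_years_times_supportive_utility(self, params, supportive_settings):
        trace = run_supportive_trace(params, supportive_settings)
        assert trace.qaly.sum() == pytest.approx(trace.ly.sum() * 0.37, rel=1e-12)
        assert round(trace.qaly.sum(), 3) == 0.076

    def test_runs_until_residual_occupancy_negligible(self, params, supportive_settings):
        trace = run_supportive_trace(params, supportive_settings)
        assert trace.living()[-1] < 1e-9


@hyp_settings(max_examples=25, derandomize=True, deadline=None)
@given(
    p_switch_pd=st.floats(0.0, 1.0),
    p_switch_hd=st.floats(0.0, 1.0),
    p_perit=st.floats(0.0, 1.0),
    p_vasc=st.floats(0.0, 1.0),
    policy=st.sampled_from([Policy.PD_FIRST, Policy.HD_FIRST]),
)
def test_occupancy_conservation_for_any_valid_transitions(
    params, p_switch_pd, p_switch_hd, p_perit, p_vasc, policy
):
    """State occupancy sums to one at every cycle for any valid parameter draw."""
    p = params.replace(
        p_switch_pd_to_hd=ParameterEstimate(p_switch_pd),
        p_switch_hd_to_pd=ParameterEstimate(p_switch_hd),
        p_peritonitis_pd=ParameterEstimate(p_perit),
        p_vascular_complication_hd=ParameterEstimate(p_vasc),
    )
    trace = run_dialysis_trace(p, AnalysisSettings(policy=policy))
    np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
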