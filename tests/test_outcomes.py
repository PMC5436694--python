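"""Discounting, lifetime accrual, ICER logic and the efficiency frontier."""

import numpy as np
import pytest

from rrtcea import (
    AnalysisSettings,
    ParameterError,
    ParameterEstimate,
    Perspective,
    Policy,
    PolicyOutcome,
    accrue_outcomes,
    discount_factor,
    frontier,
    icer,
    net_monetary_benefit,
    run_supportive_trace,
    run_trace,
)
from rrtcea.outcomes import DOMINANT, DOMINATED, EQUIVALENT


class TestDiscountFactor:
    def test_time_zero_is_unity(self):
        assert discount_factor(0.03, 0.0) == 1.0

    def test_one_year_at_three_percent(self):
        assert discount_factor(0.03, 1.0) == pytest.approx(0.97087, abs=5e-6)

    def test_zero_rate_never_discounts(self):
        assert np.all(discount_factor(0.0, np.array([0.0, 5.0, 50.0])) == 1.0)

    @pytest.mark.parametrize("rate,t", [(-0.01, 1.0), (0.03, -1.0)])
    def test_negative_inputs_rejected(self, rate, t):
        with pytest.raises(ParameterError):
            discount_factor(rate, t)


def _brute_force_accrual(trace, rate):
    """Independent plain-Python accumulation over the trace, cycle by cycle."""
    ly = qaly_u = qaly_d = dm = dnm = ind = 0.0
    for i in range(trace.n_cycles):
        ly += float(trace.ly[i])
        qaly_u += float(trace.qaly[i])
        qaly_d += float(trace.qaly[i]) * (1.0 + rate) ** (-float(trace.outcome_times[i]))
        dfc = (1.0 + rate) ** (-float(trace.cost_times[i]))
        dm += float(trace.cost_direct_medical[i]) * dfc
        dnm += float(trace.cost_direct_nonmedical[i]) * dfc
        ind += float(trace.cost_indirect[i]) * dfc
    return ly, qaly_u, qaly_d, dm, dnm, ind


class TestAccrueOutcomes:
    @pytest.mark.parametrize(
        "policy", [Policy.SUPPORTIVE, Policy.PD_FIRST, Policy.HD_FIRST]
    )
    def test_matches_brute_force_accumulation(self, params, policy):
        s = AnalysisSettings(policy=policy)
        trace = run_trace(params, s)
        out = accrue_outcomes(trace, params, s)
        ly, qaly_u, qaly_d, dm, dnm, ind = _brute_force_accrual(trace, 0.03)
        assert out.ly_undiscounted == pytest.approx(ly, rel=1e-6)
        assert out.qaly_undiscounted == pytest.approx(qaly_u, rel=1e-6)
        assert out.qaly_discounted == pytest.approx(qaly_d, rel=1e-6)
        assert out.cost_direct_medical == pytest.approx(dm, rel=1e-6)
        assert out.cost_direct_nonmedical == pytest.approx(dnm, rel=1e-6)
        assert out.cost_indirect == pytest.approx(ind, rel=1e-6)

    def test_supportive_closed_form(self, params, supportive_settings):
        """The monthly supportive arm has geometric closed forms for all streams."""
        p, u, c = 0.405, 0.37, 444_400.0
        out = accrue_outcomes(
            run_supportive_trace(params, supportive_settings), params, supportive_settings
        )
        assert out.ly_undiscounted == pytest.approx(1.0 / (12.0 * p), abs=1e-6)
        x = 1.03 ** (-1.0 / 12.0)
        q = 1.0 - p
        # sum over months m>=1 of q^(m-1) * x^(m-1), truncated tail is negligible
        series_start = 1.0 / (1.0 - q * x)
        assert out.cost_direct_medical == pytest.approx(c * series_start, rel=1e-6)
        assert out.qaly_discounted == pytest.approx(u / 12.0 * x * series_start, rel=1e-6)
        assert out.cost_direct_nonmedical == pytest.approx(274_881.0)

    def test_discounting_shrinks_every_nonzero_stream(self, params, pd_settings):
        trace = run_trace(params, pd_settings)
        disc = accrue_outcomes(trace, params, pd_settings)
        undisc = accrue_outcomes(trace, params, pd_settings.replace(discount_rate=0.0))
        assert disc.qaly_discounted < undisc.qaly_discounted
        assert disc.cost_discounted_societal < undisc.cost_discounted_societal
        assert disc.qaly_undiscounted == undisc.qaly_undiscounted

    def test_qaly_bounded_by_life_years(self, params, hd_settings):
        out = accrue_outcomes(run_trace(params, hd_settings), params, hd_settings)
        assert out.qaly_undiscounted <= out.ly_undiscounted
        assert out.cost_discounted_provider <= out.cost_discounted_societal

    def test_perspective_difference_is_the_household_stream(self, params, hd_settings):
        """Societal minus provider equals the discounted non-medical + indirect streams."""
        trace = run_trace(params, hd_settings)
        out = accrue_outcomes(trace, params, hd_settings)
        household = sum(
            (float(trace.cost_direct_nonmedical[i]) + float(trace.cost_indirect[i]))
            * 1.03 ** (-float(trace.cost_times[i]))
            for i in range(trace.n_cycles)
        )
        assert out.cost_discounted_societal - out.cost_discounted_provider == pytest.approx(
            household, rel=1e-9
        )

    def test_policy_mismatch_rejected(self, params, pd_settings, hd_settings):
        trace = run_trace(params, pd_settings)
        with pytest.raises(ParameterError):
            accrue_outcomes(trace, params, hd_settings)


def _outcome(policy, cost, qaly, perspective=Perspective.SOCIETAL, rate=0.03):
    return PolicyOutcome(
        policy=policy,
        perspective=perspective,
        discount_rate=rate,
        ly_undiscounted=qaly,
        qaly_undiscounted=qaly,
        qaly_discounted=qaly,
        cost_direct_medical=cost,
        cost_direct_nonmedical=0.0,
        cost_indirect=0.0,
        cost_undiscounted_societal=cost,
        cost_undiscounted_provider=cost,
    )


class TestICER:
    def test_hd_first_dominated_by_pd_first_at_published_totals(self):
        pd_o = _outcome(Policy.PD_FIRST, 696.6e6, 4.40)
        hd_o = _outcome(Policy.HD_FIRST, 735.4e6, 4.34)
        assert icer(pd_o, hd_o) == DOMINATED

    def test_plain_ratio(self):
        a = _outcome(Policy.SUPPORTIVE, 0.0, 0.0)
        b = _outcome(Policy.PD_FIRST, 100.0, 2.0)
        assert icer(a, b) == 50.0

    def test_identical_outcomes_are_equivalent(self):
        a = _outcome(Policy.PD_FIRST, 1.0, 1.0)
        assert icer(a, a) == EQUIVALENT

    def test_cheaper_and_better_is_dominant(self):
        a = _outcome(Policy.SUPPORTIVE, 100.0, 1.0)
        b = _outcome(Policy.PD_FIRST, 50.0, 2.0)
        assert icer(a, b) == DOMINANT

    def test_mismatched_discount_rates_rejected(self):
        a = _outcome(Policy.SUPPORTIVE, 0.0, 1.0, rate=0.03)
        b = _outcome(Policy.PD_FIRST, 1.0, 2.0, rate=0.05)
        with pytest.raises(ParameterError):
            icer(a, b)

    def test_scale_equivariance_in_costs(self, params, settings):
        """Multiplying all unit costs by k multiplies every ICER by k."""
        from rrtcea.parameters import PARAMETER_REGISTRY
        from rrtcea.psa import deterministic_outcomes

        k = 3.0
        scaled = params.replace(
            **{
                name: ParameterEstimate(getattr(params, name).mean * k)
                for name, kind, _, _ in PARAMETER_REGISTRY
                if kind == "cost"
            }
        )
        base = deterministic_outcomes(params, settings)
        big = deterministic_outcomes(scaled, settings)
        r0 = icer(base[Policy.SUPPORTIVE], base[Policy.PD_FIRST])
        r1 = icer(big[Policy.SUPPORTIVE], big[Policy.PD_FIRST])
        assert r1 == pytest.approx(k * r0, rel=1e-9)


class TestNMB:
    def test_published_supportive_example(self):
        o = _outcome(Policy.SUPPORTIVE, 1.7e6, 0.076)
        assert net_monetary_benefit(o, 43e6) == pytest.approx(1.568e6)

    def test_zero_wtp_is_negative_cost(self):
        o = _outcome(Policy.PD_FIRST, 123.0, 4.0)
        assert net_monetary_benefit(o, 0.0) == -123.0

    def test_nmb_ordering_matches_icer_threshold_logic(self):
        """For two options, NMB prefers the costlier one iff WTP > their ICER."""
        a = _outcome(Policy.SUPPORTIVE, 1.7e6, 0.076)
        b = _outcome(Policy.PD_FIRST, 696.6e6, 3.67)
        threshold = icer(a, b)
        for wtp in np.arange(0.0, 400e6, 5e6):
            prefers_b = net_monetary_benefit(b, wtp) > net_monetary_benefit(a, wtp)
            assert prefers_b == (wtp > threshold)


class TestFrontier:
    def test_published_totals_put_hd_first_off_the_frontier(self):
        outs = [
            _outcome(Policy.SUPPORTIVE, 1.7e6, 0.076),
            _outcome(Policy.PD_FIRST, 696.6e6, 4.40),
            _outcome(Policy.HD_FIRST, 735.4e6, 4.34),
        ]
        res = frontier(outs)
        assert res.frontier == (Policy.SUPPORTIVE, Policy.PD_FIRST)
        assert res.dominance[Policy.HD_FIRST] == "strict"
        (lo, hi, value), = res.frontier_icers
        assert (lo, hi) == (Policy.SUPPORTIVE, Policy.PD_FIRST)
        assert value == pytest.approx((696.6e6 - 1.7e6) / (4.40 - 0.076))

    def test_single_policy_frontier(self):
        res = frontier([_outcome(Policy.PD_FIRST, 10.0, 1.0)])
        assert res.frontier == (Policy.PD_FIRST,)
        assert res.frontier_icers == ()

    def test_collinear_middle_point_is_extendedly_dominated(self):
        outs = [
            _outcome(Policy.SUPPORTIVE, 0.0, 0.0),
            _outcome(Policy.PD_FIRST, 50.0, 1.0),
            _outcome(Policy.HD_FIRST, 100.0, 2.0),
        ]
        res = frontier(outs)
        assert res.dominance[Policy.PD_FIRST] == "extended"
        assert res.frontier == (Policy.SUPPORTIVE, Policy.HD_FIRST)
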