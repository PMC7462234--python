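"""Core research-value metrics: expectations, triggers, EVR, Monte-Carlo oracle."""

import warnings

import numpy as np
import pytest

import voihealth as vh

from conftest import LAMBDA, WORKED_COSTS, WORKED_DALYS, run_generated


class TestExpectedNet:
    def test_worked_example_expected_net(self, worked_prior, worked_net):
        assert vh.expected_net(worked_prior, worked_net) == pytest.approx(368.421052, abs=1e-4)

    def test_point_mass_prior_returns_net_at_atom(self, worked_net):
        prior = vh.fit_prior(vh.PriorSpec("beta", 0.3, 0.0))
        assert vh.expected_net(prior, worked_net) == pytest.approx(worked_net(0.3), rel=1e-12)

    @pytest.mark.parametrize("family,mean,se", [
        ("beta", 0.10, 0.04), ("normal", 0.2, 0.1), ("gamma", 0.5, 0.2),
    ])
    def test_linear_net_expectation_equals_net_at_prior_mean(self, family, mean, se, worked_net):
        """For a linear net curve, E[net(X)] = net(E[X]) under any prior."""
        prior = vh.fit_prior(vh.PriorSpec(family, mean, se))
        assert vh.expected_net(prior, worked_net) == pytest.approx(
            worked_net(prior.mean), abs=1e-6 * max(1.0, abs(worked_net(prior.mean)))
        )


class TestFindTriggers:
    def test_worked_example_trigger(self, worked_net):
        triggers = vh.find_triggers(worked_net, (0.0, 1.0))
        assert len(triggers) == 1
        assert triggers[0] == pytest.approx(0.072, abs=1e-9)

    def test_always_positive_net_has_no_trigger(self):
        assert vh.find_triggers(lambda x: np.full_like(np.asarray(x, float), 5.0), (0.0, 1.0)) == []

    def test_known_linear_root(self):
        triggers = vh.find_triggers(lambda x: 2.0 * np.asarray(x, float) - 1.0, (0.0, 1.0))
        assert triggers == pytest.approx([0.5], abs=1e-10)

    def test_multiple_roots_of_nonmonotone_curve(self):
        f = lambda x: (np.asarray(x, float) - 0.25) * (np.asarray(x, float) - 0.75)
        assert vh.find_triggers(f, (0.0, 1.0)) == pytest.approx([0.25, 0.75], abs=1e-9)


class TestExpectedResearchValue:
    def test_worked_example_evr_and_probability(self, worked_prior, worked_net):
        evr, prob = vh.expected_research_value(worked_prior, worked_net)
        assert evr == pytest.approx(59.389306, abs=1e-3)
        # probability of a decision change = prior mass below the trigger
        assert prob == pytest.approx(worked_prior.cdf(0.072), abs=1e-9)

    def test_no_decision_uncertainty_gives_zero_value(self):
        """Prior entirely where net > 0: research cannot change the decision."""
        prior = vh.fit_prior(vh.PriorSpec("beta", 0.5, 0.05))
        net = vh.build_net_curve(
            vh.fit_curve([(0.2, 1000.0), (0.8, 2000.0)]), vh.constant_curve(0.0), LAMBDA
        )
        evr, prob = vh.expected_research_value(prior, net)
        assert evr == pytest.approx(0.0, abs=1e-6)
        assert prob == pytest.approx(0.0, abs=1e-9)

    def test_point_mass_prior_has_zero_research_value(self, worked_net):
        prior = vh.fit_prior(vh.PriorSpec("beta", 0.10, 0.0))
        assert vh.expected_research_value(prior, worked_net) == (0.0, 0.0)

    def test_sign_flipped_net_swaps_decision_but_keeps_evr_nonnegative(self, worked_prior):
        """Mirror-image scenario: programme not expected to be cost-effective."""
        dalys = vh.fit_curve([(x, -y) for x, y in WORKED_DALYS])
        net = vh.build_net_curve(dalys, vh.constant_curve(-450_000.0), LAMBDA)
        e_net = vh.expected_net(worked_prior, net)
        assert e_net == pytest.approx(-368.421052, abs=1e-4)
        evr, prob = vh.expected_research_value(worked_prior, net)
        # with the decision flipped, research value = E[max(net, 0)] = EVR of the original
        assert evr == pytest.approx(59.389306, abs=1e-3)
        assert prob == pytest.approx(worked_prior.cdf(0.072), abs=1e-9)

    def test_scale_equivariance_of_evr(self, worked_prior, worked_net):
        """Scaling DALYs and costs by k (thresholds fixed) scales EVR by k."""
        k = 7.0
        dalys = vh.fit_curve([(x, k * y) for x, y in WORKED_DALYS])
        cost = vh.fit_curve([(x, k * c) for x, c in WORKED_COSTS])
        net_k = vh.build_net_curve(dalys, cost, LAMBDA)
        evr, _ = vh.expected_research_value(worked_prior, worked_net)
        evr_k, _ = vh.expected_research_value(worked_prior, net_k)
        assert evr_k == pytest.approx(k * evr, rel=1e-8)

    @pytest.mark.parametrize("seed", range(12))
    def test_jensen_bound_on_generated_scenarios(self, seed):
        """E[max(net,0)] >= max(E[net],0), so EVR >= 0, whatever the scenario."""
        out = run_generated(seed)
        assert out.result.evr >= 0.0
        assert 0.0 <= out.result.prob_decision_change <= 1.0
        assert out.result.total_with_research == pytest.approx(
            max(out.result.expected_net_current, 0.0) + out.result.evr, rel=1e-12
        )


class TestMaxResearchSpend:
    def test_thousand_dalys_at_500_per_daly(self):
        assert vh.max_research_spend(1000.0, 500.0) == 500_000.0

    def test_worked_example_spend(self, worked_prior, worked_net):
        evr, _ = vh.expected_research_value(worked_prior, worked_net)
        assert evr * 300.0 == pytest.approx(17_816.79, abs=1.0)

    def test_zero_value_means_zero_spend(self):
        assert vh.max_research_spend(0.0, 500.0) == 0.0

    def test_negative_evr_rejected(self):
        with pytest.raises(ValueError):
            vh.max_research_spend(-1.0, 500.0)


class TestMonteCarloOracle:
    def test_point_mass_prior(self, worked_net):
        prior = vh.fit_prior(vh.PriorSpec("beta", 0.10, 0.0))
        assert vh.mc_research_value(prior, worked_net, 1000, seed=0) == (0.0, 0.0)

    def test_worked_example_within_three_standard_errors(self, worked_prior, worked_net):
        evr, _ = vh.expected_research_value(worked_prior, worked_net)
        evr_hat, se = vh.mc_research_value(worked_prior, worked_net, 10**6, seed=11)
        assert abs(evr_hat - evr) < 3 * se

    def test_same_seed_reproduces(self, worked_prior, worked_net):
        a = vh.mc_research_value(worked_prior, worked_net, 10_000, seed=5)
        b = vh.mc_research_value(worked_prior, worked_net, 10_000, seed=5)
        assert a == b

    def test_small_n_rejected(self, worked_prior, worked_net):
        with pytest.raises(ValueError):
            vh.mc_research_value(worked_prior, worked_net, 10, seed=0)


class TestAnalyseScenario:
    def test_worked_example_full_chain(self, worked_result):
        r = worked_result
        assert r.decision_current == "implement"
        assert r.expected_dalys == pytest.approx(1868.421052, abs=1e-3)
        assert r.opportunity_cost_dalys == pytest.approx(1500.0, abs=1e-6)
        assert r.expected_net_current == pytest.approx(368.421052, abs=1e-3)
        assert r.trigger_points == pytest.approx([0.072], abs=1e-9)
        assert r.evr == pytest.approx(59.389306, abs=1e-3)
        assert r.max_research_spend == pytest.approx(17_816.79, abs=1.0)
        assert r.total_with_research == pytest.approx(r.expected_net_current + r.evr, rel=1e-12)

    def test_degenerate_prior_yields_zero_research_value(self):
        prior = vh.fit_prior(vh.PriorSpec("beta", 0.10, 0.0))
        r = vh.analyse_scenario(prior, WORKED_DALYS, WORKED_COSTS, LAMBDA)
        assert r.evr == 0.0
        assert r.max_research_spend == 0.0

    def test_negated_scenario_decision_and_value(self, worked_prior):
        dalys = [(x, -y) for x, y in WORKED_DALYS]
        costs = [(x, -c) for x, c in WORKED_COSTS]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = vh.analyse_scenario(worked_prior, dalys, costs, LAMBDA)
        assert r.decision_current == "do_not_implement"
        assert r.evr == pytest.approx(59.389306, abs=1e-3)
        assert r.total_with_research == pytest.approx(r.evr, rel=1e-9)

    def test_missing_cost_table_falls_back_to_constant(self, worked_prior):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = vh.analyse_scenario(
                worked_prior, WORKED_DALYS, None, LAMBDA, expected_cost=450_000.0
            )
        assert r.expected_net_current == pytest.approx(368.421052, abs=1e-3)

    def test_lambda_research_defaults_to_lambda_service(self, worked_result):
        assert worked_result.lambda_research == worked_result.lambda_service == LAMBDA

    def test_evr_shrinks_to_zero_with_prior_uncertainty(self):
        """Zero-uncertainty limit: research value vanishes as the prior SE shrinks."""
        evrs = []
        for se in (0.04, 0.03, 0.02, 0.01, 0.005):
            prior = vh.fit_prior(vh.PriorSpec("beta", 0.10, se))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                evrs.append(vh.analyse_scenario(prior, WORKED_DALYS, WORKED_COSTS, LAMBDA).evr)
        assert all(a > b for a, b in zip(evrs, evrs[1:]))
        assert evrs[-1] < 1e-3


class TestAccounting:
    def test_case_study_table_accounting(self):
        """Printed aggregates: US$888m at US$500/DALY vs 1.88m DALYs averted."""
        acc = vh.net_health_accounting(1_884_832, 888_203_454, 500.0)
        assert round(acc["opportunity_cost_dalys"]) == 1_776_407
        assert round(acc["icer"]) == 471
        assert round(acc["net_dalys_averted"]) == 108_425

    def test_icer_undefined_without_health_gain(self):
        acc = vh.net_health_accounting(0.0, 1000.0, 500.0)
        assert np.isnan(acc["icer"])
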