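"""Distribution fitting, one-way/tornado, threshold scanning, PSA, CEAC."""

import copy
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcea.model_core import discount_factor
from crcea.crc_models import REMISSION
from crcea.sensitivity import (
    Beta,
    Degenerate,
    Gamma,
    LogNormal,
    ParameterSpec,
    Uniform,
    beta_from_mean_sd,
    ceac,
    gamma_from_mean_sd,
    lognormal_from_rr_ci,
    one_way,
    run_psa,
    scan_parameter,
    threshold_scan,
    tornado,
)


class TestLogNormalFit:
    def test_aspirin_rr_parameters(self):
        mu, sigma = lognormal_from_rr_ci(0.53, 0.33, 0.86)
        assert mu == pytest.approx(-0.635, abs=5e-4)
        assert sigma == pytest.approx(0.244, abs=5e-4)

    def test_capecitabine_rr_parameters(self):
        mu, sigma = lognormal_from_rr_ci(0.78, 0.67, 0.91)
        assert mu == pytest.approx(-0.248, abs=5e-4)
        assert sigma == pytest.approx(0.0781, abs=5e-5)

    def test_degenerate_identity(self):
        assert lognormal_from_rr_ci(1.0, 1.0, 1.0) == (0.0, 0.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            lognormal_from_rr_ci(0.5, 0.0, 0.9)
        with pytest.raises(ValueError):
            lognormal_from_rr_ci(0.5, 0.6, 0.9)  # lo > rr


class TestMomentFits:
    def test_uniform_special_case_of_beta(self):
        dist = beta_from_mean_sd(0.5, math.sqrt(1 / 12))
        assert dist.alpha == pytest.approx(1.0, rel=1e-9)
        assert dist.beta == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize(
        "mean, sd", [(0.999, 0.00383), (0.86, 0.14), (0.84, 0.17)]
    )
    def test_beta_round_trips_published_utilities(self, mean, sd):
        dist = beta_from_mean_sd(mean, sd)
        assert dist.mean == pytest.approx(mean, abs=1e-9)
        assert dist.sd == pytest.approx(sd, abs=1e-9)

    def test_infeasible_beta_sd_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            beta_from_mean_sd(0.999, 0.5)

    def test_gamma_closed_form(self):
        dist = gamma_from_mean_sd(4.0, 2.0)
        assert dist.shape == pytest.approx(4.0)
        assert dist.scale == pytest.approx(1.0)

    @pytest.mark.parametrize("mean, sd", [(138_453, 630_923), (55_569, 1_329)])
    def test_gamma_round_trips_published_costs(self, mean, sd):
        dist = gamma_from_mean_sd(mean, sd)
        assert dist.mean == pytest.approx(mean, rel=1e-6)
        assert dist.sd == pytest.approx(sd, rel=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        mean=st.floats(0.01, 0.99),
        frac=st.floats(0.05, 0.95),
    )
    def test_beta_round_trip_property(self, mean, frac):
        sd = frac * math.sqrt(mean * (1 - mean))
        dist = beta_from_mean_sd(mean, sd)
        assert dist.mean == pytest.approx(mean, abs=1e-9)
        assert dist.sd == pytest.approx(sd, abs=1e-9)


class TestOneWay:
    def test_zero_range_parameter_has_zero_spread(self, bundle_I, params_I):
        p = params_I["rr_aspirin"]
        frozen = ParameterSpec(
            name="frozen", base=p.base, low=p.base, high=p.base, target=p.target
        )
        entry = one_way(frozen, bundle_I)
        assert entry.spread == 0.0

    def test_drug_cost_spread_matches_linear_oracle(self, bundle_I, params_I, outcomes_I):
        """NMB is linear in the drug cost: the spread equals the discounted
        occupancy-weighted 5-year cost difference, computed from the base
        aspirin trace."""
        p = params_I["drug_cost_aspirin"]
        entry = one_way(p, bundle_I)
        trace = outcomes_I["aspirin"].trace
        asp = bundle_I.strategies["aspirin"]
        unit = sum(
            (asp.drug_cost[t - 1] / 30.0)
            * trace.occupancy[t, REMISSION]
            * discount_factor(bundle_I.config.discount.cost_rate, t)
            for t in range(1, 21)
        ) / bundle_I.config.cohort_size
        assert entry.spread == pytest.approx((p.high - p.low) * unit, rel=1e-9)

    def test_lower_relative_risk_favors_aspirin(self, bundle_I, params_I):
        entry = one_way(params_I["rr_aspirin"], bundle_I)
        assert entry.outcome_low > entry.outcome_high  # low rr = better for aspirin

    def test_tornado_sorted_by_descending_spread(self, bundle_I, params_I):
        subset = [
            params_I["rr_aspirin"],
            params_I["u_aspirin"],
            params_I["metastatic_cost"],
            params_I["drug_cost_aspirin"],
        ]
        entries = tornado(subset, bundle_I)
        spreads = [e.spread for e in entries]
        assert spreads == sorted(spreads, reverse=True)

    def test_zero_spread_entry_ranks_last(self, bundle_I, params_I):
        p = params_I["rr_aspirin"]
        frozen = ParameterSpec(
            name="frozen", base=p.base, low=p.base, high=p.base, target=p.target
        )
        entries = tornado([frozen, params_I["u_aspirin"]], bundle_I)
        assert entries[-1].parameter == "frozen"

    def test_single_parameter_tornado(self, bundle_I, params_I):
        entries = tornado([params_I["u_aspirin"]], bundle_I)
        assert len(entries) == 1


class TestThresholdScan:
    def test_linear_toy_model_matches_analytic_root(self):
        classify = lambda x: "neg" if 3.0 * x - 1.2 < 0 else "pos"
        crossings = threshold_scan(classify, 0.0, 1.0, n_grid=101, xtol=1e-4)
        assert len(crossings) == 1
        assert crossings[0].value == pytest.approx(0.4, abs=2e-4)  # 2x tolerance

    def test_constant_classification_returns_empty(self):
        assert threshold_scan(lambda x: "same", 0.0, 1.0) == []

    def test_agrees_with_dense_grid_oracle(self):
        f = lambda x: math.sin(3 * x) - 0.5
        classify = lambda x: f(x) > 0
        crossings = threshold_scan(classify, 0.0, 2.0, n_grid=201, xtol=1e-4)
        # brute-force oracle: sign changes on a 10,000-point grid
        grid = np.linspace(0.0, 2.0, 10_000)
        signs = np.sign([f(x) for x in grid])
        brute = [
            (grid[i] + grid[i + 1]) / 2
            for i in range(len(grid) - 1)
            if signs[i] != signs[i + 1]
        ]
        assert len(crossings) == len(brute) == 2
        for found, expected in zip((c.value for c in crossings), brute):
            assert found == pytest.approx(expected, abs=2e-4)

    def test_aspirin_rr_reversal_lies_near_one(self, bundle_I, params_I):
        crossings = scan_parameter(
            params_I["rr_aspirin"], bundle_I, lo=0.80, hi=1.0,
            comparator="no_treatment", n_grid=41,
        )
        labels = {(c.label_below, c.label_above) for c in crossings}
        # no treatment goes from dominated, through a trade-off region, to
        # dominating aspirin as the treatment effect vanishes
        reversal = [c for c in crossings if c.label_above == "dominant"]
        assert len(reversal) == 1
        assert 0.9 < reversal[0].value < 1.0


def degenerate_params(params):
    return [
        ParameterSpec(
            name=p.name,
            base=p.base,
            low=p.low,
            high=p.high,
            target=p.target,
            distribution=Degenerate(p.base),
            kind=p.kind,
            is_cost=p.is_cost,
            in_psa=True,
        )
        for p in params
    ]


class TestPsa:
    def test_degenerate_distributions_reproduce_base_case_exactly(
        self, bundle_I, params_I, outcomes_I
    ):
        params = degenerate_params([p for p in params_I.values() if p.in_psa])
        res = run_psa(params, bundle_I, n_iter=2, seed=11)
        for name, outcome in outcomes_I.items():
            sub = res.samples[res.samples.strategy == name]
            assert (sub.cost == outcome.totals.cost).all()  # bit-for-bit
            assert (sub.qaly == outcome.totals.qaly).all()
        assert res.n_clamped == 0

    def test_fixed_seed_reproduces_output(self, bundle_I, params_I):
        params = [p for p in params_I.values() if p.in_psa]
        a = run_psa(params, bundle_I, n_iter=5, seed=123)
        b = run_psa(params, bundle_I, n_iter=5, seed=123)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_iterations_independent_of_batching(self, bundle_I, params_I):
        """Counter-based per-iteration generators: iteration i's draws do
        not depend on how many iterations ran before it."""
        params = [p for p in params_I.values() if p.in_psa]
        a = run_psa(params, bundle_I, n_iter=4, seed=9).draws
        b = run_psa(params, bundle_I, n_iter=2, seed=9).draws
        pd.testing.assert_frame_equal(a.iloc[:2], b)


class TestCeac:
    @staticmethod
    def toy_samples():
        return pd.DataFrame(
            {
                "iteration": [0, 0, 1, 1],
                "strategy": ["a", "b", "a", "b"],
                "cost": [100.0, 50.0, 100.0, 150.0],
                "qaly": [2.0, 1.0, 2.0, 1.5],
            }
        )

    def test_fractions_sum_to_one_at_every_wtp(self):
        curves = ceac(self.toy_samples(), [0, 50, 100, 200])
        sums = curves.groupby("wtp")["fraction"].sum()
        assert (sums == 1.0).all()

    def test_wtp_zero_rewards_cheapest_strategy(self):
        curves = ceac(self.toy_samples(), [0.0])
        by = curves.set_index("strategy")["fraction"]
        assert by["b"] == 0.5 and by["a"] == 0.5  # b cheaper in iter 0, a in iter 1

    def test_single_strategy_wins_everywhere(self):
        samples = pd.DataFrame(
            {"iteration": [0, 1], "strategy": "only", "cost": [1.0, 2.0], "qaly": [1.0, 1.0]}
        )
        curves = ceac(samples, [0, 100])
        assert (curves.fraction == 1.0).all()

    def test_exact_ties_break_lexicographically(self):
        samples = pd.DataFrame(
            {
                "iteration": [0, 0],
                "strategy": ["zeta", "alpha"],
                "cost": [10.0, 10.0],
                "qaly": [1.0, 1.0],
            }
        )
        curves = ceac(samples, [0, 100_000]).set_index(["wtp", "strategy"])
        assert (curves.loc[(slice(None), "alpha"), "fraction"] == 1.0).all()
        assert (curves.loc[(slice(None), "zeta"), "fraction"] == 0.0).all()


class TestDistributionSampling:
    @pytest.mark.parametrize(
        "dist",
        [
            Beta(2.0, 5.0),
            Gamma(3.0, 10.0),
            LogNormal(-0.635, 0.244),
            Uniform(0.2, 0.8),
        ],
        ids=["beta", "gamma", "lognormal", "uniform"],
    )
    def test_sample_mean_matches_analytic_mean(self, dist):
        rng = np.random.default_rng(5)
        draws = np.array([dist.sample(rng) for _ in range(4000)])
        se = dist.sd / math.sqrt(len(draws))
        assert abs(draws.mean() - dist.mean) < 3 * se
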