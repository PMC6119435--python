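"""Distribution fitting, joint sampling, tornado, PSA and CEAC."""

import numpy as np
import pytest
from scipy import stats

from iriscea import (
    DistributionSpec,
    fit_distribution,
    owsa,
    percentile_interval,
    run_base_case,
    run_psa,
    sample_parameter_set,
    shrink_uncertainty,
)
from iriscea.sensitivity import PsaResult, ceac


class TestFitDistribution:
    def test_fixed_spec_is_point_mass(self, rng):
        fit = fit_distribution(DistributionSpec.fixed(0.37))
        assert all(fit.sample(rng) == 0.37 for _ in range(5))

    def test_beta_fit_against_quadrature_oracle(self):
        """Method-of-moments beta for the not-abused utility: mean 0.85 and
        central 95% mass on (0.840, 0.860), checked against scipy's beta
        quantiles (an independent numeric oracle)."""
        fit = fit_distribution(DistributionSpec("beta", 0.85, 0.840, 0.860))
        a, b = fit.args
        assert fit.mean == pytest.approx(0.85, abs=1e-6)
        lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
        assert lo == pytest.approx(0.840, abs=0.002)
        assert hi == pytest.approx(0.860, abs=0.002)

    def test_gamma_fit_preserves_mean_and_sd(self):
        fit = fit_distribution(DistributionSpec("gamma", 2043.0, 52.0, 7536.0))
        shape, scale = fit.args
        assert shape * scale == pytest.approx(2043.0, abs=0.1)
        assert np.sqrt(shape) * scale == pytest.approx((7536 - 52) / 3.92, rel=1e-9)

    def test_uniform_uses_limits(self, rng):
        fit = fit_distribution(DistributionSpec("uniform", 0.003, 0.0, 0.0066))
        xs = [fit.sample(rng) for _ in range(100)]
        assert all(0.0 <= x <= 0.0066 for x in xs)

    def test_infeasible_beta_sd_names_parameter(self):
        with pytest.raises(ValueError, match="prevalence"):
            fit_distribution(DistributionSpec("beta", 0.01, 0.0, 0.9), name="prevalence")


class TestSampleParameterSet:
    def test_all_fixed_returns_base(self, national, rng):
        p = shrink_uncertainty(national, 0.0)
        draw, audit = sample_parameter_set(p, rng)
        assert audit == []
        assert draw.exit_probs("control", "U") == p.exit_probs("control", "U")
        assert draw.prevalence.base == p.prevalence.base

    def test_same_seed_identical_draws(self, national):
        d1, _ = sample_parameter_set(national, np.random.default_rng(5))
        d2, _ = sample_parameter_set(national, np.random.default_rng(5))
        assert d1 == d2

    def test_draws_pass_validation(self, national):
        rng = np.random.default_rng(11)
        for _ in range(50):
            draw, _ = sample_parameter_set(national, rng)
            assert draw.validate() == []

    def test_prevalence_sample_mean(self, national):
        """Monte Carlo mean of the prevalence draws matches the fitted mean
        within 3 standard errors."""
        rng = np.random.default_rng(7)
        n = 10_000
        fit = fit_distribution(national.prevalence)
        xs = np.array([fit.sample(rng) for _ in range(n)])
        sd = (national.prevalence.high - national.prevalence.low) / 3.92
        assert abs(xs.mean() - 0.17) <= 3 * sd / np.sqrt(n)

    def test_arm_invariant_transitions_share_draws_by_default(self, national):
        """Natural recovery and mortality (printed identically in both arms)
        get one draw; identification rates differ by arm."""
        draw, _ = sample_parameter_set(national, np.random.default_rng(3))
        c, i = draw.exit_probs("control", "U"), draw.exit_probs("intervention", "U")
        assert c["N"] == i["N"] and c["D"] == i["D"]
        assert c["A"] != i["A"]
        assert draw.exit_probs("control", "A") == draw.exit_probs("intervention", "A")

    def test_independent_arms_mode_decouples(self, national):
        p = national.copy()
        p.psa_independent_arms = True
        draw, _ = sample_parameter_set(p, np.random.default_rng(3))
        assert draw.exit_probs("control", "U")["N"] != draw.exit_probs(
            "intervention", "U"
        )["N"]

    def test_true_dirichlet_rows_are_valid(self, national):
        p = national.copy()
        p.dirichlet_mode = "true_dirichlet"
        rng = np.random.default_rng(13)
        for _ in range(20):
            draw, _ = sample_parameter_set(p, rng)
            assert draw.validate() == []

    def test_infeasible_rows_repaired_and_logged(self, national, rng):
        p = national.copy()
        # an extreme spec that frequently draws exit sums at or past 1
        p.exits["control"]["U"]["N"] = DistributionSpec("uniform", 0.9, 0.85, 0.99)
        p.exits["control"]["U"]["D"] = DistributionSpec("uniform", 0.09, 0.05, 0.14)
        p.psa_independent_arms = True
        repaired = 0
        for _ in range(50):
            draw, audit = sample_parameter_set(p, rng)
            assert draw.validate() == []
            repaired += any("exits.control.U" in a for a in audit)
        assert repaired > 0


class TestOwsa:
    def test_degenerate_range_reproduces_base_nmb(self, national):
        base = run_base_case(national)
        entries = owsa(national, overrides={"prevalence": (0.17, 0.17)})
        e = next(x for x in entries if x.parameter == "prevalence")
        assert e.nmb_at_low == pytest.approx(base.nmb, abs=1e-9)
        assert e.nmb_at_high == pytest.approx(base.nmb, abs=1e-9)

    def test_published_recovery_variation(self, national):
        """Control-arm recovery varied over the published 0.049–0.051 range
        moves the NMB from about £110 down through about −£26."""
        entries = owsa(national, overrides={"exits.control.U.N": (0.049, 0.051)})
        e = next(x for x in entries if x.parameter == "exits.control.U.N")
        assert e.nmb_at_low == pytest.approx(110, abs=35)
        assert e.nmb_at_high == pytest.approx(-26, abs=35)

    def test_limits_bracket_base_nmb_for_monotone_response(self, national):
        base = run_base_case(national).nmb
        entries = owsa(national)
        e = next(x for x in entries if x.parameter == "cost_abuse_per_cycle")
        assert min(e.nmb_at_low, e.nmb_at_high) <= base <= max(e.nmb_at_low, e.nmb_at_high)

    def test_sorted_by_span_descending(self, national):
        entries = owsa(national)
        spans = [e.span for e in entries if e.feasible]
        assert spans == sorted(spans, reverse=True)

    def test_infeasible_limit_flagged_not_clamped(self, national):
        entries = owsa(national, overrides={"exits.control.U.N": (0.05, 1.5)})
        e = next(x for x in entries if x.parameter == "exits.control.U.N")
        assert not e.feasible
        assert np.isnan(e.nmb_at_high)

    def test_all_fixed_specs_empty_tornado(self, national):
        assert owsa(shrink_uncertainty(national, 0.0)) == []


class TestPsa:
    def test_all_fixed_equals_base_case(self, national):
        p = shrink_uncertainty(national, 0.0)
        base = run_base_case(p)
        psa = run_psa(p, n_sim=5, seed=1)
        assert np.allclose(psa.incremental_cost, base.incremental_cost)
        assert np.allclose(psa.incremental_qaly, base.incremental_qaly)
        assert psa.fraction_cost_effective() in (0.0, 1.0)

    def test_seeded_reproducibility_bit_exact(self, national):
        a = run_psa(national, n_sim=40, seed=123)
        b = run_psa(national, n_sim=40, seed=123)
        assert np.array_equal(a.incremental_cost, b.incremental_cost)
        assert np.array_equal(a.incremental_qaly, b.incremental_qaly)
        assert a.fraction_cost_effective() == b.fraction_cost_effective()
        assert a.percentile_intervals() == b.percentile_intervals()

    def test_near_degenerate_variance_collapses_to_base(self, national):
        """Shrinking all 95% limits by 1e-4 makes the PSA mean reproduce the
        deterministic base case within 3 standard errors."""
        p = shrink_uncertainty(national, 1e-4)
        base = run_base_case(p)
        psa = run_psa(p, n_sim=200, seed=9)
        for samples, target in (
            (psa.incremental_cost, base.incremental_cost),
            (psa.incremental_qaly, base.incremental_qaly),
        ):
            se = samples.std(ddof=1) / np.sqrt(samples.size)
            assert abs(samples.mean() - target) <= 3 * se + 1e-12

    def test_dominance_fractions_bounded(self, national):
        psa = run_psa(national, n_sim=100, seed=2)
        assert 0 <= psa.fraction_dominant <= 1
        assert 0 <= psa.fraction_dominated <= 1
        assert psa.fraction_dominant + psa.fraction_dominated <= 1


class TestCeacAndIntervals:
    def _hand_psa(self):
        return PsaResult(
            incremental_cost=np.array([-50.0, -10.0, 5.0, 20.0, 100.0]),
            incremental_qaly=np.array([0.002, -0.001, 0.001, 0.004, -0.002]),
            seed=0,
            wtp=20_000.0,
            wtp_grid=(0.0, 10_000.0, 20_000.0),
        )

    def test_curve_matches_hand_count(self):
        """NMB > 0 counted by hand for five simulations at three thresholds."""
        psa = self._hand_psa()
        curve = dict(ceac(psa, [0, 10_000, 20_000]))
        # wtp 0: nmb = -dc > 0 for the two cost-saving draws
        assert curve[0] == pytest.approx(2 / 5)
        # wtp 10k: nmb = [70, -20, 5, 20, -120] -> 3 positive
        assert curve[10_000] == pytest.approx(3 / 5)
        # wtp 20k: nmb = [90, -30, 15, 60, -140] -> 3 positive
        assert curve[20_000] == pytest.approx(3 / 5)

    def test_always_dominant_curve_is_one(self):
        psa = PsaResult(
            incremental_cost=np.array([-5.0, -1.0]),
            incremental_qaly=np.array([0.01, 0.02]),
            seed=0,
            wtp=20_000.0,
            wtp_grid=(0.0,),
        )
        assert all(p == 1.0 for _, p in ceac(psa, [0, 20_000, 50_000]))

    def test_monotone_when_all_qaly_gains_positive(self, national):
        psa = run_psa(national, n_sim=150, seed=4)
        keep = psa.incremental_qaly >= 0
        sub = PsaResult(
            incremental_cost=psa.incremental_cost[keep],
            incremental_qaly=psa.incremental_qaly[keep],
            seed=4,
            wtp=20_000.0,
            wtp_grid=(0.0,),
        )
        probs = [p for _, p in ceac(sub, range(0, 50_001, 5000))]
        assert np.all(np.diff(probs) >= 0)

    def test_rejects_bad_grid(self):
        with pytest.raises(ValueError):
            ceac(self._hand_psa(), [])

    def test_percentile_linear_interpolation_convention(self):
        lo, hi = percentile_interval(np.arange(1, 1001, dtype=float))
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    def test_percentile_constant_samples(self):
        assert percentile_interval([3.3, 3.3, 3.3]) == (3.3, 3.3)

    def test_percentile_permutation_invariant(self, rng):
        xs = rng.normal(size=500)
        assert percentile_interval(xs) == percentile_interval(rng.permutation(xs))
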