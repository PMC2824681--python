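"""Tests for the epidemiological-input -> coefficient solver."""

import math

import numpy as np
import pytest

from gxesim import (
    EnvironmentDistribution,
    InconsistentSpecError,
    InfeasibleParametersError,
    InteractionModel,
    MLMCoefficients,
    heterozygote_rr,
    logit,
    random_valid_spec,
    solve_am,
    solve_coefficients,
    solve_em,
    solve_gem,
    solve_gm,
    target_total_risks,
    total_risk,
    validate_constraints,
)
from conftest import make_spec


class TestTargetTotalRisks:
    def test_no_genetic_effect_gives_flat_risks(self):
        trs = target_total_risks(0.1, (0.25, 0.5, 0.25), rr31=1.0, w=0.3)
        assert trs == pytest.approx((0.1, 0.1, 0.1), abs=1e-15)

    def test_dominant_case(self):
        # TR1 = 0.1 / (0.25 + 0.5*3 + 0.25*3) = 0.04
        trs = target_total_risks(0.1, (0.25, 0.5, 0.25), rr31=3.0, w=1.0)
        assert trs == pytest.approx((0.04, 0.12, 0.12), abs=1e-14)

    def test_recessive_case_conserves_m(self):
        # RR21 = 1: TR1 = 0.1 / (0.25 + 0.5 + 0.75) = 1/15, TR3 = 0.2
        trs = target_total_risks(0.1, (0.25, 0.5, 0.25), rr31=3.0, w=0.0)
        assert trs == pytest.approx((1 / 15, 1 / 15, 0.2), abs=1e-14)
        # brute-force weighted-sum oracle
        assert np.dot((0.25, 0.5, 0.25), trs) == pytest.approx(0.1, abs=1e-15)

    def test_conservation_on_random_inputs(self, rng):
        for _ in range(200):
            p = rng.dirichlet(np.ones(3))
            m = float(rng.uniform(0.01, 0.4))
            rr31 = float(rng.uniform(1, 5))
            w = float(rng.uniform(0, 1))
            try:
                trs = target_total_risks(m, p, rr31, w)
            except InfeasibleParametersError:
                continue
            assert float(np.dot(p, trs)) == pytest.approx(m, abs=1e-12)
            assert trs[1] / trs[0] == pytest.approx(
                heterozygote_rr(rr31, w), rel=1e-12
            )

    def test_infeasible_when_m_too_large(self):
        with pytest.raises(InfeasibleParametersError):
            target_total_risks(0.5, (0.9, 0.08, 0.02), rr31=5.0, w=0.0)


class TestGM:
    def test_closed_form_logits(self, std_normal_env):
        spec = make_spec("GM", m=0.1, rr31=3.0, w=1.0, env=std_normal_env)
        res = solve_gm(spec)
        assert res.coefficients.beta == (0.0, 0.0, 0.0)
        assert res.coefficients.alpha == pytest.approx(
            tuple(logit(t) for t in (0.04, 0.12, 0.12)), abs=1e-12
        )

    def test_degenerate_no_effect(self, std_normal_env):
        spec = make_spec("GM", rr31=1.0, w=0.0, env=std_normal_env)
        res = solve_gm(spec)
        assert len(set(res.coefficients.alpha)) == 1

    def test_env_is_irrelevant(self, two_point_env, std_normal_env):
        s1 = make_spec("GM", env=two_point_env)
        s2 = make_spec("GM", env=std_normal_env)
        assert solve_gm(s1).coefficients == solve_gm(s2).coefficients


class TestEM:
    def test_point_mass_env_gives_logit_m(self):
        env = EnvironmentDistribution.point_mass(0.0)
        spec = make_spec("EM", m=0.2, rr31=1.0, env=env, env_or=2.0)
        res = solve_em(spec)
        assert res.coefficients.alpha[0] == pytest.approx(logit(0.2), abs=1e-9)

    def test_two_point_worked_example(self, two_point_env):
        spec = make_spec("EM", m=0.625, rr31=1.0, env=two_point_env, env_or=3.0)
        res = solve_em(spec)
        assert res.coefficients.alpha[0] == pytest.approx(0.0, abs=1e-9)
        assert res.coefficients.beta[0] == pytest.approx(math.log(3), abs=1e-12)

    def test_rejects_genetic_effect(self, std_normal_env):
        spec = make_spec("EM", rr31=3.0, env=std_normal_env)
        with pytest.raises(InconsistentSpecError):
            solve_em(spec)

    def test_rejects_null_odds_ratio(self, std_normal_env):
        spec = make_spec("EM", rr31=1.0, env=std_normal_env, env_or=1.0)
        with pytest.raises(InconsistentSpecError):
            solve_em(spec)


class TestAM:
    def test_self_consistency_against_quadrature(self, std_normal_env):
        spec = make_spec("AM", m=0.1, rr31=3.0, w=0.5, env=std_normal_env,
                         env_or=1.5)
        res = solve_am(spec)
        beta = res.coefficients.beta[0]
        assert beta == pytest.approx(math.log(1.5), abs=1e-12)
        for alpha, target in zip(res.coefficients.alpha, res.target_trs):
            assert total_risk(alpha, beta, std_normal_env) == pytest.approx(
                target, abs=1e-8
            )

    def test_alpha_ordering_follows_risk_ordering(self, std_normal_env):
        res = solve_am(make_spec("AM", rr31=4.0, w=0.3, env=std_normal_env))
        a = res.coefficients.alpha
        assert a[0] < a[1] < a[2]

    def test_rejects_null_odds_ratio(self, std_normal_env):
        with pytest.raises(InconsistentSpecError):
            solve_am(make_spec("AM", env=std_normal_env, env_or=1.0))

    def test_small_beta_limit_approaches_gm(self, std_normal_env):
        res = solve_am(make_spec("AM", env=std_normal_env, env_or=1.0001))
        gm = solve_gm(make_spec("GM", env=std_normal_env))
        assert res.coefficients.alpha == pytest.approx(gm.coefficients.alpha, abs=1e-3)


class TestGEM:
    def test_equal_total_risks_force_equal_slopes(self):
        env = EnvironmentDistribution.uniform_dist(0.0, 2.0)
        res = solve_gem(make_spec("GEM", rr31=3.0, w=1.0, env=env, env_or=1.5))
        b = res.coefficients.beta
        assert b[1] == pytest.approx(b[2], abs=1e-8)
        assert b[0] == pytest.approx(math.log(1.5), abs=1e-12)

    def test_no_genetic_effect_reduces_to_shared_slope(self):
        env = EnvironmentDistribution.uniform_dist(0.0, 2.0)
        res = solve_gem(make_spec("GEM", rr31=1.0, w=0.0, env=env, env_or=1.5))
        b = res.coefficients.beta
        assert b[0] == pytest.approx(b[1], abs=1e-8)
        assert b[1] == pytest.approx(b[2], abs=1e-8)

    def test_conservation_of_m(self):
        env = EnvironmentDistribution.discrete_dist([0, 1, 2], [0.5, 0.3, 0.2])
        spec = make_spec("GEM", m=0.15, rr31=2.5, w=0.4, env=env, env_or=1.3)
        res = solve_gem(spec)
        c = res.coefficients
        total = sum(
            p * total_risk(c.alpha[i], c.beta[i], env)
            for i, p in enumerate(spec.causal_genotype_freqs)
        )
        assert total == pytest.approx(0.15, abs=1e-8)

    def test_rejects_negative_support(self, std_normal_env):
        with pytest.raises(InconsistentSpecError, match="nonnegative"):
            solve_gem(make_spec("GEM", env=std_normal_env))


class TestDispatchAndConstraints:
    def test_one_gene_model_yields_three_pairs(self, std_normal_env):
        res = solve_coefficients(make_spec("AM", env=std_normal_env))
        assert len(res.coefficients.pairs()) == 3

    def test_custom_model_is_not_solved(self, std_normal_env):
        with pytest.raises(InconsistentSpecError, match="CUSTOM"):
            solve_coefficients(make_spec("CUSTOM", env=std_normal_env))

    @pytest.mark.parametrize(
        "alpha, beta, model, ok",
        [
            ((1, 1, 1), (0.2, 0.5, 0.9), "GEM", True),
            ((1, 2, 3), (0.1, 0.1, 0.1), "GEM", False),
            ((1, 1, 2), (0, 0, 0), "GM", True),
            ((1, 2, 3), (0.1, 0.1, 0.1), "AM", True),
            ((3, 2, 1), (0.1, 0.1, 0.1), "AM", False),
            ((1, 1, 1), (0.5, 0.5, 0.5), "EM", True),
            ((1, 1, 1), (0, 0, 0), "EM", False),  # EM needs a non-null slope
        ],
    )
    def test_constraint_patterns(self, alpha, beta, model, ok):
        coeffs = MLMCoefficients(alpha=alpha, beta=beta)
        violations = validate_constraints(coeffs, InteractionModel(model))
        assert (not violations) is ok

    def test_all_violations_reported(self):
        coeffs = MLMCoefficients(alpha=(3, 2, 1), beta=(1, 2, 3))
        violations = validate_constraints(coeffs, InteractionModel.AM)
        assert len(violations) == 2


class TestSolverProperties:
    def test_conservation_and_rr_fidelity_randomized(self):
        """Eq. of state: sum_i P_i TR_i = m and TR ratios hit RR21/RR31."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            spec = random_valid_spec(rng)
            res = solve_coefficients(spec)
            c = res.coefficients
            env = spec.causal_env
            total = sum(
                p * total_risk(c.alpha[i], c.beta[i], env)
                for i, p in enumerate(spec.causal_genotype_freqs)
            )
            assert total == pytest.approx(spec.disease_freq, abs=1e-8)
            rr21 = res.achieved_trs[1] / res.achieved_trs[0]
            rr31 = res.achieved_trs[2] / res.achieved_trs[0]
            assert rr21 == pytest.approx(
                heterozygote_rr(spec.rr31, spec.w), rel=1e-6
            )
            assert rr31 == pytest.approx(spec.rr31, rel=1e-6)
            assert 1.0 - 1e-9 <= rr21 <= spec.rr31 + 1e-9

    def test_point_mass_closed_form_limit(self):
        """With exposure fixed at 0 every solver's alphas are logit(TR_i)."""
        env = EnvironmentDistribution.point_mass(0.0)
        cases = [
            ("GM", {"rr31": 2.0, "w": 0.5}),
            ("AM", {"rr31": 2.0, "w": 0.5, "env_or": 1.5}),
            # GEM slopes cannot move a point mass at zero, so only the
            # equal-risk case is feasible there
            ("GEM", {"rr31": 1.0, "w": 0.0, "env_or": 1.5}),
        ]
        for model, kw in cases:
            spec = make_spec(model, m=0.1, env=env, **kw)
            res = solve_coefficients(spec)
            expected = tuple(logit(t) for t in res.target_trs)
            assert res.coefficients.alpha == pytest.approx(expected, abs=1e-9)

    def test_discrete_env_residuals_by_exhaustive_sum(self):
        """Residuals recomputed by plain weighted sums, independent of quadrature."""
        from gxesim.mlm import logistic

        env = EnvironmentDistribution.discrete_dist([0, 1, 2], [0.2, 0.5, 0.3])
        spec = make_spec("GEM", m=0.12, rr31=2.0, w=0.5, env=env, env_or=1.4)
        res = solve_coefficients(spec)
        c = res.coefficients
        for i, target in enumerate(res.target_trs):
            brute = sum(
                p * logistic(c.alpha[i] + c.beta[i] * x)
                for x, p in zip(env.values, env.probs)
            )
            assert brute == pytest.approx(target, abs=1e-8)

    def test_determinism(self, std_normal_env):
        spec = make_spec("AM", env=std_normal_env)
        r1 = solve_coefficients(spec)
        r2 = solve_coefficients(spec)
        assert r1.coefficients == r2.coefficients
        assert r1.achieved_trs == r2.achieved_trs


class TestGEMPointMassInfeasibility:
    def test_unreachable_slope_reported(self):
        # a point mass at 0 makes beta powerless: distinct TRs are unreachable
        env = EnvironmentDistribution.point_mass(0.0)
        with pytest.raises(InfeasibleParametersError):
            solve_gem(make_spec("GEM", rr31=3.0, w=0.5, env=env, env_or=1.5))
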