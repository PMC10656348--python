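import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from irtpower import (ItemParametrization, LinearHypothesis, MarginalModel,
                      compute_ncps, dif_first_item, expected_fisher,
                      rasch_vs_2pl, restricted_parameters)
from irtpower.analytic import (ncp_gradient, ncp_lr, ncp_score, ncp_wald,
                               outer_product_information)

# Frozen values from an independent brute-force oracle for a 3-item 2PL
# alternative (adaptive quadrature for every pattern probability, dense
# finite-difference Fisher matrix, Nelder-Mead restricted optimization).
ORACLE_BETA = np.array([0.8, 0.3, 1.3, -0.4, 1.0, 0.1])
ORACLE_LAMBDAS = {
    "wald": 0.0020901607070538644,
    "lr": 0.002168032049351676,
    "score": 0.0021690776354947316,
    "gradient": 0.002231411203419091,
}


@pytest.fixture(scope="module")
def ncp_3item():
    m = MarginalModel(ItemParametrization("two_pl", 3), ORACLE_BETA)
    return compute_ncps(m, rasch_vs_2pl(3))


class TestBruteForceOracle:
    def test_all_four_lambdas_match_independent_implementation(self, ncp_3item):
        for stat, expected in ORACLE_LAMBDAS.items():
            assert ncp_3item.lambdas[stat] == pytest.approx(expected, rel=1e-5), stat

    def test_two_item_equal_slope_test_is_degenerate(self):
        """With 2 items the 2PL has more parameters than the pattern simplex
        has dimensions: the restricted model fits the alternative exactly and
        every noncentrality parameter is zero."""
        m = MarginalModel(ItemParametrization("two_pl", 2), [0.8, 0.3, 1.3, -0.4])
        h = rasch_vs_2pl(2)
        r = restricted_parameters(m, h)
        assert ncp_lr(m, h, r) < 1e-8
        assert abs(ncp_gradient(m, h, r)) < 1e-8


class TestNullBehaviour:
    def test_all_lambdas_zero_under_null(self):
        beta = np.array([1.2, 0.5, 1.2, -0.3, 1.2, 0.8])
        m = MarginalModel(ItemParametrization("two_pl", 3), beta)
        ncp = compute_ncps(m, rasch_vs_2pl(3))
        for stat, lam in ncp.lambdas.items():
            assert abs(lam) < 1e-8, stat

    def test_restricted_returns_beta_itself_on_null(self):
        beta = np.array([1.2, 0.5, 1.2, -0.3, 1.2, 0.8])
        m = MarginalModel(ItemParametrization("two_pl", 3), beta)
        r = restricted_parameters(m, rasch_vs_2pl(3))
        np.testing.assert_allclose(r.beta_r, beta, atol=1e-6)

    def test_scaling_in_n_is_exact(self, ncp_3item):
        at = ncp_3item.at_n(1000)
        for stat, lam in ncp_3item.lambdas.items():
            assert at[stat] == pytest.approx(1000 * lam, rel=1e-15)


class TestExpectedInformation:
    def test_symmetric_and_positive_definite(self, model_2pl_5):
        info = expected_fisher(model_2pl_5)
        assert np.max(np.abs(info.matrix - info.matrix.T)) < 1e-8
        assert info.min_eigenvalue > 0

    def test_agrees_with_outer_product_form(self, model_2pl_5):
        info = expected_fisher(model_2pl_5)
        assert np.max(np.abs(info.matrix - outer_product_information(model_2pl_5))) < 1e-4

    def test_single_item_intercept_information_scalar_oracle(self):
        """For one item with a=1, d=0 the marginal response is Bernoulli(g)
        with g = int p phi; its information for d is (dg/dd)^2 / (g(1-g))."""
        m = MarginalModel(ItemParametrization("two_pl", 1), [1.0, 0.0])
        info = expected_fisher(m)
        g = quad(lambda t: norm.pdf(t) / (1 + np.exp(-t)), -10, 10)[0]
        dg = quad(lambda t: norm.pdf(t) * np.exp(-t) / (1 + np.exp(-t)) ** 2, -10, 10)[0]
        expected = dg * dg / (g * (1 - g))
        assert info.matrix[1, 1] == pytest.approx(expected, rel=1e-6)

    def test_dif_anchor_block_matches_single_group(self):
        """With identical item-1 parameters and equal groups, the anchor-item
        information block equals the single-group model's block."""
        beta_dif = np.array([1.1, 0.2, 1.1, 0.2, 0.9, -0.4, 1.3, 0.6])
        beta_one = np.array([1.1, 0.2, 0.9, -0.4, 1.3, 0.6])
        info_d = expected_fisher(MarginalModel(
            ItemParametrization("dif_two_group", 3), beta_dif)).matrix
        info_s = expected_fisher(MarginalModel(
            ItemParametrization("two_pl", 3), beta_one)).matrix
        np.testing.assert_allclose(info_d[4:, 4:], info_s[2:, 2:], atol=1e-6)


class TestRestrictedParameters:
    def test_common_slope_between_alternative_slopes(self):
        beta = np.array([0.8, 0.3, 1.2, 0.3, 1.0, 0.3])
        m = MarginalModel(ItemParametrization("two_pl", 3), beta)
        r = restricted_parameters(m, rasch_vs_2pl(3))
        assert r.converged
        slope = r.beta_r[0]
        assert 0.8 < slope < 1.2
        np.testing.assert_allclose(r.beta_r[0::2], slope, rtol=1e-10)

    def test_restricted_objective_is_a_maximum(self):
        beta = np.array([0.8, 0.3, 1.2, -0.5, 1.0, 0.1])
        m = MarginalModel(ItemParametrization("two_pl", 3), beta)
        h = rasch_vs_2pl(3)
        r = restricted_parameters(m, h)
        pats, grp = m.pattern_space()
        g = m.prob()
        rng = np.random.default_rng(4)
        from irtpower.analytic import project_onto_null
        for _ in range(20):
            other = project_onto_null(h, r.beta_r + rng.normal(scale=0.05, size=6))
            assert g @ m.logprob(pats, grp, beta=other) <= r.objective + 1e-10

    def test_dif_restricted_satisfies_constraint_exactly(self):
        beta = np.array([1.2, 0.5, 1.0, 0.96, 0.9, -0.4, 1.3, 0.6])
        m = MarginalModel(ItemParametrization("dif_two_group", 3), beta)
        r = restricted_parameters(m, dif_first_item(3))
        assert r.beta_r[0] == pytest.approx(r.beta_r[2], abs=1e-12)
        assert r.beta_r[1] == pytest.approx(r.beta_r[3], abs=1e-12)


class TestInvarianceAndEquivalence:
    def test_wald_and_gradient_invariant_under_reparametrization(self, ncp_3item):
        m = MarginalModel(ItemParametrization("two_pl", 3), ORACLE_BETA)
        h = rasch_vs_2pl(3)
        rng = np.random.default_rng(12)
        info = expected_fisher(m)
        r = restricted_parameters(m, h)
        for _ in range(5):
            C = rng.normal(size=(h.df, h.df))
            while abs(np.linalg.det(C)) < 1e-3:
                C = rng.normal(size=(h.df, h.df))
            h2 = LinearHypothesis(C @ h.A, C @ h.c)
            w2 = ncp_wald(m, h2, info)
            g2 = ncp_gradient(m, h2, r)
            assert w2 == pytest.approx(ncp_3item.lambdas["wald"], rel=1e-8)
            assert g2 == pytest.approx(ncp_3item.lambdas["gradient"], rel=1e-8)

    def test_lambda_ratios_converge_for_vanishing_effect(self):
        """All four statistics are asymptotically equivalent: for a shrinking
        one-parameter family of alternatives the lambda ratios approach 1."""
        base = np.array([1.0, 0.3, 1.0, -0.4, 1.0, 0.1])
        direction = np.zeros(6)
        direction[[0, 2]] = [1.0, -1.0]
        h = rasch_vs_2pl(3)
        eps = 0.05
        m = MarginalModel(ItemParametrization("two_pl", 3), base + eps * direction)
        lam = compute_ncps(m, h).lambdas
        vals = np.array(list(lam.values()))
        assert np.max(vals) / np.min(vals) < 1.05

    def test_lambda_nonnegative_for_random_alternatives(self):
        rng = np.random.default_rng(21)
        p = ItemParametrization("two_pl", 3)
        h = rasch_vs_2pl(3)
        for _ in range(10):
            beta = rng.normal(scale=0.6, size=6)
            beta[0::2] = np.abs(beta[0::2]) + 0.4
            ncp = compute_ncps(MarginalModel(p, beta), h)
            for stat, lam in ncp.lambdas.items():
                assert lam >= -1e-10, stat
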