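import numpy as np
import pytest
from scipy.stats import chi2

from irtpower import (ItemParametrization, LinearHypothesis, MarginalModel,
                      ResponseData, compute_ncps, fit_mml,
                      observed_gradient, observed_lr, observed_statistics,
                      observed_wald, rasch_vs_2pl, sampling_ncp,
                      simulate_responses)
from irtpower.fitting import covariance_at, total_score


@pytest.fixture(scope="module")
def rasch_data():
    """n=2000 responses from a 5-item Rasch model (common slope 1)."""
    beta = np.empty(10)
    beta[0::2] = 1.0
    beta[1::2] = [0.5, -0.3, 0.1, 0.9, -0.7]
    p = ItemParametrization("two_pl", 5)
    return simulate_responses(beta, p, n=2000, seed=99), p, beta


class TestResponseData:
    def test_pattern_counts_sum_to_n(self, rasch_data):
        data, _, _ = rasch_data
        assert data.pattern_counts.sum() == data.n_persons

    def test_csv_round_trip_with_groups(self, tmp_path):
        rng = np.random.default_rng(0)
        data = ResponseData(rng.integers(0, 2, size=(50, 4)), rng.integers(0, 2, 50))
        path = tmp_path / "resp.csv"
        data.to_csv(path)
        back = ResponseData.from_csv(path)
        np.testing.assert_array_equal(back.responses, data.responses)
        np.testing.assert_array_equal(back.group, data.group)

    def test_rejects_negative_categories(self):
        with pytest.raises(ValueError):
            ResponseData(np.array([[0, -1]]))


class TestFitMml:
    def test_pattern_collapsed_equals_rowwise_likelihood(self, rasch_data):
        data, p, beta = rasch_data
        m = MarginalModel(p, beta)
        by_pattern = float(data.pattern_counts @ m.logprob(data.patterns, data.pattern_groups))
        by_row = float(np.sum(m.logprob(data.responses, None)))
        assert by_pattern == pytest.approx(by_row, rel=1e-12)

    def test_parameter_recovery_large_sample(self):
        beta = np.empty(10)
        beta[0::2] = [0.8, 1.1, 1.25, 0.9, 1.43]
        beta[1::2] = [0.5, -0.3, 0.1, 0.9, -0.7]
        p = ItemParametrization("two_pl", 5)
        data = simulate_responses(beta, p, n=100_000, seed=5)
        fit = fit_mml(data, p)
        assert fit.converged
        assert np.max(np.abs(fit.beta_hat - beta)) < 0.05

    def test_constrained_fit_has_equal_slopes(self, rasch_data):
        data, p, _ = rasch_data
        fit = fit_mml(data, p, constraint=rasch_vs_2pl(5))
        slopes = fit.beta_hat[0::2]
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-12)

    def test_nesting_inequality(self, rasch_data):
        data, p, _ = rasch_data
        full = fit_mml(data, p)
        restr = fit_mml(data, p, constraint=rasch_vs_2pl(5))
        assert full.loglik >= restr.loglik - 1e-8

    def test_dif_fit_requires_groups(self):
        p = ItemParametrization("dif_two_group", 3)
        data = ResponseData(np.zeros((10, 3), dtype=int) + np.eye(3, dtype=int)[0])
        with pytest.raises(ValueError):
            fit_mml(data, p)


class TestObservedStatistics:
    def test_wald_zero_when_estimates_satisfy_null(self, rasch_data):
        data, p, _ = rasch_data
        h = rasch_vs_2pl(5)
        fit = fit_mml(data, p, constraint=h)  # estimates satisfy A beta = c
        cov = covariance_at(fit, data)
        assert observed_wald(fit, h, cov) == pytest.approx(0.0, abs=1e-12)

    def test_lr_zero_for_identical_fits(self, rasch_data):
        data, p, _ = rasch_data
        fit_r = fit_mml(data, p, constraint=rasch_vs_2pl(5))
        assert observed_lr(fit_r, fit_r) == 0.0

    def test_restricted_score_lies_in_row_space(self, rasch_data):
        """At the restricted optimum the total score is orthogonal to the
        null space of A, so the Lagrange system A'k = s is consistent."""
        data, p, _ = rasch_data
        h = rasch_vs_2pl(5)
        fit_r = fit_mml(data, p, constraint=h)
        s = total_score(fit_r, data)
        k, *_ = np.linalg.lstsq(h.A.T, s, rcond=None)
        assert np.max(np.abs(h.A.T @ k - s)) < 1e-3 * max(1.0, np.abs(s).max())

    def test_wald_and_gradient_invariant_under_reparametrization(self, rasch_data):
        data, p, _ = rasch_data
        h = rasch_vs_2pl(5)
        stats = observed_statistics(data, p, h)
        rng = np.random.default_rng(8)
        C = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        h2 = LinearHypothesis(C @ h.A, C @ h.c)
        stats2 = observed_statistics(data, p, h2)
        assert stats2["wald"] == pytest.approx(stats["wald"], rel=1e-6)
        assert stats2["gradient"] == pytest.approx(stats["gradient"], rel=1e-6)

    def test_null_batch_means_near_df(self):
        """Over null-generated datasets each statistic is asymptotically
        central chi-square with df = I-1, so its mean should be near df."""
        n_reps, n, I = 200, 1000, 5
        p = ItemParametrization("two_pl", I)
        h = rasch_vs_2pl(I)
        rng = np.random.default_rng(31)
        sums = {s: 0.0 for s in ("wald", "lr", "score", "gradient")}
        for _ in range(n_reps):
            beta = np.empty(2 * I)
            beta[0::2] = 1.0
            beta[1::2] = rng.standard_normal(I)
            data = simulate_responses(beta, p, n=n, seed=rng)
            for s, v in observed_statistics(data, p, h).items():
                sums[s] += v
        se = np.sqrt(2 * h.df / n_reps)  # SD of a chi2_df mean
        for s, total in sums.items():
            assert total / n_reps == pytest.approx(h.df, abs=4 * se), s


class TestSamplingNcp:
    def test_null_beta_gives_near_zero_lambda(self):
        p = ItemParametrization("two_pl", 5)
        beta = np.empty(10)
        beta[0::2] = 1.0
        beta[1::2] = [0.5, -0.3, 0.1, 0.9, -0.7]
        ncp = sampling_ncp(beta, p, rasch_vs_2pl(5), n_artificial=100_000, seed=2)
        for s, lam in ncp.lambdas.items():
            assert lam <= 3 * 4 / 100_000, s

    def test_converges_to_analytical(self, model_2pl_5, beta_2pl_5):
        h = rasch_vs_2pl(5)
        ana = compute_ncps(model_2pl_5, h).lambdas
        p = ItemParametrization("two_pl", 5)
        # average a few moderate-size draws; MC error ~ sqrt(4 n lam)/n
        lams = {s: [] for s in ana}
        for seed in range(4):
            smp = sampling_ncp(beta_2pl_5, p, h, n_artificial=100_000, seed=seed)
            for s, v in smp.lambdas.items():
                lams[s].append(v)
        for s in ana:
            mc_se = np.sqrt(2 * 4 + 4 * 100_000 * ana[s]) / 100_000 / 2
            assert np.mean(lams[s]) == pytest.approx(ana[s], abs=4 * mc_se), s

    def test_seed_stability_at_large_n(self, model_2pl_5, beta_2pl_5):
        """Two independent draws at n_artificial = 1e6 agree within the
        noncentral chi-square Monte-Carlo error bound."""
        p = ItemParametrization("two_pl", 5)
        h = rasch_vs_2pl(5)
        n_art = 1_000_000
        ana = compute_ncps(model_2pl_5, h).lambdas
        a = sampling_ncp(beta_2pl_5, p, h, n_artificial=n_art, seed=1)
        b = sampling_ncp(beta_2pl_5, p, h, n_artificial=n_art, seed=2)
        for s in a.lambdas:
            # var(S) = 2(df + 2 n lambda); two independent draws
            bound = 4 * np.sqrt(2 * (2 * h.df + 4 * n_art * ana[s])) / n_art
            assert abs(a.lambdas[s] - b.lambdas[s]) < bound, s
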