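"""Marginal maximum likelihood fitting and the observed test statistics.

Fitting maximizes the pattern-collapsed marginal log-likelihood
``sum_x h(x) log g_beta(x)`` (h = observed pattern frequencies) by
quasi-Newton iteration with the analytic gradient; equality constraints
(e.g. the common Rasch slope) are handled by optimizing in a null-space
coordinate system of {beta : A beta = c}. This targets exactly the same
maximizer as a Bock-Aitkin EM run to convergence and is fast at the
pattern-space sizes where the observed statistics are computed.

The observed statistics for a dataset X~ with pattern frequencies h:

* Wald:     S1 = (A bh - c)' [A Sigma(bh, X~) A']^{-1} (A bh - c)
* LR:       S2 = 2 (loglik(unrestricted) - loglik(restricted))
* score:    S3 = s' Sigma(bhr, X~) s with s the total score at the
              restricted estimates
* gradient: S4 = k' (A bh - c) with s = -A'k; no information matrix needed

For the covariance in S1/S3 the expected Fisher information evaluated at
the estimates is used whenever the pattern space is enumerable (``Sigma =
[n I_F(b, 1)]^{-1}``); otherwise the empirical cross-product of per-person
scores serves as the information estimate. Both converge to the expected
Fisher information in large samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import logit

from .analytic import (NCPResult, _null_space_coords, expected_fisher,
                       project_onto_null)
from .families import ItemParametrization, LatentDistribution
from .hypotheses import LinearHypothesis
from .marginal import (MAX_ENUMERABLE_PATTERNS, MarginalModel,
                       pattern_space_size)

logger = logging.getLogger(__name__)


@dataclass
class ResponseData:
    """A person-by-item integer response matrix, pattern-collapsed.

    ``responses`` holds 0-based categories; ``group`` optionally labels each
    person 0/1 for the two-group DIF design.
    """

    responses: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.int64)
        if self.responses.ndim != 2 or self.responses.size == 0:
            raise ValueError("responses must be a nonempty n x I matrix")
        if np.any(self.responses < 0):
            raise ValueError("responses must be 0-based nonnegative categories")
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=np.int64)
            if self.group.shape != (self.responses.shape[0],):
                raise ValueError("group must have one label per person")
        self._collapse()

    def _collapse(self) -> None:
        rows = self.responses
        if self.group is not None:
            rows = np.column_stack([self.group, rows])
        uniq, counts = np.unique(rows, axis=0, return_counts=True)
        if self.group is not None:
            self.pattern_groups = uniq[:, 0]
            self.patterns = uniq[:, 1:]
        else:
            self.pattern_groups = None
            self.patterns = uniq
        self.pattern_counts = counts.astype(float)

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_categories(self) -> int:
        return int(self.responses.max()) + 1

    # -- CSV round trip -------------------------------------------------
    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.responses,
                          columns=[f"item{i+1}" for i in range(self.n_items)])
        if self.group is not None:
            df.insert(0, "group", self.group)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ResponseData":
        df = pd.read_csv(path)
        group = None
        if "group" in df.columns:
            group = df.pop("group").to_numpy()
        return cls(df.to_numpy(), group)


@dataclass
class FitResult:
    """A converged (or flagged) MML fit."""

    beta_hat: np.ndarray
    loglik: float
    converged: bool
    n_iterations: int
    parametrization: ItemParametrization
    constraint: LinearHypothesis | None = None
    grad_norm: float = np.nan
    message: str = ""


def _start_values(data: ResponseData, param: ItemParametrization) -> np.ndarray:
    """Moment-flavoured starting values: unit slopes, marginal intercepts."""
    beta = np.zeros(param.length)
    if param.family == "two_pl":
        pbar = np.clip(data.responses.mean(axis=0), 0.02, 0.98)
        beta[0::2] = 1.0
        beta[1::2] = logit(pbar)
    elif param.family == "gpcm":
        beta[param.slope_indices] = 1.0
    else:  # dif_two_group
        pbar = np.clip(data.responses.mean(axis=0), 0.02, 0.98)
        d0 = logit(pbar)
        beta[0], beta[1] = 1.0, d0[0]
        beta[2], beta[3] = 1.0, d0[0]
        beta[4::2] = 1.0
        beta[5::2] = d0[1:]
    return beta


def fit_mml(data: ResponseData, parametrization: ItemParametrization,
            constraint: LinearHypothesis | None = None,
            latent: LatentDistribution | None = None,
            start=None, gtol: float = 1e-7, maxiter: int = 5000) -> FitResult:
    """Fit the model to observed responses by marginal maximum likelihood.

    With ``constraint`` given, the optimization runs in the null-space
    parametrization of {beta : A beta = c}, so the returned ``beta_hat``
    satisfies the constraint exactly (e.g. equal slopes for a Rasch fit in
    2PL coordinates).
    """
    if data.n_items != parametrization.n_items:
        raise ValueError("data and parametrization disagree on the item count")
    if data.n_categories > parametrization.n_categories:
        raise ValueError("data contain categories beyond the parametrization")
    if parametrization.family == "dif_two_group" and data.group is None:
        raise ValueError("the DIF family requires group labels")
    for k in range(parametrization.n_categories):
        if not np.any(data.responses == k):
            logger.warning("category %d never observed; estimates may drift", k)

    latent = latent if latent is not None else LatentDistribution.standard_normal()
    # a throwaway model object: only the layout/quadrature machinery is used
    probe = MarginalModel(parametrization, np.zeros(parametrization.length), latent)
    patterns, counts = data.patterns, data.pattern_counts
    groups = data.pattern_groups
    n = data.n_persons

    beta0 = _start_values(data, parametrization) if start is None else np.asarray(start, float)

    if constraint is None:
        def negloglik(beta):
            logg, G = probe.logprob_and_score(patterns, groups, beta=beta)
            return -counts @ logg, -(G.T @ counts)

        res = optimize.minimize(negloglik, beta0, jac=True, method="BFGS",
                                options={"gtol": gtol * n, "maxiter": maxiter})
        beta_hat = res.x
    else:
        beta_part, N = _null_space_coords(constraint)
        gamma0 = N.T @ (project_onto_null(constraint, beta0) - beta_part)

        def negloglik(gamma):
            beta = beta_part + N @ gamma
            logg, G = probe.logprob_and_score(patterns, groups, beta=beta)
            return -counts @ logg, -(N.T @ (G.T @ counts))

        res = optimize.minimize(negloglik, gamma0, jac=True, method="BFGS",
                                options={"gtol": gtol * n, "maxiter": maxiter})
        beta_hat = beta_part + N @ res.x

    grad_norm = float(np.linalg.norm(res.jac, ord=np.inf))
    converged = bool(res.success or grad_norm < 1e-4 * n)
    if not converged:
        logger.warning("MML fit did not converge: %s", res.message)
    return FitResult(beta_hat, float(-res.fun), converged, int(res.nit),
                     parametrization, constraint, grad_norm, str(res.message))


# ---------------------------------------------------------------------------
# information / covariance estimates at the MML estimates
# ---------------------------------------------------------------------------

def covariance_at(fit: FitResult, data: ResponseData,
                  latent: LatentDistribution | None = None) -> np.ndarray:
    """Sigma(beta_hat, X~): inverse information estimate for the dataset.

    Expected Fisher information at the estimates when the pattern space is
    enumerable; otherwise the empirical cross-product of per-person scores.
    """
    latent = latent if latent is not None else LatentDistribution.standard_normal()
    p = fit.parametrization
    n = data.n_persons
    if pattern_space_size(p.n_items, p.n_categories) <= MAX_ENUMERABLE_PATTERNS:
        model = MarginalModel(p, fit.beta_hat, latent)
        info = expected_fisher(model).matrix * n
    else:
        model = MarginalModel(p, fit.beta_hat, latent)
        _, G = model.logprob_and_score(data.patterns, data.pattern_groups)
        info = (G * data.pattern_counts[:, None]).T @ G
    return linalg.inv(info)


def total_score(fit: FitResult, data: ResponseData,
                latent: LatentDistribution | None = None) -> np.ndarray:
    """Total observed score sum_x dlog g_{beta}(x) h(x) at the fit's estimates."""
    latent = latent if latent is not None else LatentDistribution.standard_normal()
    model = MarginalModel(fit.parametrization, fit.beta_hat, latent)
    _, G = model.logprob_and_score(data.patterns, data.pattern_groups)
    return G.T @ data.pattern_counts


# ---------------------------------------------------------------------------
# observed statistics S1-S4
# ---------------------------------------------------------------------------

def observed_wald(fit: FitResult, h: LinearHypothesis, cov: np.ndarray) -> float:
    """S1: Wald quadratic form at the unrestricted estimates."""
    r = h.residual(fit.beta_hat)
    M = h.A @ cov @ h.A.T
    return float(r @ linalg.solve(M, r, assume_a="pos"))


def observed_lr(fit_full: FitResult, fit_restricted: FitResult) -> float:
    """S2: twice the log-likelihood difference of nested fits."""
    if fit_restricted.constraint is None:
        raise ValueError("the restricted fit must carry its constraint")
    value = 2.0 * (fit_full.loglik - fit_restricted.loglik)
    if value < -1e-6:
        raise ValueError("restricted fit has higher likelihood: fits are not nested "
                         "or did not converge")
    return max(value, 0.0)


def observed_score(fit_restricted: FitResult, data: ResponseData,
                   cov_r: np.ndarray,
                   latent: LatentDistribution | None = None) -> float:
    """S3: quadratic form of the total score at the restricted estimates."""
    s = total_score(fit_restricted, data, latent)
    return float(s @ cov_r @ s)


def observed_gradient(fit_full: FitResult, fit_restricted: FitResult,
                      data: ResponseData, h: LinearHypothesis,
                      latent: LatentDistribution | None = None) -> float:
    """S4: k'(A beta_hat - c); needs no information matrix.

    Sign convention as in the analytical noncentrality: the total score at
    the restricted estimates equals A'k, so S4 equals the score-times-
    displacement product and is positive in regular samples.
    """
    s = total_score(fit_restricted, data, latent)
    k, *_ = np.linalg.lstsq(h.A.T, s, rcond=None)
    resid = float(np.linalg.norm(h.A.T @ k - s, ord=np.inf))
    if resid > 1e-4 * max(1.0, float(np.linalg.norm(s, ord=np.inf))):
        logger.warning("Lagrange system residual %.3e: restricted fit may not "
                       "be converged", resid)
        fit_restricted.converged = False
    return float(k @ h.residual(fit_full.beta_hat))


def observed_statistics(data: ResponseData, parametrization: ItemParametrization,
                        h: LinearHypothesis,
                        latent: LatentDistribution | None = None) -> dict[str, float]:
    """Fit restricted and unrestricted models and return all four statistics."""
    fit_full = fit_mml(data, parametrization, latent=latent)
    fit_r = fit_mml(data, parametrization, constraint=h, latent=latent)
    cov = covariance_at(fit_full, data, latent)
    cov_r = covariance_at(fit_r, data, latent)
    return {
        "wald": observed_wald(fit_full, h, cov),
        "lr": observed_lr(fit_full, fit_r),
        "score": observed_score(fit_r, data, cov_r, latent),
        "gradient": observed_gradient(fit_full, fit_r, data, h, latent),
    }


# ---------------------------------------------------------------------------
# sampling-based noncentrality parameters
# ---------------------------------------------------------------------------

def sampling_ncp(beta, parametrization: ItemParametrization, h: LinearHypothesis,
                 latent: LatentDistribution | None = None,
                 n_artificial: int = 100_000, seed: int = 1,
                 group_weights=None) -> NCPResult:
    """Approximate lambda(beta, 1) from one large artificial dataset.

    Generates n_artificial responses from the alternative model, fits the
    restricted and unrestricted models, computes the observed statistics,
    and returns (statistic - df) / n_artificial per statistic, clamped at 0.
    Converges to the analytical noncentrality as n_artificial grows.
    """
    from .simdata import simulate_responses  # local import to avoid a cycle

    data = simulate_responses(beta, parametrization, latent=latent,
                              n=n_artificial, seed=seed,
                              group_weights=group_weights)
    stats = observed_statistics(data, parametrization, h, latent)
    lambdas = {}
    for name, value in stats.items():
        lam = (value - h.df) / n_artificial
        if lam < 0:
            logger.debug("sampling lambda for %s below 0 (%.3e); clamped", name, lam)
            lam = 0.0
        lambdas[name] = lam
    return NCPResult(lambdas, np.asarray(beta, dtype=float), None, h,
                     {"method": "sampling", "n_artificial": n_artificial,
                      "seed": seed, "statistics": stats})
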