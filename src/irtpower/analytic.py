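"""Analytical noncentrality parameters for the four test statistics.

Given population item parameters ``beta`` (the alternative) and a linear
hypothesis ``A beta = c``, each of the Wald, likelihood-ratio, score, and
gradient statistics asymptotically follows a noncentral chi-square
distribution whose noncentrality parameter is obtained by evaluating the
statistic at the population parameters. All four scale exactly linearly in
the sample size, lambda(beta, n) = n * lambda(beta, 1), so everything here
is computed at unit sample size.

Ingredients:

* the expected Fisher information ``I_F(beta, 1) = -E_x[d^2 log g / d beta^2]``
  summed over the full pattern space;
* the expected restricted parameters ``beta_r``, the point of the null set
  maximizing the expected log-likelihood under the alternative's pattern
  distribution (constrained optimization in a null-space coordinate system);
* the expected score at ``beta_r`` under the alternative distribution.

The four parameters at unit n:

* Wald:     lambda_1 = (A b - c)' [A Sigma(b,1) A']^{-1} (A b - c)
* LR:       lambda_2 = 2 sum_x (log g_b(x) - log g_{b_r}(x)) g_b(x)
* score:    lambda_3 = s' Sigma(b_r,1) s,  s = sum_x  dlog g_{b_r}(x) g_b(x)
* gradient: lambda_4 = k' (A b - c),       s = -A' k (Lagrange multipliers)

with Sigma(., 1) the inverse expected Fisher information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .hypotheses import LinearHypothesis
from .marginal import MarginalModel

logger = logging.getLogger(__name__)

STATISTICS = ("wald", "lr", "score", "gradient")

_NULL_TOL = 1e-12  # ||A beta - c||_inf below this counts as "no effect"
_NEG_TOL = -1e-10  # roundoff tolerance before clamping a lambda to zero


@dataclass
class ExpectedInformation:
    """Expected Fisher information at unit sample size, and where it holds."""

    matrix: np.ndarray
    at_beta: np.ndarray

    @property
    def covariance(self) -> np.ndarray:
        """Sigma(beta, 1) = inverse information."""
        return linalg.inv(self.matrix)

    @property
    def min_eigenvalue(self) -> float:
        return float(linalg.eigvalsh(self.matrix)[0])


@dataclass
class RestrictedSolution:
    """Expected restricted parameters beta_r maximizing E_g[log g_{b0}]."""

    beta_r: np.ndarray
    objective: float
    converged: bool
    n_iterations: int
    grad_norm: float
    message: str = ""


@dataclass
class NCPResult:
    """Noncentrality parameters per statistic at unit sample size."""

    lambdas: dict[str, float]
    beta: np.ndarray
    restricted: RestrictedSolution | None
    hypothesis: LinearHypothesis
    diagnostics: dict = field(default_factory=dict)

    def at_n(self, n: int) -> dict[str, float]:
        """lambda(beta, n) = n * lambda(beta, 1)."""
        return {k: n * v for k, v in self.lambdas.items()}


# ---------------------------------------------------------------------------
# expected Fisher information
# ---------------------------------------------------------------------------

def expected_fisher(model: MarginalModel, beta=None, step: float = 1e-5) -> ExpectedInformation:
    """-sum_x d^2 log g(x) g(x) over the full pattern space.

    Second derivatives are central finite differences of the analytic
    gradient of log g; the result is symmetrized. The expectation weights
    are g evaluated at the same beta (the information is a property of the
    model at that point).
    """
    beta = model.beta if beta is None else np.asarray(beta, dtype=float)
    patterns, groups = model.pattern_space()
    g = np.exp(model.logprob(patterns, groups, beta))
    l = beta.shape[0]
    info = np.empty((l, l))
    for j in range(l):
        h = step * max(1.0, abs(beta[j]))
        bp = beta.copy(); bp[j] += h
        bm = beta.copy(); bm[j] -= h
        _, Gp = model.logprob_and_score(patterns, groups, beta=bp)
        _, Gm = model.logprob_and_score(patterns, groups, beta=bm)
        # column j of E[hessian]: expectation of (dG/dbeta_j) over g
        info[:, j] = -g @ ((Gp - Gm) / (2 * h))
    info = 0.5 * (info + info.T)
    result = ExpectedInformation(info, beta.copy())
    if result.min_eigenvalue <= 0:
        logger.warning("expected information is singular (min eigenvalue %.3e): "
                       "the parametrization may be unidentified", result.min_eigenvalue)
    return result


def outer_product_information(model: MarginalModel, beta=None) -> np.ndarray:
    """sum_x (dlog g)(dlog g)' g — equals the expected Fisher information."""
    beta = model.beta if beta is None else np.asarray(beta, dtype=float)
    patterns, groups = model.pattern_space()
    logg, G = model.logprob_and_score(patterns, groups, beta)
    return (G * np.exp(logg)[:, None]).T @ G


# ---------------------------------------------------------------------------
# expected restricted parameters
# ---------------------------------------------------------------------------

def _null_space_coords(h: LinearHypothesis):
    """Particular solution and null-space basis of {beta : A beta = c}."""
    N = linalg.null_space(h.A)
    beta_part = h.A.T @ linalg.solve(h.A @ h.A.T, h.c)
    return beta_part, N


def project_onto_null(h: LinearHypothesis, beta) -> np.ndarray:
    """Euclidean projection of beta onto the null set {A beta = c}."""
    beta = np.asarray(beta, dtype=float)
    r = h.residual(beta)
    return beta - h.A.T @ linalg.solve(h.A @ h.A.T, r)


def restricted_parameters(model: MarginalModel, h: LinearHypothesis,
                          start=None, gtol: float = 1e-8,
                          maxiter: int = 2000) -> RestrictedSolution:
    """Maximize the expected log-likelihood over the null set (BFGS).

    The constraint A beta = c is eliminated by writing
    beta = beta_part + N gamma with N a basis of the null space of A, and
    running unconstrained quasi-Newton on gamma. The default start is the
    projection of the alternative beta onto the constraint set.
    """
    if h.n_params != model.parametrization.length:
        raise ValueError("hypothesis dimension does not match the model")
    patterns, groups = model.pattern_space()
    g_alt = np.exp(model.logprob(patterns, groups))

    if h.follows_null(model.beta, tol=1e-10):
        logg = model.logprob(patterns, groups)
        return RestrictedSolution(model.beta.copy(), float(g_alt @ logg),
                                  True, 0, 0.0, "beta already satisfies the null")

    beta_part, N = _null_space_coords(h)
    start_beta = project_onto_null(h, model.beta if start is None else start)
    gamma0 = N.T @ (start_beta - beta_part)

    def negobj(gamma):
        beta0 = beta_part + N @ gamma
        logg, G = model.logprob_and_score(patterns, groups, beta=beta0)
        val = g_alt @ logg
        grad = N.T @ (G.T @ g_alt)
        return -val, -grad

    res = optimize.minimize(negobj, gamma0, jac=True, method="BFGS",
                            options={"gtol": gtol, "maxiter": maxiter})
    beta_r = beta_part + N @ res.x
    grad_norm = float(np.linalg.norm(res.jac, ord=np.inf))
    converged = bool(res.success or grad_norm < 1e-6)
    if not converged:
        logger.warning("restricted optimization did not converge: %s", res.message)
    return RestrictedSolution(beta_r, float(-res.fun), converged,
                              int(res.nit), grad_norm, str(res.message))


# ---------------------------------------------------------------------------
# the four noncentrality parameters (unit sample size)
# ---------------------------------------------------------------------------

def _clamp(value: float, name: str) -> float:
    if value < _NEG_TOL:
        logger.warning("%s noncentrality is negative beyond roundoff: %.3e", name, value)
        return value
    if value < 0:
        logger.debug("clamping tiny negative %s noncentrality %.3e to 0", name, value)
        return 0.0
    return float(value)


def ncp_wald(model: MarginalModel, h: LinearHypothesis,
             info: ExpectedInformation) -> float:
    """lambda_1(beta, 1): Wald quadratic form at the alternative."""
    r = h.residual(model.beta)
    M = h.A @ info.covariance @ h.A.T
    return _clamp(float(r @ linalg.solve(M, r, assume_a="pos")), "Wald")


def ncp_lr(model: MarginalModel, h: LinearHypothesis,
           restricted: RestrictedSolution) -> float:
    """lambda_2(beta, 1): twice the expected log-likelihood gap."""
    patterns, groups = model.pattern_space()
    logg_alt = model.logprob(patterns, groups)
    logg_r = model.logprob(patterns, groups, beta=restricted.beta_r)
    g = np.exp(logg_alt)
    return _clamp(2.0 * float(g @ (logg_alt - logg_r)), "LR")


def expected_score_at_restricted(model: MarginalModel,
                                 restricted: RestrictedSolution) -> np.ndarray:
    """s = sum_x dlog g_{beta_r}(x) g_beta(x): expected score under the alternative."""
    patterns, groups = model.pattern_space()
    g_alt = np.exp(model.logprob(patterns, groups))
    _, G_r = model.logprob_and_score(patterns, groups, beta=restricted.beta_r)
    return G_r.T @ g_alt


def ncp_score(model: MarginalModel, h: LinearHypothesis,
              restricted: RestrictedSolution,
              info_restricted: ExpectedInformation | None = None) -> float:
    """lambda_3(beta, 1): score quadratic form in the metric Sigma(beta_r, 1)."""
    if info_restricted is None:
        info_restricted = expected_fisher(model, beta=restricted.beta_r)
    s = expected_score_at_restricted(model, restricted)
    return _clamp(float(s @ linalg.solve(info_restricted.matrix, s, assume_a="pos")),
                  "score")


def ncp_gradient(model: MarginalModel, h: LinearHypothesis,
                 restricted: RestrictedSolution,
                 residual_tol: float = 1e-6) -> float:
    """lambda_4(beta, 1): k'(A beta - c) with Lagrange multipliers from s = -A'k.

    At an interior restricted optimum the expected score lies in the row
    space of A, so the least-squares solve is exact; a large residual flags
    a non-converged restricted solution. The sign convention for k is fixed
    so that lambda_4 equals the first-order-equivalent positive quadratic
    form (Terrell's score-times-displacement product s'(beta - beta_r)).
    """
    s = expected_score_at_restricted(model, restricted)
    k, *_ = np.linalg.lstsq(h.A.T, s, rcond=None)
    resid = float(np.linalg.norm(h.A.T @ k - s, ord=np.inf))
    scale = max(1.0, float(np.linalg.norm(s, ord=np.inf)))
    if resid > residual_tol * scale:
        logger.warning("Lagrange system residual %.3e: restricted solution may "
                       "not be converged", resid)
        restricted.converged = False
    return _clamp(float(k @ h.residual(model.beta)), "gradient")


def compute_ncps(model: MarginalModel, h: LinearHypothesis,
                 statistics=STATISTICS) -> NCPResult:
    """All requested noncentrality parameters lambda(beta, 1) for one model."""
    beta = model.beta
    if float(np.max(np.abs(h.residual(beta)))) < _NULL_TOL:
        lambdas = {s: 0.0 for s in statistics}
        return NCPResult(lambdas, beta.copy(), None, h,
                         {"note": "beta satisfies the null; all lambdas are 0"})

    lambdas: dict[str, float] = {}
    diagnostics: dict = {}
    restricted = None
    info_r = None
    if any(s in statistics for s in ("lr", "score", "gradient")):
        restricted = restricted_parameters(model, h)
        diagnostics["restricted_converged"] = restricted.converged
        diagnostics["restricted_grad_norm"] = restricted.grad_norm
    if "wald" in statistics:
        info_alt = expected_fisher(model)
        diagnostics["info_min_eigenvalue"] = info_alt.min_eigenvalue
        lambdas["wald"] = ncp_wald(model, h, info_alt)
    if "lr" in statistics:
        lambdas["lr"] = ncp_lr(model, h, restricted)
    if "score" in statistics:
        info_r = expected_fisher(model, beta=restricted.beta_r)
        lambdas["score"] = ncp_score(model, h, restricted, info_r)
    if "gradient" in statistics:
        lambdas["gradient"] = ncp_gradient(model, h, restricted)
    return NCPResult(lambdas, beta.copy(), restricted, h, diagnostics)
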