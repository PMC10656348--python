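"""Marginal response-pattern probabilities and their derivatives.

Under marginal maximum likelihood the person parameter theta is integrated
out of the conditional pattern probability over an assumed population
distribution Phi::

    g_beta(x) = E_theta[f_{beta,theta}(x)] = int f_{beta,theta}(x) Phi(theta) dtheta

with ``f_{beta,theta}(x) = prod_i P(x_i | theta)`` by local independence.
The integral is approximated by Gauss-Hermite quadrature. The gradient of
``log g_beta(x)`` is computed analytically as the posterior expectation of
the complete-data score; second derivatives are obtained by central finite
differences of that analytic gradient.

For the two-group DIF family the "pattern" space is the product
{group} x {1..K}^I and ``g`` carries the group weight, so that all
downstream expectation formulas are uniform across families.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_expit, logsumexp

from .families import ItemParametrization, LatentDistribution

#: largest pattern space the analytical (full-enumeration) path will handle
MAX_ENUMERABLE_PATTERNS = 2_000_000


def pattern_space_size(n_items: int, n_categories: int) -> int:
    """Number of distinct response patterns, K**I (exact Python integer)."""
    if n_items < 1 or n_categories < 1:
        raise ValueError("n_items and n_categories must be >= 1")
    return n_categories ** n_items


def enumerate_patterns(n_items: int, n_categories: int) -> np.ndarray:
    """All response patterns as a (K**I, I) int array, last item fastest."""
    size = pattern_space_size(n_items, n_categories)
    if size > MAX_ENUMERABLE_PATTERNS:
        raise PatternSpaceTooLarge(
            f"pattern space has {size:.3g} patterns (> {MAX_ENUMERABLE_PATTERNS}); "
            "use the sampling-based method instead"
        )
    idx = np.arange(size)
    cols = []
    for i in range(n_items - 1, -1, -1):
        cols.append(idx % n_categories)
        idx //= n_categories
    return np.stack(cols[::-1], axis=1).astype(np.int64)


class PatternSpaceTooLarge(ValueError):
    """Raised when full pattern enumeration is computationally infeasible."""


class MarginalModel:
    """An IRT model with its latent distribution, exposing g_beta(x).

    Parameters
    ----------
    parametrization : ItemParametrization
    beta : array-like
        The item parameter vector in the family's layout.
    latent : LatentDistribution, optional
        Defaults to a standard normal on 61 Gauss-Hermite nodes.
    group_weights : array-like, optional
        Mixing proportions of the two groups for the DIF family
        (default equal split).
    """

    def __init__(self, parametrization: ItemParametrization, beta,
                 latent: LatentDistribution | None = None,
                 group_weights=None):
        self.parametrization = parametrization
        self.beta = np.asarray(beta, dtype=float)
        if self.beta.shape != (parametrization.length,):
            raise ValueError(
                f"beta must have length {parametrization.length}, got {self.beta.shape}")
        self.latent = latent if latent is not None else LatentDistribution.standard_normal()
        if parametrization.n_groups == 2:
            gw = np.asarray(group_weights if group_weights is not None else [0.5, 0.5],
                            dtype=float)
            if gw.shape != (2,) or np.any(gw < 0):
                raise ValueError("group_weights must be two nonnegative numbers")
            self.group_weights = gw / gw.sum()
        else:
            self.group_weights = None
        self._cache: dict = {}

    # -- pattern space --------------------------------------------------
    @property
    def n_patterns(self) -> int:
        base = pattern_space_size(self.parametrization.n_items,
                                  self.parametrization.n_categories)
        return base * self.parametrization.n_groups

    def pattern_space(self) -> tuple[np.ndarray, np.ndarray | None]:
        """Full pattern enumeration: (patterns, groups).

        ``groups`` is None for single-group families; for the DIF family it
        labels each row 0 (group A) or 1 (group B) and the pattern block is
        repeated once per group.
        """
        if "space" not in self._cache:
            pat = enumerate_patterns(self.parametrization.n_items,
                                     self.parametrization.n_categories)
            if self.parametrization.n_groups == 2:
                patterns = np.vstack([pat, pat])
                groups = np.repeat([0, 1], pat.shape[0])
            else:
                patterns, groups = pat, None
            self._cache["space"] = (patterns, groups)
        return self._cache["space"]

    # -- conditional category log-probabilities -------------------------
    def _category_logprobs(self, beta: np.ndarray, group: int) -> np.ndarray:
        """log P(x_i = k | theta_q) as an array (Q, I, K)."""
        p = self.parametrization
        theta = self.latent.nodes  # (Q,)
        a, d = p.item_params(beta, group)
        if p.n_categories == 2 and p.family != "gpcm":
            z = np.outer(theta, a) + d  # (Q, I)
            logP = np.stack([log_expit(-z), log_expit(z)], axis=-1)
            return logP
        # gpcm (also covers K == 2 uniformly)
        K = p.n_categories
        k = np.arange(K)
        z = k[None, None, :] * a[None, :, None] * theta[:, None, None] + d[None, :, :]
        return z - logsumexp(z, axis=-1, keepdims=True)

    # -- log g and its analytic gradient --------------------------------
    def logprob(self, patterns=None, groups=None, beta=None) -> np.ndarray:
        """log g_beta(x) for the given patterns (default: the whole space)."""
        logg, _ = self._core(patterns, groups, beta, want_score=False)
        return logg

    def prob(self, patterns=None, groups=None, beta=None) -> np.ndarray:
        return np.exp(self.logprob(patterns, groups, beta))

    def logprob_and_score(self, patterns=None, groups=None, beta=None):
        """(log g (P,), d log g / d beta (P, l)) with the analytic gradient."""
        return self._core(patterns, groups, beta, want_score=True)

    def _core(self, patterns, groups, beta, want_score: bool):
        p = self.parametrization
        if beta is None:
            beta = self.beta
        beta = np.asarray(beta, dtype=float)
        if patterns is None:
            patterns, groups = self.pattern_space()
        patterns = np.asarray(patterns)
        if patterns.ndim != 2 or patterns.shape[1] != p.n_items:
            raise ValueError(f"patterns must be (n, {p.n_items})")
        P = patterns.shape[0]
        logg = np.empty(P)
        G = np.empty((P, p.length)) if want_score else None

        if p.n_groups == 1:
            self._core_group(beta, 0, patterns, slice(None), logg, G, 0.0)
        else:
            if groups is None:
                raise ValueError("the DIF family requires group labels")
            groups = np.asarray(groups)
            for g in (0, 1):
                sel = np.flatnonzero(groups == g)
                if sel.size:
                    self._core_group(beta, g, patterns[sel], sel, logg, G,
                                     np.log(self.group_weights[g]))
        return logg, G

    def _core_group(self, beta, group, pat, sel, logg, G, log_w) -> None:
        """Fill logg[sel] and G[sel] for patterns belonging to one group."""
        p = self.parametrization
        theta = self.latent.nodes
        logw = np.log(self.latent.weights)
        logP = self._category_logprobs(beta, group)  # (Q, I, K)
        Q, I, K = logP.shape
        logf = np.zeros((Q, pat.shape[0]))
        for i in range(I):
            logf += logP[:, i, pat[:, i]]
        joint = logf + logw[:, None]  # (Q, P)
        lg = logsumexp(joint, axis=0)
        logg[sel] = lg + log_w
        if G is None:
            return
        post = np.exp(joint - lg[None, :])  # posterior over nodes, cols sum to 1
        Pcat = np.exp(logP)  # (Q, I, K)
        a_idx, d_idx = self._param_indices(group)
        Gblock = np.zeros((pat.shape[0], p.length))
        if p.family == "gpcm":
            kk = np.arange(K)
            E = Pcat @ kk  # (Q, I) expected category score
            for i in range(I):
                resid = pat[None, :, i] - E[:, i, None]  # (Q, P)
                Gblock[:, a_idx[i]] = np.einsum("qp,qp->p", post, theta[:, None] * resid)
                for k in range(1, K):
                    ind = (pat[:, i] == k).astype(float)
                    Gblock[:, d_idx[i][k - 1]] = np.einsum(
                        "qp,qp->p", post, ind[None, :] - Pcat[:, i, k, None])
        else:
            P1 = Pcat[:, :, 1]  # (Q, I)
            for i in range(I):
                resid = pat[None, :, i] - P1[:, i, None]  # (Q, P)
                Gblock[:, d_idx[i]] = np.einsum("qp,qp->p", post, resid)
                Gblock[:, a_idx[i]] = np.einsum("qp,qp->p", post, theta[:, None] * resid)
        G[sel] = Gblock

    def _param_indices(self, group: int):
        """beta indices of each item's slope and intercept(s) for a group."""
        p = self.parametrization
        I, K = p.n_items, p.n_categories
        if p.family == "two_pl":
            a_idx = [2 * i for i in range(I)]
            d_idx = [2 * i + 1 for i in range(I)]
        elif p.family == "gpcm":
            a_idx = [K * i for i in range(I)]
            d_idx = [[K * i + 1 + (k - 1) for k in range(1, K)] for i in range(I)]
        else:  # dif_two_group
            a_idx = [0 if group == 0 else 2] + [4 + 2 * (i - 1) for i in range(1, I)]
            d_idx = [1 if group == 0 else 3] + [5 + 2 * (i - 1) for i in range(1, I)]
        return a_idx, d_idx

    # -- per-pattern second derivatives ---------------------------------
    def score_and_hessian(self, x, group: int = 0, step: float = 1e-5):
        """Gradient and Hessian of log g_beta at one pattern.

        The gradient is analytic; the Hessian is a central finite difference
        of the analytic gradient with per-coordinate step
        ``step * max(1, |beta_j|)``, symmetrized.
        """
        x = np.atleast_2d(np.asarray(x))
        groups = np.array([group]) if self.parametrization.n_groups == 2 else None
        _, G = self.logprob_and_score(x, groups)
        l = self.parametrization.length
        H = np.empty((l, l))
        for j in range(l):
            h = step * max(1.0, abs(self.beta[j]))
            bp = self.beta.copy(); bp[j] += h
            bm = self.beta.copy(); bm[j] -= h
            _, Gp = self.logprob_and_score(x, groups, beta=bp)
            _, Gm = self.logprob_and_score(x, groups, beta=bm)
            H[:, j] = (Gp[0] - Gm[0]) / (2 * h)
        return G[0], 0.5 * (H + H.T)

    def with_beta(self, beta) -> "MarginalModel":
        """A copy of this model at different parameter values."""
        m = MarginalModel(self.parametrization, beta, self.latent,
                         None if self.group_weights is None else self.group_weights)
        m._cache = self._cache  # pattern space is beta-independent
        return m
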