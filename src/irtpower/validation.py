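"""Simulation checks of the asymptotic calibration of the four tests.

The central check: on data generated under the null hypothesis, each
statistic should reject at close to the nominal level when compared against
the central chi-square critical value. ``null_rejection_rates`` runs this
for the equal-slopes (Rasch) null and reports the empirical rejection
proportion per statistic.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import chi2

from .families import ItemParametrization, LatentDistribution
from .fitting import ResponseData, observed_statistics
from .hypotheses import rasch_vs_2pl
from .simdata import simulate_responses

logger = logging.getLogger(__name__)


def null_rejection_rates(n_reps: int = 1000, n: int = 3000, n_items: int = 5,
                         seed: int = 1, alpha: float = 0.05,
                         n_nodes: int = 61) -> dict[str, float]:
    """Empirical type-I error of all four statistics under a Rasch null.

    Each replication draws fresh Rasch parameters (common slope 1,
    standard-normal intercepts), simulates ``n`` respondents, fits the
    restricted (Rasch) and unrestricted (2PL) models, and rejects when a
    statistic exceeds the central chi-square (1 - alpha) quantile with
    df = I - 1.
    """
    param = ItemParametrization("two_pl", n_items)
    h = rasch_vs_2pl(n_items)
    latent = LatentDistribution.standard_normal(n_nodes)
    crit = chi2.ppf(1 - alpha, h.df)

    rng = np.random.default_rng(seed)
    rejections = {s: 0 for s in ("wald", "lr", "score", "gradient")}
    for rep in range(n_reps):
        beta = np.empty(2 * n_items)
        beta[0::2] = 1.0
        beta[1::2] = rng.standard_normal(n_items)
        data = simulate_responses(beta, param, latent=latent, n=n, seed=rng)
        stats = observed_statistics(data, param, h, latent)
        for s, value in stats.items():
            if value > crit:
                rejections[s] += 1
    return {s: count / n_reps for s, count in rejections.items()}


def null_statistic_batch(n_reps: int, n: int, n_items: int, seed: int = 1,
                         n_nodes: int = 61) -> dict[str, np.ndarray]:
    """Raw statistic values over a batch of null-generated datasets."""
    param = ItemParametrization("two_pl", n_items)
    h = rasch_vs_2pl(n_items)
    latent = LatentDistribution.standard_normal(n_nodes)
    rng = np.random.default_rng(seed)
    values: dict[str, list] = {s: [] for s in ("wald", "lr", "score", "gradient")}
    for rep in range(n_reps):
        beta = np.empty(2 * n_items)
        beta[0::2] = 1.0
        beta[1::2] = rng.standard_normal(n_items)
        data = simulate_responses(beta, param, latent=latent, n=n, seed=rng)
        stats = observed_statistics(data, param, h, latent)
        for s, v in stats.items():
            values[s].append(v)
    return {s: np.asarray(v) for s, v in values.items()}
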