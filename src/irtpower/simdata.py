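"""Synthetic response data and simulation-study parameter draws.

``simulate_responses`` generates person-by-item response matrices from any
supported model family: each person's trait is drawn from the latent
distribution (per group for the two-group design) and item responses are
then drawn independently from the item response functions — i.e. local
independence holds exactly in the generated data.

``draw_condition_parameters`` reproduces the generating recipes of the
evaluation design: a 3 x 4 x 5 x 3 grid of hypothesis type
(rasch_2pl / dif / pcm_gpcm), item count (5/10/20/50), sample size
(100/250/500/1000/3000) and effect size (no/small/large). Intercepts are
standard normal; slopes are lognormal with natural-scale mean 1 and an
effect-size- and item-count-dependent SD; the DIF conditions fix item 1's
group difference at 0.25 (small) or 0.5 (large) in both parameters.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .families import ItemParametrization, LatentDistribution
from .fitting import ResponseData

HypothesisType = Literal["rasch_2pl", "dif", "pcm_gpcm"]

N_ITEMS_GRID = (5, 10, 20, 50)
SAMPLE_SIZE_GRID = (100, 250, 500, 1000, 3000)
EFFECT_GRID = ("no", "small", "large")

#: SD of the lognormal slope distribution by (effect, n_items); the SDs
#: shrink with the item count so every condition spans a broad power range.
#: The polytomous conditions reuse the binary values (their exact SDs are
#: not part of the published design).
_SLOPE_SD = {
    ("large", 5): 0.22, ("large", 10): 0.17, ("large", 20): 0.12, ("large", 50): 0.10,
    ("small", 5): 0.16, ("small", 10): 0.12, ("small", 20): 0.08, ("small", 50): 0.05,
}

#: item-1 parameters (a_A, d_A, a_B, d_B) for the DIF conditions
_DIF_ITEM1 = {
    "no": (1.0, 0.0, 1.0, 0.0),
    "small": (1.125, 0.125, 0.875, -0.125),
    "large": (1.25, 0.25, 0.75, -0.25),
}
_DIF_ANCHOR_SD = 0.1


@dataclass(frozen=True)
class SimCondition:
    """One cell of the fully crossed simulation design."""

    hypothesis_type: HypothesisType
    n_items: int
    n: int
    effect: str
    seed: int | None = None
    n_categories: int = 3  # polytomous conditions only

    def __post_init__(self) -> None:
        if self.hypothesis_type not in ("rasch_2pl", "dif", "pcm_gpcm"):
            raise ValueError(f"unknown hypothesis type {self.hypothesis_type!r}")
        if self.n_items not in N_ITEMS_GRID:
            raise ValueError(f"n_items must be one of {N_ITEMS_GRID}")
        if self.n not in SAMPLE_SIZE_GRID:
            raise ValueError(f"n must be one of {SAMPLE_SIZE_GRID}")
        if self.effect not in EFFECT_GRID:
            raise ValueError(f"effect must be one of {EFFECT_GRID}")

    @property
    def parametrization(self) -> ItemParametrization:
        if self.hypothesis_type == "rasch_2pl":
            return ItemParametrization("two_pl", self.n_items)
        if self.hypothesis_type == "dif":
            return ItemParametrization("dif_two_group", self.n_items)
        return ItemParametrization("gpcm", self.n_items, self.n_categories)

    def derived_seed(self) -> int:
        """A stable per-condition seed (CRC of the condition tuple)."""
        if self.seed is not None:
            return self.seed
        key = f"{self.hypothesis_type}|{self.n_items}|{self.n}|{self.effect}"
        return zlib.crc32(key.encode()) % (2**31)


def full_grid() -> list[SimCondition]:
    """All 180 design cells (3 hypothesis types x 4 item counts x 5 n x 3 effects)."""
    return [SimCondition(h, i, n, e)
            for h in ("rasch_2pl", "dif", "pcm_gpcm")
            for i in N_ITEMS_GRID
            for n in SAMPLE_SIZE_GRID
            for e in EFFECT_GRID]


def _lognormal_mean1(sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Lognormal draws with natural-scale mean 1 and natural-scale SD ``sd``."""
    sigma2 = np.log1p(sd * sd)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def draw_condition_parameters(cond: SimCondition,
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw a beta vector following the condition's generating recipe."""
    rng = rng if rng is not None else np.random.default_rng(cond.derived_seed())
    I = cond.n_items
    p = cond.parametrization

    if cond.hypothesis_type == "rasch_2pl":
        a = (np.ones(I) if cond.effect == "no"
             else _lognormal_mean1(_SLOPE_SD[(cond.effect, I)], I, rng))
        d = rng.standard_normal(I)
        beta = np.empty(2 * I)
        beta[0::2], beta[1::2] = a, d
        return beta

    if cond.hypothesis_type == "dif":
        a1A, d1A, a1B, d1B = _DIF_ITEM1[cond.effect]
        a_anchor = _lognormal_mean1(_DIF_ANCHOR_SD, I - 1, rng)
        d_anchor = rng.standard_normal(I - 1)
        beta = np.empty(p.length)
        beta[:4] = (a1A, d1A, a1B, d1B)
        beta[4::2], beta[5::2] = a_anchor, d_anchor
        return beta

    # pcm_gpcm
    K = cond.n_categories
    a = (np.ones(I) if cond.effect == "no"
         else _lognormal_mean1(_SLOPE_SD[(cond.effect, I)], I, rng))
    beta = np.zeros(p.length)
    for i in range(I):
        beta[K * i] = a[i]
        beta[K * i + 1: K * (i + 1)] = rng.standard_normal(K - 1)
    return beta


def simulate_responses(beta, parametrization: ItemParametrization,
                       latent: LatentDistribution | None = None,
                       n: int = 1000, seed: int | np.random.Generator = 1,
                       group_weights=None) -> ResponseData:
    """Draw ``n`` response vectors from the model.

    Traits are sampled from a normal distribution matching the latent
    specification (exact sampling, not the quadrature grid); categories are
    then drawn independently per item.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = parametrization
    beta = np.asarray(beta, dtype=float)

    # trait distribution: recover mean/sd from the quadrature nodes
    if latent is None:
        mean, sd = 0.0, 1.0
    else:
        mean = float(latent.weights @ latent.nodes)
        sd = float(np.sqrt(latent.weights @ (latent.nodes - mean) ** 2))
    theta = rng.normal(mean, sd, size=n)

    if p.family == "dif_two_group":
        gw = np.asarray(group_weights if group_weights is not None else [0.5, 0.5],
                        dtype=float)
        gw = gw / gw.sum()
        group = rng.choice(2, size=n, p=gw)
    else:
        group = None

    X = np.empty((n, p.n_items), dtype=np.int64)
    K = p.n_categories
    k_arr = np.arange(K)
    for g in ([0] if group is None else [0, 1]):
        sel = slice(None) if group is None else np.flatnonzero(group == g)
        th = theta[sel]
        a, d = p.item_params(beta, group=g)
        if p.family == "gpcm":
            # z: (n_g, I, K) category log-weights
            z = k_arr[None, None, :] * a[None, :, None] * th[:, None, None] + d[None, :, :]
            z -= z.max(axis=-1, keepdims=True)
            probs = np.exp(z)
            probs /= probs.sum(axis=-1, keepdims=True)
            cum = np.cumsum(probs, axis=-1)
            u = rng.random((th.shape[0], p.n_items, 1))
            X[sel] = (u > cum[..., :-1]).sum(axis=-1)
        else:
            prob1 = 1.0 / (1.0 + np.exp(-(np.outer(th, a) + d)))
            X[sel] = (rng.random(prob1.shape) < prob1).astype(np.int64)
    return ResponseData(X, group)
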