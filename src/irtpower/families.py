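"""Model families, item response functions and parameter-vector layouts.

Three families are supported, all in the slope/intercept parametrization:

* ``two_pl`` — binary items, P(x_i = 1 | theta) = logistic(a_i * theta + d_i).
  The parameter vector is ``beta = (a_1, d_1, ..., a_I, d_I)`` of length 2I.
  The Rasch model is the equal-slopes special case and is represented in the
  same full-length coordinate system via a linear constraint, not in a
  reduced space.
* ``gpcm`` — ordered polytomous items with K categories,
  P(x_i = k) proportional to exp((k-1) * a_i * theta + d_ik), with d_i1 = 0
  fixed for identification. Item block: (a_i, d_i2, ..., d_iK), so beta has
  length I*K. The partial credit model (PCM) is the equal-slopes special case.
* ``dif_two_group`` — binary items in two groups where the first item's
  parameters may differ between groups A and B:
  ``beta = (a_1A, d_1A, a_1B, d_1B, a_2, d_2, ..., a_I, d_I)``, length 2I+2.
  Items 2..I are shared across groups and act as the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import expit

Family = Literal["two_pl", "gpcm", "dif_two_group"]

#: named roles a beta entry can play
SLOPE = "a"
INTERCEPT = "d"


@dataclass(frozen=True)
class Slot:
    """One named entry of the parameter vector beta."""

    item: int  # 1-based item index
    role: str  # "a" or "d"; for gpcm intercepts "d2".."dK"
    group: str | None = None  # "A"/"B" for group-specific DIF entries


@dataclass(frozen=True)
class ItemParametrization:
    """Layout of the parameter vector beta for one model family.

    Parameters
    ----------
    family : {"two_pl", "gpcm", "dif_two_group"}
    n_items : int
        Number of items I.
    n_categories : int
        Number of response categories K (2 for the binary families).
    """

    family: Family
    n_items: int
    n_categories: int = 2

    def __post_init__(self) -> None:
        if self.family not in ("two_pl", "gpcm", "dif_two_group"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_items < 1:
            raise ValueError("n_items must be positive")
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        if self.family in ("two_pl", "dif_two_group") and self.n_categories != 2:
            raise ValueError(f"{self.family} requires n_categories == 2")

    # -- layout ---------------------------------------------------------
    @property
    def layout(self) -> list[Slot]:
        I, K = self.n_items, self.n_categories
        if self.family == "two_pl":
            slots = []
            for i in range(1, I + 1):
                slots += [Slot(i, SLOPE), Slot(i, INTERCEPT)]
            return slots
        if self.family == "gpcm":
            slots = []
            for i in range(1, I + 1):
                slots.append(Slot(i, SLOPE))
                slots += [Slot(i, f"d{k}") for k in range(2, K + 1)]
            return slots
        # dif_two_group
        slots = [Slot(1, SLOPE, "A"), Slot(1, INTERCEPT, "A"),
                 Slot(1, SLOPE, "B"), Slot(1, INTERCEPT, "B")]
        for i in range(2, I + 1):
            slots += [Slot(i, SLOPE), Slot(i, INTERCEPT)]
        return slots

    @property
    def length(self) -> int:
        """Length l of the unrestricted parameter vector."""
        I, K = self.n_items, self.n_categories
        if self.family == "two_pl":
            return 2 * I
        if self.family == "gpcm":
            return I * K
        return 2 * I + 2

    @property
    def slope_indices(self) -> np.ndarray:
        """Indices of all slope entries in beta."""
        return np.array([j for j, s in enumerate(self.layout) if s.role == SLOPE])

    @property
    def n_groups(self) -> int:
        return 2 if self.family == "dif_two_group" else 1

    # -- per-group views ------------------------------------------------
    def item_params(self, beta: np.ndarray, group: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Split beta into per-item slopes ``a`` (I,) and intercepts ``d``.

        For binary families ``d`` has shape (I,); for gpcm shape (I, K) with
        the identification zero in column 0. ``group`` selects A (0) or B (1)
        for the DIF family and is ignored otherwise.
        """
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.length,):
            raise ValueError(f"beta must have length {self.length}, got {beta.shape}")
        I, K = self.n_items, self.n_categories
        if self.family == "two_pl":
            return beta[0::2].copy(), beta[1::2].copy()
        if self.family == "gpcm":
            blocks = beta.reshape(I, K)
            a = blocks[:, 0].copy()
            d = np.zeros((I, K))
            d[:, 1:] = blocks[:, 1:]
            return a, d
        # dif_two_group
        off = 0 if group == 0 else 2
        a = np.empty(I)
        d = np.empty(I)
        a[0], d[0] = beta[off], beta[off + 1]
        rest = beta[4:].reshape(I - 1, 2)
        a[1:], d[1:] = rest[:, 0], rest[:, 1]
        return a, d

    def group_column_mask(self, group: int) -> np.ndarray:
        """Boolean mask over beta entries active for ``group``'s likelihood."""
        if self.family != "dif_two_group":
            return np.ones(self.length, dtype=bool)
        mask = np.ones(self.length, dtype=bool)
        if group == 0:
            mask[2:4] = False
        else:
            mask[0:2] = False
        return mask


def parameter_count(param: ItemParametrization, restricted: bool = False) -> int:
    """Number of identified parameters under MML.

    ``restricted=True`` counts the equal-slopes submodel (Rasch for binary,
    PCM for polytomous): one common slope plus all free intercepts. For the
    Rasch model this is I + 1 — one plus the number of items.
    """
    I, K = param.n_items, param.n_categories
    if not restricted:
        return param.length
    if param.family == "two_pl":
        return I + 1
    if param.family == "gpcm":
        return I * (K - 1) + 1
    raise ValueError("restricted count is not defined for dif_two_group")


# ---------------------------------------------------------------------------
# item response functions
# ---------------------------------------------------------------------------

def prob_2pl(a: float, d: float, theta):
    """P(x = 1 | theta) for a binary logistic item: 1 / (1 + exp(-(a*theta+d)))."""
    z = np.asarray(a) * np.asarray(theta) + np.asarray(d)
    out = expit(z)
    return out if out.shape else float(out)


def prob_gpcm(a: float, d, theta):
    """Category probabilities (length K) of a generalized partial credit item.

    ``d`` holds the K intercepts with the identification constraint d[0] == 0.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or d.shape[0] < 2:
        raise ValueError("d must be a vector of K >= 2 intercepts")
    if d[0] != 0.0:
        raise ValueError("first intercept must be 0 (identification constraint)")
    K = d.shape[0]
    k = np.arange(K)
    z = k * a * np.asarray(theta) + d
    z = z - z.max()
    ez = np.exp(z)
    return ez / ez.sum()


# ---------------------------------------------------------------------------
# latent trait distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatentDistribution:
    """Quadrature representation of the latent-trait distribution.

    Defaults to a standard normal discretized by Gauss-Hermite quadrature
    (probabilists' convention), weights renormalized to sum to one.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.shape != weights.shape or nodes.ndim != 1:
            raise ValueError("nodes and weights must be 1-D and the same length")
        if np.any(weights < 0):
            raise ValueError("quadrature weights must be nonnegative")
        weights = weights / weights.sum()
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @classmethod
    def normal(cls, mean: float = 0.0, sd: float = 1.0, n_nodes: int = 61) -> "LatentDistribution":
        x, w = hermegauss(n_nodes)
        return cls(mean + sd * x, w)

    @classmethod
    def standard_normal(cls, n_nodes: int = 61) -> "LatentDistribution":
        return cls.normal(0.0, 1.0, n_nodes)
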