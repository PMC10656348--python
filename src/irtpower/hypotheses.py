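"""Linear hypotheses A @ beta = c on item parameters.

The degrees of freedom of every test equal the number of rows of A. All
built-in constructors use c = 0, but c is stored explicitly so that general
affine constraints are supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .families import ItemParametrization

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class LinearHypothesis:
    """The null hypothesis A @ beta = c.

    A must have full row rank; rank deficiency would silently corrupt the
    degrees of freedom, so it is rejected at construction.
    """

    A: np.ndarray
    c: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        c = np.atleast_1d(np.asarray(self.c, dtype=float))
        if c.shape != (A.shape[0],):
            raise ValueError("c must have one entry per row of A")
        s = np.linalg.svd(A, compute_uv=False)
        if s.size == 0 or s[-1] <= _RANK_TOL * max(A.shape) * s[0]:
            raise ValueError("A must have full row rank")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "c", c)

    @property
    def df(self) -> int:
        return self.A.shape[0]

    @property
    def n_params(self) -> int:
        return self.A.shape[1]

    def residual(self, beta) -> np.ndarray:
        """A @ beta - c; the zero vector iff beta satisfies the null."""
        return self.A @ np.asarray(beta, dtype=float) - self.c

    def follows_null(self, beta, tol: float = 1e-12) -> bool:
        return bool(np.max(np.abs(self.residual(beta))) < tol)

    # -- JSON round trip for user-defined hypotheses --------------------
    def to_json(self) -> str:
        return json.dumps({"A": self.A.tolist(), "c": self.c.tolist(),
                           "description": self.description})

    @classmethod
    def from_json(cls, text: str) -> "LinearHypothesis":
        obj = json.loads(text)
        return cls(np.asarray(obj["A"], dtype=float),
                   np.asarray(obj["c"], dtype=float),
                   obj.get("description", ""))


def rasch_vs_2pl(n_items: int) -> LinearHypothesis:
    """Equal-slopes hypothesis of the Rasch model within the 2PL.

    Rows are consecutive slope differences a_i - a_{i+1}; df = I - 1.
    """
    if n_items < 2:
        raise ValueError("need at least 2 items")
    p = ItemParametrization("two_pl", n_items)
    return _slope_contrasts(p, "Rasch vs 2PL (equal slopes)")


def pcm_vs_gpcm(n_items: int, n_categories: int) -> LinearHypothesis:
    """Equal-slopes hypothesis of the PCM within the GPCM; df = I - 1."""
    if n_items < 2:
        raise ValueError("need at least 2 items")
    p = ItemParametrization("gpcm", n_items, n_categories)
    return _slope_contrasts(p, "PCM vs GPCM (equal slopes)")


def _slope_contrasts(p: ItemParametrization, description: str) -> LinearHypothesis:
    slopes = p.slope_indices
    I = p.n_items
    A = np.zeros((I - 1, p.length))
    for r in range(I - 1):
        A[r, slopes[r]] = 1.0
        A[r, slopes[r + 1]] = -1.0
    return LinearHypothesis(A, np.zeros(I - 1), description)


def dif_first_item(n_items: int) -> LinearHypothesis:
    """No-DIF hypothesis for item 1 in the two-group layout.

    Rows: a_1A - a_1B = 0 and d_1A - d_1B = 0; df = 2.
    """
    if n_items < 2:
        raise ValueError("need at least 2 items (anchor items must exist)")
    p = ItemParametrization("dif_two_group", n_items)
    A = np.zeros((2, p.length))
    A[0, 0], A[0, 2] = 1.0, -1.0
    A[1, 1], A[1, 3] = 1.0, -1.0
    return LinearHypothesis(A, np.zeros(2), "two-group DIF on item 1")


def equivalent_under_reparametrization(h1: LinearHypothesis, h2: LinearHypothesis,
                                       tol: float = 1e-8) -> bool:
    """Whether h2 is h1 rewritten as (C @ A, C @ c) for an invertible C.

    Equivalent hypotheses define the same null set, so all four test
    statistics are unchanged by the rewriting.
    """
    if h1.n_params != h2.n_params:
        raise ValueError("hypotheses are over different parameter spaces")
    if h1.df != h2.df:
        return False
    # augment with c so the affine sets, not just the row spaces, must agree
    M1 = np.hstack([h1.A, h1.c[:, None]])
    M2 = np.hstack([h2.A, h2.c[:, None]])
    stacked = np.vstack([M1, M2])
    return int(np.linalg.matrix_rank(stacked, tol=tol)) == h1.df
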