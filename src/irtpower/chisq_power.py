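"""Power and sample-size calculations from noncentrality parameters.

Under the null each statistic follows a central chi-square distribution with
df equal to the number of hypothesis rows; under a local alternative it
follows the noncentral chi-square with noncentrality lambda(beta, n)
= n * lambda(beta, 1). Power at sample size n is therefore the upper tail
of ncx2(df, n * lambda1) beyond the central (1 - alpha) quantile.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize
from scipy.stats import chi2, ncx2


def power_at_n(lambda_unit: float, df: int, n, alpha: float = 0.05):
    """P(chi2_{df, n*lambda} > q_{1-alpha}) — the power at sample size n."""
    if lambda_unit < 0:
        raise ValueError("lambda_unit must be nonnegative")
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    q = chi2.ppf(1.0 - alpha, df)
    nc = np.asarray(n, dtype=float) * lambda_unit
    if np.ndim(nc) == 0 and nc == 0:
        return float(alpha)
    out = np.where(nc == 0, alpha, ncx2.sf(q, df, nc))
    return float(out) if np.ndim(n) == 0 else out


def target_noncentrality(df: int, target_power: float, alpha: float = 0.05) -> float:
    """Noncentrality at which the chi-square test reaches the target power."""
    q = chi2.ppf(1.0 - alpha, df)

    def gap(nc):
        return ncx2.sf(q, df, nc) - target_power

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e8:  # pragma: no cover - unattainable targets
            raise RuntimeError("could not bracket the target noncentrality")
    return optimize.brentq(gap, 0.0, hi, xtol=1e-10)


def required_sample_size(lambda_unit: float, df: int, target_power: float = 0.9,
                         alpha: float = 0.05) -> int | None:
    """Smallest integer n with power_at_n(...) >= target_power.

    Solves n* = lambda_target / lambda(beta, 1) on the continuous scale,
    takes the ceiling, and verifies +-1 against chi-square CDF roundoff.
    Returns None when lambda_unit <= 0 (no finite sample size suffices).
    """
    if lambda_unit <= 0:
        return None
    if not 0 < target_power < 1:
        raise ValueError("target_power must be in (0, 1)")
    n = math.ceil(target_noncentrality(df, target_power, alpha) / lambda_unit - 1e-9)
    n = max(n, 1)
    while n > 1 and power_at_n(lambda_unit, df, n - 1, alpha) >= target_power:
        n -= 1
    while power_at_n(lambda_unit, df, n, alpha) < target_power:
        n += 1
    return n


def power_curve(lambda_unit: float, df: int, n_grid, alpha: float = 0.05) -> dict[int, float]:
    """Power at each sample size of an integer grid (no interpolation)."""
    n_grid = [int(n) for n in np.asarray(n_grid).ravel()]
    values = power_at_n(lambda_unit, df, np.asarray(n_grid), alpha)
    return dict(zip(n_grid, np.atleast_1d(values).tolist()))


def confidence_envelope(n_runs: int, expected_rate: float) -> float:
    """Half-width of the 99% confidence envelope around an expected hit rate:
    2.576 * sqrt(n_r * p_e * (1 - p_e)) / n_r."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not 0 <= expected_rate <= 1:
        raise ValueError("expected_rate must be in [0, 1]")
    return 2.576 * math.sqrt(n_runs * expected_rate * (1 - expected_rate)) / n_runs
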