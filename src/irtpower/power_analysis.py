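"""Model/Results interface for IRT power analysis.

``PowerAnalysis`` bundles an alternative item-parameter set, a latent-trait
distribution and a linear hypothesis; ``fit()`` computes the noncentrality
parameters of the Wald, likelihood-ratio, score and gradient statistics
(analytically over the full pattern space, or by the sampling-based
approximation) and returns a ``PowerAnalysisResults`` object that converts
them into power values and required sample sizes.

Example
-------
>>> from irtpower import PowerAnalysis, datasets, hypotheses
>>> pa = PowerAnalysis.from_items(datasets.pisa_m1(),
...                               hypotheses.rasch_vs_2pl(10))
>>> res = pa.fit()
>>> res.required_n(target_power=0.9)           # doctest: +SKIP
{'wald': 422, 'lr': 389, 'score': 397, 'gradient': 378}
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import analytic, chisq_power
from .analytic import NCPResult, STATISTICS
from .datasets import beta_from_table
from .families import ItemParametrization, LatentDistribution
from .fitting import sampling_ncp
from .hypotheses import LinearHypothesis
from .marginal import MarginalModel


class PowerAnalysis:
    """A power-analysis problem: alternative model + linear hypothesis.

    Parameters
    ----------
    parametrization : ItemParametrization
    beta : array-like
        Population (alternative) item parameters in the family's layout.
    hypothesis : LinearHypothesis
        The null hypothesis A beta = c being tested.
    latent : LatentDistribution, optional
        Defaults to standard normal (61-node Gauss-Hermite).
    group_weights : array-like, optional
        Group mixing proportions for the two-group DIF family.
    """

    def __init__(self, parametrization: ItemParametrization, beta,
                 hypothesis: LinearHypothesis,
                 latent: LatentDistribution | None = None,
                 group_weights=None):
        if hypothesis.n_params != parametrization.length:
            raise ValueError("hypothesis and parametrization disagree on the "
                             "parameter count")
        self.parametrization = parametrization
        self.beta = np.asarray(beta, dtype=float)
        self.hypothesis = hypothesis
        self.latent = latent if latent is not None else LatentDistribution.standard_normal()
        self.group_weights = group_weights
        self.model = MarginalModel(parametrization, self.beta, self.latent,
                                   group_weights)

    @classmethod
    def from_items(cls, table: pd.DataFrame, hypothesis: LinearHypothesis,
                   latent: LatentDistribution | None = None) -> "PowerAnalysis":
        """Build a 2PL power analysis from an item table (columns a, d)."""
        param = ItemParametrization("two_pl", len(table))
        return cls(param, beta_from_table(table), hypothesis, latent)

    def fit(self, method: str = "analytical", n_artificial: int = 100_000,
            seed: int = 1) -> "PowerAnalysisResults":
        """Compute the unit-n noncentrality parameters.

        ``method="analytical"`` enumerates the pattern space (feasible up to
        roughly 20 binary items); ``method="sampling"`` estimates the
        statistics from one large artificial dataset and works at any scale.
        """
        if method == "analytical":
            ncp = analytic.compute_ncps(self.model, self.hypothesis)
        elif method == "sampling":
            ncp = sampling_ncp(self.beta, self.parametrization, self.hypothesis,
                               self.latent, n_artificial=n_artificial, seed=seed,
                               group_weights=self.group_weights)
        else:
            raise ValueError("method must be 'analytical' or 'sampling'")
        return PowerAnalysisResults(self, ncp, method)


class PowerAnalysisResults:
    """Noncentrality parameters and the power quantities derived from them."""

    def __init__(self, model: PowerAnalysis, ncp: NCPResult, method: str):
        self.model = model
        self.ncp = ncp
        self.method = method
        self.lambdas = dict(ncp.lambdas)
        self.df = model.hypothesis.df
        self.beta_r = None if ncp.restricted is None else ncp.restricted.beta_r

    def power(self, n: int, alpha: float = 0.05) -> dict[str, float]:
        """Power of each test at overall sample size n."""
        return {s: chisq_power.power_at_n(lam, self.df, n, alpha)
                for s, lam in self.lambdas.items()}

    def power_curve(self, n_grid, alpha: float = 0.05) -> pd.DataFrame:
        """Power on an integer grid of sample sizes, one column per statistic."""
        rows = {s: chisq_power.power_curve(lam, self.df, n_grid, alpha)
                for s, lam in self.lambdas.items()}
        return pd.DataFrame(rows)

    def required_n(self, target_power: float = 0.9,
                   alpha: float = 0.05) -> dict[str, int | None]:
        """Smallest sample size reaching the target power, per statistic."""
        return {s: chisq_power.required_sample_size(lam, self.df, target_power, alpha)
                for s, lam in self.lambdas.items()}

    def plot_power_curve(self, n_grid, alpha: float = 0.05, ax=None):
        """Convenience matplotlib plot of the power curves."""
        import matplotlib.pyplot as plt

        curve = self.power_curve(n_grid, alpha)
        if ax is None:
            _, ax = plt.subplots()
        for s in curve.columns:
            ax.plot(curve.index, curve[s], label=s)
        ax.set_xlabel("sample size n")
        ax.set_ylabel("power")
        ax.set_ylim(0, 1)
        ax.legend()
        return ax

    def summary(self, target_power: float = 0.9, alpha: float = 0.05) -> str:
        """Plain-text summary table."""
        req = self.required_n(target_power, alpha)
        lines = [
            "IRT power analysis",
            "==================",
            f"hypothesis:    {self.model.hypothesis.description or 'A beta = c'}"
            f" (df = {self.df})",
            f"family:        {self.model.parametrization.family}, "
            f"I = {self.model.parametrization.n_items}",
            f"method:        {self.method}",
            f"alpha = {alpha}, target power = {target_power}",
            "",
            f"{'statistic':<10}{'lambda(beta,1)':>16}{'required n':>12}",
        ]
        for s in STATISTICS:
            if s in self.lambdas:
                rn = req[s]
                lines.append(f"{s:<10}{self.lambdas[s]:>16.6f}"
                             f"{'inf' if rn is None else rn:>12}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-ready report of the noncentrality computation."""
        out = {
            "hypothesis": self.model.hypothesis.description,
            "df": self.df,
            "method": self.method,
            "lambda1": self.lambdas,
            "diagnostics": {k: (v if not isinstance(v, float) else float(v))
                            for k, v in self.ncp.diagnostics.items()
                            if not isinstance(v, np.ndarray)},
        }
        if self.beta_r is not None:
            out["beta_r"] = np.asarray(self.beta_r).tolist()
        return out
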