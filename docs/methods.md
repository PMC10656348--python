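# Methods

## Model and scope

The package works with unidimensional IRT models under marginal maximum
likelihood: the 2PL for binary items, the GPCM for ordered polytomous
items (with `d_i1 = 0` fixed for identification), and a two-group 2PL
layout for DIF in which item 1 has group-specific parameters
`(a_1A, d_1A, a_1B, d_1B)` and items 2…I are shared anchors. Persons are
i.i.d. draws from a latent-trait distribution Φ (standard normal by
default); items are locally independent given θ. Restricted models (Rasch,
PCM) are represented in the *full* parameter space via the equality
constraint `Aβ = c`, never in a reduced coordinate system, so the design
matrix, the covariance matrix, and all four statistics live in one common
layout `β = (a₁, d₁, …, a_I, d_I)` (2PL), `(a_i, d_i2, …, d_iK)` blocks
(GPCM), or `(a_1A, d_1A, a_1B, d_1B, a₂, d₂, …)` (DIF).

Out of scope: the 3PL guessing parameter (its boundary breaks the χ²
asymptotics for all but the score test), multidimensional traits,
conditional-ML power methods, and hypotheses on person-distribution
parameters.

## Numerical choices

**Quadrature.** Marginal pattern probabilities
`g_β(x) = ∫ Π_i P(x_i|θ) Φ(θ) dθ` use 61-node Gauss–Hermite quadrature
transformed to the latent mean/SD, weights renormalized. For the models in
scope this is converged far beyond the quantities of interest: results are
identical to six decimals under a 61-node equally-spaced rule on [−6, 6].

**Derivatives.** The gradient of `log g_β(x)` is analytic — the posterior
expectation (over quadrature nodes) of the complete-data score, which for
the 2PL is `((x_i − p_i(θ))θ, x_i − p_i(θ))` per item and for the GPCM the
usual multinomial-logit residuals. Second derivatives (for the expected
Fisher information) are central finite differences of the analytic
gradient with step `1e-5 · max(1, |β_j|)`, symmetrized; the result agrees
with the outer-product form `Σ_x l̇ l̇' g` to ~1e-6.

**Expected restricted parameters.** `β_r` maximizes
`Σ_x g_β(x) log g_{β₀}(x)` over the null set. The constraint is eliminated
by the null-space parametrization `β₀ = β_part + Nγ` (N an orthonormal
basis of null(A)) and the reduced problem is solved by BFGS with the
analytic gradient (gradient tolerance 1e-8, at most 2000 iterations),
started from the Euclidean projection of the alternative onto the
constraint set. If `β` already satisfies the null, `β_r = β` is returned
without optimization.

**Gradient-statistic sign.** The Lagrange multipliers are defined through
`A'k = s` (score at the restricted optimum lies in the row space of A, so
the least-squares solve is exact), which makes `λ₄ = k'(Aβ−c)` equal to
the positive score-times-displacement form `s'(β − β_r)` to first order
and nonnegative in all regular configurations. The opposite sign
convention for k produces the same magnitude with a negative sign; the
first-order expansion `s ≈ A'(AΣA')⁻¹(Aβ−c)` fixes the choice.

**Degenerate inputs.** If `‖Aβ−c‖∞ < 1e-12` all λ are returned as exactly
0 without optimization. Tiny negative λ from roundoff (above −1e-10) are
clamped to 0 with a debug log entry; anything more negative is reported as
a warning, not silently repaired. Rank-deficient A matrices are rejected
at construction (SVD rank check) because they would corrupt the degrees of
freedom. A pattern space beyond 2×10⁶ patterns makes the analytical path
raise and point to the sampling-based path.

**Power inversion.** Power is `P(χ²(df, nλ₁) > q₀.₉₅)`; the required n
solves the continuous equation via the target noncentrality (Brent root
find on the noncentral χ² CDF), takes the ceiling, and verifies ±1 against
CDF roundoff. α defaults to 0.05 and target power to 0.9.

## Fitting and observed statistics

`fit_mml` maximizes the pattern-collapsed marginal log-likelihood
`Σ_x h(x) log g_β(x)` by BFGS with the analytic gradient (cap 5000
iterations), in the null-space parametrization when a constraint is given.
This targets the same maximizer as a Bock–Aitkin EM run to convergence and
is considerably faster at the pattern-space sizes where observed
statistics are computed; start values are unit slopes and marginal-logit
intercepts. The covariance entering the observed Wald/score statistics is
the inverse *expected* Fisher information at the estimates whenever the
pattern space is enumerable, and the empirical cross-product of per-person
scores otherwise — both converge to the expected information in large
samples, which is what the sampling-based noncentrality method relies on.
The two-group DIF model is fitted as a single marginal likelihood over
both groups with shared anchor parameters.

The sampling-based noncentrality per statistic is `(S − df)/n_artificial`
(clamped at 0), with `n_artificial` defaulting to 1e5 and configurable to
the 1e6 used at small item counts in the published evaluation.

## Synthetic data

`simulate_responses` draws θ per person from the (normal) latent
distribution — per group for the DIF design, with group labels sampled
from the mixing weights (default equal) — and then item categories
independently from the response functions, so local independence holds
exactly. `draw_condition_parameters` reproduces the evaluation design's
recipes: intercepts standard normal; slopes lognormal with natural-scale
mean 1 and SD depending on effect size and item count (large:
0.22/0.17/0.12/0.10 and small: 0.16/0.12/0.08/0.05 for 5/10/20/50 items);
DIF item-1 blocks (1.125, 0.125, 0.875, −0.125) for the small and
(1.25, 0.25, 0.75, −0.25) for the large effect; anchor slopes lognormal
with SD 0.1. Two readings of "lognormal with mean 1 and SD s" are
possible; the natural-scale reading is used, with (μ, σ) of the underlying
normal solved from the moment equations. The polytomous conditions reuse
the binary slope SDs (their exact values were not published) and default
to K = 3 categories. "No effect" cells return exactly null-satisfying β.

What the generator does *not* emulate: multidimensionality, local
dependence, guessing, non-normal trait distributions, and unbalanced or
informative group assignment. Passing simulation checks therefore
demonstrate calibration of the statistics under the assumed model, not
robustness to its violation.

## Problem sizes used in the checked examples

The acceptance computations use the built-in PISA 2015 item tables (10 and
9 binary items; pattern spaces of 1024/512, and 2×1024 for the two-group
DIF model) for the analytical path, a 1000-replication Monte Carlo
type-I-error study at n = 3000 with 5 items, parameter recovery at
n = 100 000, and sampling-based noncentralities at n_artificial up to 1e6.
The full published evaluation grid (180 cells × 5000 replications) is
provided in scaled-down form by `scripts/simulation_grid.py`.

## Known limitations

* The analytical path is exponential in the item count; beyond ~20 binary
  items use the sampling path.
* Noncentral-χ² power is an asymptotic approximation: at small n (≲250)
  the observed Wald power tends to fall below, and score/gradient above,
  the predicted curves, as in the published evaluation.
* Published worked-example sample sizes computed from *rounded* printed
  item parameters can differ from values computed on unrounded internal
  parameters by a few percent; the package reports the exact evaluation of
  the formulas on the table it is given.
* The group-size ratio of the DIF design defaults to an equal split; real
  applications with unbalanced groups need larger overall samples.
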