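# Methods

## The model

`sggm` estimates a sparse microbial interaction network from longitudinal
abundance profiles that are irregularly spaced in time and short per
subject. Transformed abundances `y_{i,t}` (subject `i`, time `t`, `p`
taxa) are modeled as centered Gaussian vectors with a shared covariance
`Σ`; the network is the support of the precision matrix `Ω = Σ⁻¹`, whose
zero off-diagonals encode conditional independence between taxa given all
others. Rows from the same subject are temporally correlated: the stacked
vector of subject `i`'s `n_i` observations has the separable covariance

```
Cov(y_i) = Φ_i(τ_i) ⊗ Ω⁻¹ ,    Φ_i[j,k] = exp(−τ_i |t_j − t_k|) .
```

`τ_i > 0` is the subject's dampening rate: large `τ_i` means correlation
decays quickly toward independence, `τ_i → ∞` recovers the
cross-sectional (SPIEC-EASI-style) model. The exponential kernel makes
the process Markov on the observation grid, so `Φ_i⁻¹` is tridiagonal and
the log-likelihood reduces to a weighted scatter matrix

```
S_i(τ) = Σ_{jk} (Φ_i⁻¹)_{jk} y_{t_k} y_{t_j}ᵀ ,   S̄(τ) = (1/n) Σ_i S_i ,
```

with `tr(S_i(τ) Ω) = y_iᵀ (Φ_i⁻¹ ⊗ Ω) y_i`. All solvers minimize the
L1-penalized negative log-likelihood `−2 l(Ω, ·) + n λ Σ_{j≠k} |ω_{jk}|`.
The kernel exponent is fixed at 1; uniform (exponent 0) and squared
(exponent 2) kernels are exposed as options in `build_phi` but untested
against any benchmark.

Three nested treatments of the dampening rates are provided:

1. **Homogeneous** (`fit_homogeneous`): one shared `τ`. Block coordinate
   descent alternates a graphical lasso on `S̄(τ)` with a bounded Brent
   search for `τ` on a log scale (a Newton step would need second
   derivatives and is fragile near the domain boundary; any maximizer of
   the same 1-D objective serves).
2. **Heterogeneous** (`fit_heterogeneous`): `τ_i ~ Exponential(α)` latent
   per subject. Monte-Carlo EM: the E-step samples each `τ_i` posterior
   by inverse-CDF on a fixed 2048-point logarithmic grid over
   `[1e-4, 1e4]` (the density is 1-D and cheap; grid sampling removes all
   MCMC tuning and is bit-reproducible), averages `S_i` over `h` draws
   (default 500 per subject, with a 10× refinement pass for the reported
   posterior means), and the M-step sets `α = m / Σ_i E[τ_i]` and runs a
   graphical lasso on `S⁽⁰⁾ = (1/n) Σ_i E[S_i(τ_i)]`.
3. **Covariate-adjusted** (`fit_covariate`): `τ_i ~ Exponential(exp(αᵀx_i))`.
   Identical loop, except the strictly convex M-step for the coefficient
   vector is solved by BFGS with the analytic gradient (covariates
   standardized internally for conditioning and the coefficients mapped
   back). An intercept-only design reproduces the heterogeneous solver
   draw for draw on a shared seed.

A fixed panel of uniform variates is drawn once per fit and reused in
every E-step (common random numbers), which turns the EM update into a
deterministic map and makes stopping rules meaningful at moderate `h`.

## The likelihood degeneracy and early stopping

The penalized likelihood of every variant is *unbounded* along the
direction where dampening rates shrink toward zero while `Ω` rescales:
with `ρ → 1` the prefactor `|Φ_i|^{−p/2}` diverges like
`−p·Σ log(1−ρ²)/2` while the trace term is absorbed by shrinking
`diag(Ω)` toward `1/diag(S)` (the same mechanism as variance collapse in
Gaussian mixtures; the off-diagonal L1 penalty does not control the
diagonal scale). Iterating any of the solvers to stationarity therefore
drifts into a degenerate state — rates at the domain floor and a nearly
complete graph — that is useless scientifically despite having the better
objective value.

The package regularizes this by information-criterion early stopping: at
every outer iteration the EBIC of the current iterate is evaluated (exact
profile likelihood for the homogeneous model; observed-data likelihood by
grid quadrature for the latent-rate models) and the EBIC-best iterate is
returned once the criterion has not improved for `patience = 3`
iterations. The criterion is the same one used for path-level model
selection, so the two levels of selection are coherent. The alternative
stopping rule (`stop_rule="tolerance"`: iterate until parameter changes
fall below `tol`) is retained but converges to the degenerate state in
strongly-correlated regimes and should be used only for diagnosis. For
the same reason, penalty paths do **not** warm-start the dampening
parameters of the latent-rate solvers from the previous penalty value:
every fit must see the same initial state, or fits late in the path
inherit partially collapsed rates.

Relatedly, the diagonal of `Ω` is *not* penalized by default. Penalizing
it shrinks `diag(Ω)` away from `1/diag(S̄)`, which biases the dampening
estimate downward, inflates `S̄`, makes the penalty relatively weaker,
and feeds the same collapse; with the off-diagonal-only penalty the rate
estimates track the generative values. `penalize_diagonal=True` is
available as a flag.

## Model selection

Solution paths are computed over a decreasing log-spaced penalty grid
from `λ_max` (the largest off-diagonal of `S̄` at a pilot estimate of the
dampening rate, beyond which the network is empty) down to
`λ_max × ratio`. Because the scale of `S̄(τ)` grows like `1/(1−ρ²)`, the
pilot matters; it alternates a diagonal precision with the 1-D `τ` step
twice. Networks are selected by the extended BIC

```
EBIC(G) = −2 loglik + |G| log n + |G| log p / T ,  T = 2 ,
```

with natural logarithms, `n` the total row count and each undirected edge
counted once; ties break toward the sparser model.

Two likelihoods play distinct roles for the latent-rate models. The
*observed-data (marginal) likelihood* `∫ f(y_i|τ) α e^{−ατ} dτ` is
evaluated per subject by log-sum-exp quadrature on the same grid the
E-step uses (`marginal_loglik`; the integral is one-dimensional, so no
surrogate is needed) — it is what the within-fit early stopping
monitors, because it is the quantity the degenerate direction inflates
and its EBIC turns sharply against collapsed iterates. The *reported*
`fit.loglik`, used for selection across penalties, is instead the
temporally-whitened Gaussian working likelihood
`(n/2)(log|Ω̂| − tr(S⁽⁰⁾ Ω̂))` at the refinement E-step's scatter: this
is the objective the M-step itself maximizes, and the same formula the
cross-sectional baselines use, so EBIC values are comparable across
methods and across penalty values. (The marginal likelihood is far more
conservative — at `n ≈ 50` rows its per-edge gains rarely exceed the
EBIC edge cost and it selects nearly empty networks; fits carry a
`loglik_kind` flag naming the convention.)

## Synthetic data

The generator reproduces the benchmark study conditions:

- **Network / precision**: Erdős–Rényi support at edge density 0.1
  (default); magnitudes from a G-Wishart `W_G(3, I)` draw via the direct
  sampler (full Wishart draw followed by maximum-determinant completion
  cycles), matching the convention of graph simulators used for such
  benchmarks. `Ω` is rescaled so `Σ` is a correlation matrix, which
  preserves both the graph and the partial correlations. A
  diagonally-dominant scheme (`method="dominance"`, weights ±[0.3, 0.7],
  diagonal = |row sum| + 0.5) is retained as an option; its partial
  correlations are uniformly weak (~0.1) and network recovery under it is
  much harder.
- **Schedules**: `n_i ~ Poisson(mean_ni)` truncated to at least 2 (every
  subject then informs the rates; the untruncated variant would leave
  some subjects uninformative), gaps `max(Poisson(1), 0.5)`.
- **Draws**: `y ~ N(0, Φ_i ⊗ Σ)` through the Cholesky factors of the two
  Kronecker factors. Preset shared rates s1–s4 = 0.36, 0.14, 0.049,
  0.018 span weak to strong temporal correlation (gaps are ~1, so s4
  means lag-one correlation ≈ 0.982).
- **Heterogeneous communities**: a block-diagonal truth over two
  independent taxon blocks, each evolving with its own (possibly random)
  rate.
- **Left-censoring** (`censor_left`): per taxon, values below the pooled
  empirical `q1`-quantile are replaced by that quantile with probability
  `q2`, emulating detection-limit zero inflation. Censored data should be
  re-centered before fitting.

What the generator does *not* emulate: compositional count noise
(multinomial read depth), non-Gaussian margins, time-varying networks,
and taxon-specific dampening beyond the two-block case. Passing tests
therefore demonstrate correctness of the estimator under its own model
and robustness to the two specific violations studied (sub-communities,
censoring), not performance on raw sequencing counts.

## Evaluation

Recovery is scored by TPR/FPR over undirected pairs against the simulated
truth. ROC curves are built exactly as the benchmark protocol specifies:
for each replicate the within-path proportion of networks containing each
edge is computed, proportions are averaged across replicates into
connection probabilities `p_ij`, and the ROC is a threshold sweep over
`p_ij` (AUC by trapezoid). The comparison baselines pool all rows and
ignore the longitudinal correlation: a plain graphical lasso on the
pooled second-moment matrix, and per-node lasso neighborhood selection
with AND-rule symmetrization (OR available). The neighborhood penalty is
on the raw sum-of-squares scale so one λ grid serves all three methods;
its path is selected by the pseudo-likelihood EBIC computed from the
lasso's own residuals (an OLS refit on the selected neighborhoods makes
the residual variance collapse under the near-singular pooled data and
the criterion monotone).

Under strong temporal correlation the pooled covariance has effective
rank far below `p` and scikit-learn's all-at-once coordinate descent can
fail; `glasso_subproblem` then falls back to a block-coordinate-descent
graphical lasso (the classical column-by-column algorithm, built on
scikit-learn's Gram coordinate-descent core) and, as a last resort, to an
accelerated proximal-gradient solver. All three agree to solver tolerance
where they all run.

## Phylogeny concordance

`alr_transform` implements the additive log-ratio preprocessing for raw
counts: taxa with fewer than 10% nonzero observations are pooled into a
composite reference, remaining zeros are replaced by the taxon's minimum
positive value divided by 10, and each taxon is mapped to
`log(taxon/composite)` and centered.

Concordance between an estimated network and a phylogeny is measured by
the Pearson correlation of shortest-path distance vectors over taxon
pairs present in both structures and connected in the network. Tree
distances are topological hop counts through internal nodes by default
(branch-length-weighted distances are an option; Spearman correlation
likewise). Significance comes from a label permutation test: the network
structure is held fixed, taxa are reassigned to its nodes uniformly at
random, and the one-sided p-value uses the add-one convention
`(1 + #{r_perm ≥ r_0}) / (1 + n_perm)`. Permutations only reindex the
precomputed distance matrix, so the test costs one BFS pass regardless of
`n_perm`.

## Numerical choices and defaults

| Parameter | Default | Notes |
| --- | --- | --- |
| `τ` domain | `[1e-4, 1e4]` | avoids the singular `Φ` limit at 0; superset of all benchmark rates |
| posterior grid | 2048 points, log-spaced | quadrature error on posterior means < 1% |
| `h` (E-step draws/subject) | 500 | 10× refinement pass for reported posterior means |
| `tol` (outer stopping) | 1e-3 | relative on rates, absolute max-norm on `Ω` |
| `max_outer` | 20 (EM), 50 (homogeneous) | EBIC early stopping usually triggers first |
| `patience` | 3 | iterations without EBIC improvement before stopping |
| glasso tolerance | 1e-3, 100 iters | support agrees with 1e-6 solves on test problems |
| edge threshold | `1e-8` on `|ω_jk|` | solver sparsity is exact only to tolerance |
| `λ` grid | 8–15 points, ratio 0.02–0.1 | from `λ_max` at the pilot rate |
| EBIC `T` | 2 | conventional value |

Degenerate inputs: subjects with a single observation are accepted (they
inform `Ω` but not the rates); datasets where *no* subject has two
observations fall back to the cross-sectional model with a warning;
duplicate observation times, missing values and rank-deficient covariate
designs are rejected with descriptive errors.

## Problem sizes used in the shipped studies

The packaged tests and the reproduction script run the benchmark designs
at these sizes, chosen to keep a full run on a laptop-class single core
comfortable: likelihood oracles at `p ≤ 3`; recovery probes at `p = 20`
over 20 replicates; the operating-point reproduction at the full
`p = 80`, `m = 10` design over 10 replicates; ROC orderings at `p = 40`
in five batches of three replicates; permutation-test calibration over
500 network/tree pairs at 30 taxa with 200 permutations each.

## Known limitations

- The unbounded-likelihood direction means the reported fits are defined
  by the (documented) early-stopping rule, not by a global optimum; the
  same is true of any procedure for this model family that terminates.
- Under heavy left-censoring (e.g. censoring 40% of the support with
  probability 0.7) the difference-weighted scatter `S̄(τ)` degrades
  faster than the pooled covariance, and the longitudinal solver can lose
  its advantage over the cross-sectional baseline entirely; see the
  censoring acceptance check.
- The EBIC for the latent-rate models uses the quadrature marginal
  likelihood restricted to the `τ` domain; mass outside `[1e-4, 1e4]` is
  ignored.
- Sign recovery of covariate effects on the rates is weak at `m = 10`
  subjects (the effective sample size for `α` is `m`, not `n`).
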