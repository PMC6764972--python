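# Methods

## Model

`mgmix` fits a pairwise exponential-family model over p continuous and q
categorical variables,

    p(x, y; Θ) ∝ exp( ½ Σ_st β_st x_s x_t + Σ_s α_s x_s
                      + Σ_sj ρ_sj(y_j) x_s + Σ_j θ_j(y_j)
                      + Σ_{r<j} φ_rj(y_r, y_j) ).

The continuous block alone is a Gaussian graphical model, the categorical
block alone a pairwise Markov random field; ρ couples the two.  Conditional
independence of a pair given everything else is equivalent to its whole
parameter block (a scalar β_st, a vector ρ_sj, a matrix φ_rj) being zero,
which is what the graph displays.

Identifiability choices:

- **Reference-level coding.**  The first declared level of each categorical
  variable carries exactly zero parameters (ρ_sj[0] = 0, first row/column of
  φ_rj = 0, θ_j[0] = 0).  Binary–anything edges are therefore single signed
  scalars, which is what the network reports.  Sum-to-zero coding would
  spread a binary edge over two tied entries without changing the model.
- **θ_j stored separately** from φ (not as diagonal blocks), avoiding double
  counting in the ½ΣΣ term.
- **β diagonal** is estimated, unpenalized, and kept feasible by projection
  onto β_ss ≤ −ε with ε = 1e-4; −β_ss is node s's conditional precision.

## Pseudo-likelihood and gradient

The joint normalizer is intractable, so the loss is the negative
pseudo-log-likelihood: the average over rows of each node's conditional
log-loss — Gaussian N(A_s/(−β_ss), 1/(−β_ss)) for continuous nodes, softmax
over levels for categorical nodes.  The loss is averaged over n (not summed)
so λ is comparable across sample sizes.  The loss is jointly convex, and its
gradient is analytic; symmetry-tied parameters (β_st, φ entries) accumulate
the derivative of both occurrences.  Correctness is pinned by central
finite differences (relative error < 1e-6 across mixed shapes including the
p = 0 and q = 0 edge cases) and by closed-form limits: at λ = 0 the Gaussian
block reproduces node-wise OLS exactly, and a binary pair reproduces the 2×2
log odds ratio.

## Optimizer

FISTA on the flattened free-parameter vector:

- gradient step at the momentum point, then soft-thresholding of the edge
  parameters only (α, θ, β diagonal are never penalized), then projection of
  the β diagonal;
- backtracking line search (initial step 1.0, halving) against the standard
  proximal quadratic upper bound — no Lipschitz precomputation, which is
  robust for mixed blocks of very different curvature;
- **function-value adaptive restart** (default): if the penalized objective
  would increase, the momentum is discarded and the iteration redone as a
  plain proximal step from the previous iterate.  The accepted objective
  sequence is therefore monotone by construction (asserted in tests).  A
  gradient-based restart and plain ISTA (momentum off) are available;
- stopping at relative objective change < 1e-6 (default), max 10 000
  iterations.  KKT residuals at convergence are < 1e-4 at working tolerance
  and scale down with `tol`.

λ_max (the smallest λ with an empty graph) is computed from the gradient at
the closed-form edge-free optimum (MLE node potentials).  Because tied pair
parameters sum the gradient of both node regressions, λ_max for a duplicated
standardized variable is exactly 2 — twice the empirical correlation — under
this convention.

`edge_parameter_count` reports the number of free edge parameters under the
reference-level coding; note that parameter counts are coding dependent, so
totals from other MGM implementations (e.g. full one-hot codings) need not
match for the same variable set.

Regularization paths are warm-started from the previous solution with
momentum reset; the default grid is 25 log-spaced values from λ_max down to
0.02·λ_max.

## Model selection: relaxed EBIC

`select_lambda(method="ebic")` scores each candidate edge support S on the
path by

    n · loss(refit_S) + k · log n + 2γ · k · log(#penalized parameters),

where refit_S is the *unpenalized* fit restricted to S (all other edge
parameters frozen at zero), k = |S|, and γ = 0.5 by default.  Scoring the
penalized iterates directly conflates shrinkage bias with support: as λ
decreases, the loss keeps improving through the *true* edges, which drags
false positives into the selected model.  Scoring relaxed refits makes the
loss saturate once the true support is included, and the refit — returned as
the selected model — reports edge weights free of L1 shrinkage.  This also
keeps rankings comparable across variable types: lasso shrinkage per unit
effect is roughly λ divided by a coordinate's curvature, which penalizes
low-prevalence binary indicators hardest, distorting |weight| rankings.
K-fold cross-validation on held-out pseudo-log-likelihood is available as an
alternative (`method="cv"`); it returns the penalized fit at the winning λ
and refuses fold splits that lose a categorical level.

## Network and neighborhoods

Each nonzero block collapses to one undirected edge with a scalar signed
weight: β_st itself, the single free ρ/φ entry for binary variables, and the
signed maximum-magnitude entry for blocks with more than two levels — with
the full block's L2 norm retained alongside, so nothing is lost.  A node's
first-order neighborhood (its directly connected nodes, |weight| descending,
ties broken by name) doubles as a predictor without refitting: the Gaussian
conditional mean for continuous centers, the softmax conditional probability
for categorical centers.  Continuous predictions are scored by Pearson
correlation, binary ones by ROC/AUC (normalized Mann–Whitney, ties ½;
one-vs-rest plus macro average for multi-level centers).

## Univariate screening and the adjustment contrast

The screen regresses every variable on every other one — simple linear
regression with a two-sided t test for continuous responses, logistic
regression with a Wald test for binary responses (multi-level responses are
skipped; as predictors they enter via L−1 dummies with a joint F/Wald test).
p-values are floored at 1e-300 before −log10; a Benjamini–Hochberg column is
emitted as supplementary output but never used for ranking.  Perfectly
separated logistic fits fall back to a ridge-penalized Newton fit and are
flagged.

`compare_screens` contrasts, per response, the univariate top association
with the network's top neighbor: unadjusted −log10 p, and adjusted versions
where each pick is re-tested jointly with either the next five predictors of
its own ranking (`top5`) or five shared variables drawn without replacement
from univariate ranks 2–11 (`random5`).  "Next five" excludes the pick and
the response; responses with fewer than six candidate predictors or an empty
neighborhood are excluded and listed.  If a neighborhood has fewer than five
further members, the available ones are used (sparsity is the method's
point); a singleton neighborhood falls back to the univariate ranking for
its confounder set.

## Synthetic data

`make_ground_truth` draws a sparse truth: each pair carries an edge with
probability `density`, nonzero weights uniform on ±[lo, hi] (every free
entry of a multi-level block drawn independently), and β_ss = −(1 + Σ|β_st|).
Diagonal dominance is a conservative sufficient condition for a proper joint
density — it guarantees β ≺ 0 for every categorical configuration.

`gibbs_sample` runs systematic-scan Gibbs (continuous nodes first, then
categorical, fixed order) as several independent chains updated side by side
— per-node updates vectorize across chains, and the pooled draws are less
autocorrelated than a single chain's.  Each chain discards `burn_in = 500`
sweeps and keeps every `thin = 2`-th state; `chains=1` recovers a classical
single chain.  Everything is deterministic given the seed.  Correctness is
checked against closed forms: Gaussian-only sample covariance vs (−β)⁻¹
(max error < 0.02 at 50 000 draws) and binary-pair cell frequencies vs exact
enumeration (< 0.01).

**Benchmark conditions.**  The recovery benchmark is p = 15 continuous +
q = 5 binary variables, density 0.1, weights ±[0.3, 0.6], n = 2000, EBIC
selection: F1 ≥ 0.8 in at least 8 of 10 seeds (observed: 10/10, median
≈ 0.93), with mean F1 non-decreasing over n ∈ {250, 1000, 4000}.

**Mediation hub motif.**  `mediation_hub_truth` plants the constellation in
which marginal screening and the graphical model disagree: a balanced binary
hub z coupled (φ = 3.0) to five binary mediators of ≈ 0.4 prevalence, each
with a direct edge (ρ = 0.5 … 0.4) to a continuous response r, and *no*
direct z–r edge, plus noise variables.  Marginally z aggregates all mediated
paths and outranks every mediator; conditionally only the mediators matter.
A single chain z–m–r cannot produce this reversal for a continuous response
— corr(z, r) = corr(z, m)·corr(m, r) is always below corr(m, r) unless a
direct edge stronger than the mediator's is added, which would defeat the
point — so several parallel paths are essential.  In simulation the
univariate screen crowns z and the fitted network a mediator, and after
top-5 adjustment only the mediator's significance survives, reproducing the
indirect-association phenomenology the method is designed to expose.  The
companion sign-test study uses generic sparse truths (20 continuous + 10
binary variables, density 0.15, n = 2000): pooled over replicates,
adjustment costs the univariate top associations significantly more
significance than the network's top neighbors.

**What the generator does not emulate:** real spectral noise structure,
block correlations of clinical panels, heavy-tailed or skewed laboratory
values, and missingness (the estimator requires complete cases by design).
Passing tests demonstrate correctness of the machinery and the qualitative
confounding phenomenology, not performance on any particular cohort.

## Preprocessing

Continuous variables can be log2 transformed (strictly positive values
enforced) and are scaled to standard units; the standard deviation uses the
n−1 denominator.  The training (center, scale) pair is stored per variable
and replayed verbatim on held-out data — test statistics are never used.
Mean-value subtraction of spectral buckets is subsumed by standardization.
Spectra are aligned by translating each spectrum an integer number of grid
steps so the maximum inside a search window lands on the reference position
(default 8.463 ppm, the formic-acid internal standard); windows without a
peak above median + 3·sd are left unshifted and flagged.  Bucketing sums
intensities over half-open equidistant intervals [c − w/2, c + w/2), default
width 0.01 ppm with centers at odd multiples of 0.005; buckets overlapping
an exclusion region (default: water, 4.40–5.00 ppm; fully configurable) are
dropped.  Train/test splitting takes floor(fraction·n) rows (with a tiny
tolerance so exact rational fractions survive floating point: 2/3 of 3705 is
2470).

## Numerical conventions and degenerate inputs

- p-value floor 1e-300; conditional precision floor ε = 1e-4.
- Constant predictors in the screen are flagged with p = 1 rather than
  raised; rank-deficient adjustment designs are errors naming the collinear
  columns.
- Constant prediction vectors (empty neighborhoods of continuous centers)
  are flagged `undefined` in validation reports; constant scores yield AUC
  0.5 by convention.
- Neighbor ordering ties break lexicographically; all randomized procedures
  take explicit seeds and are reproducible bit for bit.

## Problem sizes used in the shipped checks

Gradient checks use n = 50 rows across mixed shapes; limiting-case
equivalences n = 500–2000; sampler checks 50 000 draws; the recovery
benchmark 10 seeds at n = 2000 plus a 3-replicate n-sweep; the adjustment
contrast 10 replicates at n = 2000 (5 in the acceptance script) and the
mediation motif 10 replicates at n = 1000 (5 in the acceptance script).
These sizes give comfortable Monte-Carlo margins for every asserted
threshold while keeping a full run in the minutes range on one core.

## Known limitations

- Pseudo-likelihood is consistent but not efficient; no standard errors or
  edge-level p-values are provided for the MGM itself (validation is by
  out-of-sample prediction, as intended).
- Pairwise interactions only; no higher-order terms.
- Complete cases only; no imputation.
- The penalty defaults to plain L1 on every free edge entry; a group-L2
  variant (one L2 norm per ρ/φ block, zeroing whole blocks jointly) is
  available via `FitConfig(penalty="group")` but is not used by the default
  selection path.  Multi-level edge collapse (signed max entry) is a
  reporting convention, not part of the model.
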