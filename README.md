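# mgmix — sparse mixed graphical models for multi-layer biomedical data

Large clinical studies assemble variables of very different types: continuous
laboratory values and spectral features next to binary diagnoses, drug
indicators and demographic factors.  The routine way to mine such tables —
regressing every variable on every other and ranking by p-value — cannot tell
a direct association from one mediated by a third variable, and fixing this
post hoc requires knowing which confounders to adjust for.

`mgmix` instead estimates the **joint** distribution of all variables as a
pairwise Mixed Graphical Model (MGM).  An edge connects two variables only if
they remain dependent *given all other variables*, so the network is
intrinsically adjusted for every measured confounder.  The package is aimed at
statistically minded researchers integrating metabolomics/omics layers with
clinical and demographic data, and at methodologists who want a transparent,
testable MGM implementation.

## The model

For p continuous variables x and q categorical variables y (y_j with L_j
levels) the density is

    p(x, y; Θ) ∝ exp( ½ Σ_st β_st x_s x_t + Σ_s α_s x_s
                      + Σ_sj ρ_sj(y_j) x_s + Σ_j θ_j(y_j)
                      + Σ_{r<j} φ_rj(y_r, y_j) )

with Θ = [{β_st}, {α_s}, {ρ_sj}, {φ_rj}].  β is symmetric with negative
diagonal (−β_ss is the conditional precision of x_s); ρ_sj and φ_rj couple
continuous–categorical and categorical–categorical pairs.  Reference-level
coding (first level ≡ 0) makes every edge touching a binary variable a single
signed scalar.

The joint normalizer is intractable, so estimation minimizes the **negative
pseudo-log-likelihood** — the sum of each node's conditional log-loss
(Gaussian for continuous nodes, softmax for categorical ones) — plus an L1
penalty λ·Σ|edge weights| that switches edges off exactly.  The optimizer is
FISTA: proximal gradient steps with Nesterov momentum, backtracking line
search, and function-value adaptive restarts that keep the objective monotone.
λ is chosen by relaxed extended BIC (or cross-validation); the selected model
is the unpenalized refit on the chosen support, so reported edge weights carry
no shrinkage bias.

Around the estimator the package provides the full workflow: mixed-table
loading and validation, log2/standard-unit transforms replayable on held-out
data, spectral bucketing for 1D NMR-style inputs, train/test splitting,
signed-network extraction (GraphML/TSV), out-of-sample validation of
first-order neighborhoods (correlation, ROC/AUC), a univariate screening
module with confounder adjustment for method comparison, and a Gibbs-sampling
synthetic-data generator with known edge support for end-to-end testing.

## Worked example

Simulate from a known sparse model, fit, and validate out of sample:

```python
import numpy as np
from mgmix import (make_ground_truth, gibbs_sample, apply_transforms,
                   transform_like, split_train_test, select_lambda,
                   collapse_edges, first_order_neighborhood,
                   predict_from_neighborhood, pearson_correlation,
                   edge_recovery_metrics)

truth = make_ground_truth(p=15, q=5, density=0.1, weight_range=(0.3, 0.6), seed=0)
data = gibbs_sample(truth, n=3000, seed=1)
train, test = split_train_test(data, 2/3, seed=0)
train_t = apply_transforms(train)              # standard units, stats recorded
test_t = transform_like(test, train_t)         # training affine map replayed

lam, model = select_lambda(train_t, method="ebic")
net = collapse_edges(model)
print(f"selected lambda = {lam:.4f}; network has {net.n_edges()} edges")

m = edge_recovery_metrics(truth, net)
print(f"support recovery vs ground truth: precision {m.precision:.2f}, "
      f"recall {m.recall:.2f}, F1 {m.f1:.2f}")

nb = first_order_neighborhood(net, "x4")
print("neighborhood of x4:", [(n, round(w, 2)) for n, w, _ in nb.neighbors])

scores = predict_from_neighborhood(nb, model, test_t)
r = pearson_correlation(test_t.continuous_column("x4"), np.asarray(scores))
print(f"out-of-sample correlation for x4: {r:.3f}")
```

Output:

```
selected lambda = 0.1204; network has 18 edges
support recovery vs ground truth: precision 1.00, recall 0.86, F1 0.92
neighborhood of x4: [('x8', -0.26), ('x2', -0.2), ('x11', 0.16), ('x1', -0.14)]
out-of-sample correlation for x4: 0.356
```

Reading the numbers: of the 21 true edges the selected network recovers 18
with no false positives; `x4`'s first-order neighborhood (its directly
connected nodes, ordered by |weight|) acts as a linear signature that predicts
`x4` on held-out rows with correlation 0.356 — close to the best achievable
for this node, whose conditional variance is a large share of its marginal
variance.

The same pipeline is scriptable from the shell:

```bash
mgmix simulate --p 15 --q 5 --n 2000 --seed 0 --out-prefix bench
mgmix fit bench_data.csv bench_meta.csv --select ebic --model-out model.json
mgmix network model.json --graphml-out net.graphml --tsv-out edges.tsv
mgmix neighborhood model.json x4
mgmix screen bench_data.csv bench_meta.csv --out screen.tsv
mgmix compare bench_data.csv bench_meta.csv model.json --out compare.tsv
```

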