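"""Out-of-sample validation of first-order neighborhoods.

A fitted neighborhood doubles as a predictor without any refitting: for a
continuous center the conditional mean of its Gaussian conditional is a
linear signature in the neighbors; for a categorical center the softmax
conditional gives class probabilities.  Continuous predictions are scored by
Pearson correlation against held-out truth, binary ones by ROC/AUC (AUC is
the normalized Mann–Whitney U statistic, ties counted 1/2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_auc_score, roc_curve

from .model import EPS_DIAG, MGMParameters, _cat_logits, _cont_linear
from .network import EdgeNetwork, NeighborhoodModel

__all__ = [
    "predict_from_neighborhood",
    "pearson_correlation",
    "roc_auc",
    "validate_all_neighborhoods",
]


def _scores_continuous(params: MGMParameters, s: int, X, Z) -> np.ndarray:
    d = -params.beta[s, s]
    if d < EPS_DIAG:
        raise ValueError("degenerate conditional variance at the center node")
    return _cont_linear(params, X, Z)[:, s] / d


def _probs_categorical(params: MGMParameters, j: int, X, Z) -> np.ndarray:
    sl = params.block_slice(j)
    Zm = Z.copy()
    Zm[:, sl] = 0.0  # the center's own state must not enter its logits
    logits = _cat_logits(params, X, Zm)[:, sl]
    w = np.exp(logits - logits.max(axis=1, keepdims=True))
    return w / w.sum(axis=1, keepdims=True)


def predict_from_neighborhood(
    model: NeighborhoodModel, params: MGMParameters, d_test, refit_on=None
) -> np.ndarray:
    """Per-sample score for the neighborhood's center on a test dataset.

    Continuous center: the conditional mean (a linear signature in the fitted
    edge weights).  Binary center: the conditional probability of level 1.
    Multi-level center: the full probability matrix (n × L).  The test data
    must carry the same variables, transformed with the training affine map.

    ``refit_on``: optionally a *training* dataset; instead of using the
    fitted edge weights directly, an ordinary linear/logistic regression of
    the center on its neighbors is refit there and evaluated on ``d_test``
    (a comparison mode; binary centers only for the logistic variant).
    """
    cont, cat = params.var_names()
    test_names = d_test.var_names()
    needed = [model.center] + model.neighbor_names()
    missing = [v for v in needed if v not in test_names]
    if missing:
        raise ValueError(f"test data lacks variables: {missing}")
    if refit_on is not None:
        return _refit_predict(model, refit_on, d_test)
    X, Z = d_test.continuous_values, d_test.one_hot()
    if model.center in cont:
        return _scores_continuous(params, cont.index(model.center), X, Z)
    j = cat.index(model.center)
    probs = _probs_categorical(params, j, X, Z)
    if params.levels[j] == 2:
        return probs[:, 1]
    return probs


def _refit_predict(model: NeighborhoodModel, d_train, d_test) -> np.ndarray:
    nbrs = model.neighbor_names()
    A_tr = np.column_stack([np.ones(d_train.n)] + [d_train.column(v) for v in nbrs])
    A_te = np.column_stack([np.ones(d_test.n)] + [d_test.column(v) for v in nbrs])
    if model.kind == "continuous":
        coef = np.linalg.lstsq(A_tr, d_train.continuous_column(model.center), rcond=None)[0]
        return A_te @ coef
    import statsmodels.api as sm

    y = d_train.categorical_column(model.center)
    res = sm.Logit(y, A_tr).fit(disp=0, maxiter=200)
    return np.asarray(res.predict(A_te))


def pearson_correlation(truth: np.ndarray, pred: np.ndarray) -> float:
    """Standard Pearson coefficient; errors on degenerate input."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValueError("truth and pred must be 1-D of equal length")
    if len(truth) < 3:
        raise ValueError("need at least 3 observations")
    if truth.std() == 0 or pred.std() == 0:
        raise ValueError("zero variance on one side; correlation undefined")
    return float(stats.pearsonr(truth, pred).statistic)


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC curve points (FPR, TPR at every distinct threshold) and the AUC.

    AUC equals the Mann–Whitney U statistic normalized by the number of
    positive–negative pairs, ties counted 1/2; the curve is integrated
    trapezoidally with thresholds swept from +inf downward.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    y = (labels == classes.max()).astype(int)
    if np.all(scores == scores[0]):
        # constant scores: single non-trivial threshold, chance curve
        points = np.array([[0.0, 0.0], [1.0, 1.0]])
        return points, 0.5
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(roc_auc_score(y, scores))


def validate_all_neighborhoods(
    params: MGMParameters, net: EdgeNetwork, d_test
) -> pd.DataFrame:
    """One validation row per node: correlation (continuous) or AUC (binary).

    Multi-level categorical centers get a one-vs-rest AUC row per level plus
    a macro average.  Degenerate cases (constant prediction, single-class
    test labels) are flagged rather than raised.
    """
    cont, cat = params.var_names()
    X, Z = d_test.continuous_values, d_test.one_hot()
    rows = []
    for s, name in enumerate(cont):
        size = net.graph.degree(name) if name in net.graph else 0
        pred = _scores_continuous(params, s, X, Z)
        truth = X[:, s]
        if pred.std() == 0 or truth.std() == 0:
            rows.append((name, "correlation", np.nan, size, "undefined"))
        else:
            rows.append((name, "correlation", pearson_correlation(truth, pred), size, ""))
    for j, name in enumerate(cat):
        size = net.graph.degree(name) if name in net.graph else 0
        L = params.levels[j]
        probs = _probs_categorical(params, j, X, Z)
        truth = d_test.categorical_column(name)
        if L == 2:
            if len(np.unique(truth)) < 2:
                rows.append((name, "auc", np.nan, size, "single-class"))
            else:
                _, a = roc_auc(truth, probs[:, 1])
                rows.append((name, "auc", a, size, ""))
        else:
            per_level = []
            for l in range(L):
                y = (truth == l).astype(int)
                if len(np.unique(y)) < 2:
                    rows.append((name, f"auc_level_{l}", np.nan, size, "single-class"))
                    continue
                _, a = roc_auc(y, probs[:, l])
                per_level.append(a)
                rows.append((name, f"auc_level_{l}", a, size, ""))
            if per_level:
                rows.append((name, "auc_macro", float(np.mean(per_level)), size, ""))
    return pd.DataFrame(
        rows, columns=["node", "metric", "value", "neighborhood_size", "flag"]
    )
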