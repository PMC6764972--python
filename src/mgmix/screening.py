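"""Univariate association screening and the confounder-adjustment contrast.

The screen regresses every variable on every other variable (linear for
continuous responses, logistic for binary ones) and ranks predictors per
response by −log10 p.  The comparison machinery then contrasts each
response's univariate "top association" against its strongest fitted-network
neighbor ("top neighbor"): both are re-tested after adjusting for either the
next five predictors of the respective ranking, or five shared predictors
drawn at random from univariate ranks 2–11.  Because the graphical model
conditions on all variables at once, its top neighbors should lose less
significance under adjustment than marginal top associations — this module
quantifies that.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MixedDataset
from .network import EdgeNetwork, first_order_neighborhood

__all__ = [
    "ScreeningResult",
    "ComparisonResult",
    "univariate_screen",
    "adjusted_pvalue",
    "mgm_top_neighbors",
    "compare_screens",
]

P_FLOOR = 1e-300


def _neglog10(p: float) -> float:
    return float(-np.log10(max(float(p), P_FLOOR)))


def _predictor_matrix(d: MixedDataset, name: str) -> np.ndarray:
    """Design columns for one predictor: raw column, or L−1 dummies."""
    s = d.spec(name)
    if s.kind == "continuous":
        return d.continuous_column(name)[:, None]
    y = d.categorical_column(name)
    if s.n_levels == 2:
        return y[:, None].astype(float)
    return np.column_stack([(y == l).astype(float) for l in range(1, s.n_levels)])


def _response_kind(d: MixedDataset, name: str) -> str | None:
    s = d.spec(name)
    if s.kind == "continuous":
        return "linear"
    if s.n_levels == 2:
        return "logistic"
    return None  # multi-level responses are outside the screen


def _ridge_logit(Xd: np.ndarray, y: np.ndarray, alpha: float = 1.0, n_iter: int = 50):
    """Ridge-penalized logistic Newton fit; fallback when the MLE separates.

    Returns (coef, cov) with cov from the penalized information matrix.  The
    intercept is not penalized.
    """
    n, k = Xd.shape
    pen = np.full(k, alpha)
    pen[0] = 0.0
    b = np.zeros(k)
    for _ in range(n_iter):
        eta = np.clip(Xd @ b, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        H = Xd.T @ (Xd * W[:, None]) + np.diag(pen)
        g = Xd.T @ (y - mu) - pen * b
        step = np.linalg.solve(H, g)
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(Xd @ b, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1 - mu)
    cov = np.linalg.inv(Xd.T @ (Xd * W[:, None]) + np.diag(pen))
    return b, cov


def _fit_and_test(
    y: np.ndarray, kind: str, pred_cols: np.ndarray, conf_cols: np.ndarray | None
) -> tuple[float, float, bool]:
    """(coefficient, p-value, flagged) for the predictor block in a joint model.

    Linear responses: OLS, two-sided t (single column) or F test (block).
    Binary responses: logistic MLE, Wald z / Wald chi2; on separation or a
    failed MLE, a ridge-penalized fit is used and the result flagged.
    """
    import statsmodels.api as sm

    n = len(y)
    k_pred = pred_cols.shape[1]
    Xd = np.column_stack([np.ones(n), pred_cols]) if conf_cols is None else np.column_stack(
        [np.ones(n), pred_cols, conf_cols]
    )
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("rank-deficient design (collinear predictor/confounder columns)")
    sel = slice(1, 1 + k_pred)

    if kind == "linear":
        res = sm.OLS(y, Xd).fit()
        if k_pred == 1:
            return float(res.params[1]), float(res.pvalues[1]), False
        R = np.zeros((k_pred, Xd.shape[1]))
        R[np.arange(k_pred), 1 + np.arange(k_pred)] = 1.0
        p = float(res.f_test(R).pvalue)
        coefs = res.params[sel]
        return float(coefs[np.argmax(np.abs(coefs))]), p, False

    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
            bse = np.asarray(res.bse)
            if not np.all(np.isfinite(bse)) or np.max(np.abs(res.params)) > 1e3:
                raise np.linalg.LinAlgError("unstable logistic MLE")
            if k_pred == 1:
                return float(res.params[1]), float(res.pvalues[1]), False
            R = np.zeros((k_pred, Xd.shape[1]))
            R[np.arange(k_pred), 1 + np.arange(k_pred)] = 1.0
            p = float(np.squeeze(res.wald_test(R, scalar=True).pvalue))
            coefs = res.params[sel]
            return float(coefs[np.argmax(np.abs(coefs))]), p, False
        except Exception:
            flagged = True
    b, cov = _ridge_logit(Xd, y)
    if k_pred == 1:
        z = b[1] / np.sqrt(cov[1, 1])
        return float(b[1]), float(2 * stats.norm.sf(abs(z))), flagged
    sub = b[sel]
    Vsub = cov[sel, sel]
    chi2 = float(sub @ np.linalg.solve(Vsub, sub))
    return (
        float(sub[np.argmax(np.abs(sub))]),
        float(stats.chi2.sf(chi2, k_pred)),
        flagged,
    )


@dataclasses.dataclass
class ScreeningResult:
    """All pairwise univariate associations with per-response rankings."""

    pairs: pd.DataFrame  # response, predictor, coef, neglog10p, neglog10p_bh, flagged
    responses: list[str]
    skipped: list[str]  # multi-level responses not screened

    def ranking(self, response: str) -> pd.DataFrame:
        """Predictors of ``response`` sorted by −log10 p desc, |coef|, name."""
        sub = self.pairs[self.pairs["response"] == response].copy()
        if sub.empty:
            raise KeyError(f"no screening rows for response {response!r}")
        sub["_abs"] = sub["coef"].abs()
        sub = sub.sort_values(
            ["neglog10p", "_abs", "predictor"], ascending=[False, False, True]
        ).drop(columns="_abs")
        sub["rank"] = np.arange(1, len(sub) + 1)
        return sub.reset_index(drop=True)

    def top_association(self, response: str) -> str:
        return str(self.ranking(response).iloc[0]["predictor"])


def univariate_screen(d: MixedDataset) -> ScreeningResult:
    """Regress each variable on every single remaining variable.

    Continuous responses use simple linear regression with a two-sided t test
    on the slope; binary responses use logistic regression with a Wald test.
    Multi-level categorical responses are listed as skipped (they still act
    as predictors, via dummy encoding).
    """
    from statsmodels.stats.multitest import multipletests

    names = d.var_names()
    rows = []
    responses, skipped = [], []
    n = d.n
    # cache predictor design blocks
    blocks = {name: _predictor_matrix(d, name) for name in names}
    for resp in names:
        kind = _response_kind(d, resp)
        if kind is None:
            skipped.append(resp)
            continue
        responses.append(resp)
        if kind == "logistic":
            y = d.categorical_column(resp).astype(float)
            if len(np.unique(y)) < 2:
                raise ValueError(f"binary response {resp!r} has a single class")
        else:
            y = d.continuous_column(resp)
        for pred in names:
            if pred == resp:
                continue
            P = blocks[pred]
            if np.all(P.std(axis=0) == 0):
                rows.append((resp, pred, 0.0, 0.0, True))
                continue
            if kind == "linear" and P.shape[1] == 1:
                # closed-form simple regression t test
                x = P[:, 0]
                sx, sy = x.std(ddof=1), y.std(ddof=1)
                if sy == 0:
                    rows.append((resp, pred, 0.0, 0.0, True))
                    continue
                r = float(np.corrcoef(x, y)[0, 1])
                r = np.clip(r, -1.0, 1.0)
                if abs(r) == 1.0:
                    p = 0.0
                else:
                    t = r * np.sqrt((n - 2) / (1 - r * r))
                    p = 2 * stats.t.sf(abs(t), n - 2)
                rows.append((resp, pred, r * sy / sx, _neglog10(p), False))
            else:
                coef, p, flagged = _fit_and_test(y, kind, P, None)
                rows.append((resp, pred, coef, _neglog10(p), flagged))
    pairs = pd.DataFrame(
        rows, columns=["response", "predictor", "coef", "neglog10p", "flagged"]
    )
    # supplementary Benjamini–Hochberg column (per response); ranking uses raw p
    bh = np.empty(len(pairs))
    for resp, idx in pairs.groupby("response").groups.items():
        praw = np.power(10.0, -pairs.loc[idx, "neglog10p"].values)
        bh[np.asarray(idx)] = [
            _neglog10(v) for v in multipletests(np.clip(praw, P_FLOOR, 1), method="fdr_bh")[1]
        ]
    pairs["neglog10p_bh"] = bh
    return ScreeningResult(pairs, responses, skipped)


def adjusted_pvalue(
    d: MixedDataset, response: str, predictor: str, confounders: list[str]
) -> float:
    """−log10 p of ``predictor`` in a joint model with the confounders.

    With an empty confounder list this equals the univariate screen result.
    """
    if predictor in confounders or response in confounders or predictor == response:
        raise ValueError("response, predictor and confounders must be distinct")
    kind = _response_kind(d, response)
    if kind is None:
        raise ValueError(f"response {response!r} is neither continuous nor binary")
    y = (
        d.continuous_column(response)
        if kind == "linear"
        else d.categorical_column(response).astype(float)
    )
    P = _predictor_matrix(d, predictor)
    C = (
        np.column_stack([_predictor_matrix(d, c) for c in confounders])
        if confounders
        else None
    )
    if C is not None and np.linalg.matrix_rank(np.column_stack([P, C])) < P.shape[1] + C.shape[1]:
        raise ValueError(
            f"collinear design for response {response!r}: predictor {predictor!r} "
            f"with confounders {confounders}"
        )
    _, p, _ = _fit_and_test(y, kind, P, C)
    return _neglog10(p)


def mgm_top_neighbors(net: EdgeNetwork, response: str, k: int) -> list[str]:
    """Top-k neighbors of ``response`` by absolute collapsed edge weight."""
    if response not in net.graph:
        return []
    return first_order_neighborhood(net, response).neighbor_names()[:k]


@dataclasses.dataclass
class ComparisonResult:
    """Per-response contrast of univariate top association vs MGM top neighbor."""

    table: pd.DataFrame
    excluded: list[str]
    scheme: str

    def summary(self) -> dict:
        out = {}
        for col in ("diff_unadj", "diff_adj"):
            v = self.table[col].values
            if len(v) == 0:
                out[col] = {"positive": np.nan, "negative": np.nan, "zero": np.nan}
                continue
            zero = np.abs(v) < 1e-12
            out[col] = {
                "positive": float(np.mean(v > 1e-12)),
                "negative": float(np.mean(v < -1e-12)),
                "zero": float(np.mean(zero)),
            }
        return out


def _rank_percentiles(v: np.ndarray) -> np.ndarray:
    if len(v) <= 1:
        return np.zeros(len(v))
    order = stats.rankdata(v, method="average") - 1
    return order / (len(v) - 1)


def compare_screens(
    d_train: MixedDataset,
    net: EdgeNetwork,
    scheme: str = "top5",
    seed: int = 0,
    screen: ScreeningResult | None = None,
) -> ComparisonResult:
    """Contrast top univariate associations with top network neighbors.

    For every screenable response the unadjusted −log10 p of both picks is
    recomputed, then re-tested after adjustment: scheme ``top5`` adjusts each
    pick for the next five predictors of its own ranking; ``random5`` adjusts
    both picks for the same five variables drawn (without replacement) from
    univariate ranks 2–11.  Responses with fewer than 6 candidate predictors
    or an empty network neighborhood are excluded and listed.
    """
    if scheme not in ("top5", "random5"):
        raise ValueError("scheme must be 'top5' or 'random5'")
    if screen is None:
        screen = univariate_screen(d_train)
    rng = np.random.default_rng(seed)
    rows, excluded = [], []
    for resp in screen.responses:
        rank = screen.ranking(resp)
        if len(rank) < 6:
            excluded.append(resp)
            continue
        mgm_order = mgm_top_neighbors(net, resp, 6)
        mgm_order = [m for m in mgm_order if m in set(rank["predictor"])]
        if not mgm_order:
            excluded.append(resp)
            continue
        uni_top = str(rank.iloc[0]["predictor"])
        mgm_top = mgm_order[0]
        uni_unadj = float(rank.iloc[0]["neglog10p"])
        mgm_unadj = float(
            rank.loc[rank["predictor"] == mgm_top, "neglog10p"].iloc[0]
        )
        if scheme == "top5":
            uni_conf = list(rank["predictor"].iloc[1:6])
            mgm_conf = [m for m in mgm_order[1:6]]
            if not mgm_conf:  # singleton neighborhood: fall back to its own ranking
                mgm_conf = [v for v in rank["predictor"] if v != mgm_top][:5]
        else:
            pool = list(rank["predictor"].iloc[1:11])
            draw = list(rng.choice(pool, size=min(5, len(pool)), replace=False))
            uni_conf = [v for v in draw if v != uni_top]
            mgm_conf = [v for v in draw if v != mgm_top]
        try:
            uni_adj = adjusted_pvalue(d_train, resp, uni_top, uni_conf)
            mgm_adj = adjusted_pvalue(d_train, resp, mgm_top, mgm_conf)
        except ValueError:
            excluded.append(resp)
            continue
        rows.append(
            {
                "response": resp,
                "uni_top": uni_top,
                "mgm_top": mgm_top,
                "uni_unadj": uni_unadj,
                "mgm_unadj": mgm_unadj,
                "uni_adj": uni_adj,
                "mgm_adj": mgm_adj,
                "diff_unadj": mgm_unadj - uni_unadj,
                "diff_adj": mgm_adj - uni_adj,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "response",
            "uni_top",
            "mgm_top",
            "uni_unadj",
            "mgm_unadj",
            "uni_adj",
            "mgm_adj",
            "diff_unadj",
            "diff_adj",
        ],
    )
    if len(table):
        table["diff_unadj_pct"] = _rank_percentiles(table["diff_unadj"].values)
        table["diff_adj_pct"] = _rank_percentiles(table["diff_adj"].values)
    else:
        table["diff_unadj_pct"] = []
        table["diff_adj_pct"] = []
    return ComparisonResult(table, excluded, scheme)
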