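"""L1-penalized pseudo-likelihood estimation by accelerated proximal gradient.

The estimator minimizes

    F(Theta) = (1/n) Σ_rows neg. pseudo-log-likelihood  +  λ Σ_edges |θ_e|

over the free parameters of the mixed graphical model.  Only edge parameters
(off-diagonal β, ρ, φ) are penalized; node potentials (α, θ) and the β
diagonal are not.  The β diagonal is kept feasible (β_ss ≤ −ε) by projection
inside the proximal step.

The solver is FISTA: a gradient step at the momentum point, soft-thresholding
of the penalized coordinates, Nesterov momentum, and a backtracking line
search against the standard quadratic upper bound.  The default adaptive
restart is function-value based: whenever the penalized objective would
increase, momentum is discarded and the iteration is redone as a plain
proximal-gradient step from the previous iterate, which makes the recorded
objective sequence monotone.  A gradient-based restart criterion is available
as an alternative, as is plain ISTA (momentum off).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np

from .model import (
    EPS_DIAG,
    MGMParameters,
    ParamVectorizer,
    _objective,
)

__all__ = [
    "FitConfig",
    "FitTrace",
    "soft_threshold",
    "prox_step",
    "fit_mgm",
    "lambda_max",
    "regularization_path",
    "select_lambda",
    "default_lambda_grid",
    "kkt_violation",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class FitConfig:
    """Solver settings; ``lam`` is the L1 weight on edge parameters."""

    lam: float = 0.01
    max_iter: int = 10000
    tol: float = 1e-6
    step_init: float = 1.0
    backtracking_factor: float = 0.5
    restart: str = "function"  # "function" | "gradient" | "none"
    momentum: bool = True
    penalty: str = "l1"  # "l1" | "group" (L2 per rho/phi block)
    seed: int = 0

    def validate(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.penalty not in ("l1", "group"):
            raise ValueError("penalty must be 'l1' or 'group'")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.step_init > 0:
            raise ValueError("step_init must be > 0")
        if not 0 < self.backtracking_factor < 1:
            raise ValueError("backtracking_factor must be in (0, 1)")
        if self.restart not in ("function", "gradient", "none"):
            raise ValueError("restart must be function, gradient, or none")


@dataclasses.dataclass
class FitTrace:
    """Per-iteration objective, step size, restart flag, and momentum coefficient."""

    objective: list[float] = dataclasses.field(default_factory=list)
    step: list[float] = dataclasses.field(default_factory=list)
    restarted: list[bool] = dataclasses.field(default_factory=list)
    momentum: list[float] = dataclasses.field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    def record(self, objective: float, step: float, restarted: bool, momentum: float) -> None:
        if not np.isfinite(objective):
            raise FloatingPointError("non-finite objective recorded")
        self.objective.append(float(objective))
        self.step.append(float(step))
        self.restarted.append(bool(restarted))
        self.momentum.append(float(momentum))

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "iteration": np.arange(len(self.objective)),
                "objective": self.objective,
                "step": self.step,
                "restarted": np.asarray(self.restarted, dtype=int),
                "momentum": self.momentum,
            }
        ).to_csv(path, sep="\t", index=False)


def soft_threshold(v, t):
    """Proximal operator of t·|·|: sign(v) · max(|v| − t, 0)."""
    v = np.asarray(v, dtype=float)
    out = np.sign(v) * np.maximum(np.abs(v) - t, 0.0)
    return out if out.ndim else float(out)


def _prox_vec(
    vz: ParamVectorizer,
    v: np.ndarray,
    step: float,
    lam: float,
    frozen: np.ndarray | None = None,
    penalty: str = "l1",
) -> np.ndarray:
    out = v.copy()
    if lam > 0:
        m = vz.penalty_mask
        if penalty == "l1":
            out[m] = soft_threshold(out[m], step * lam)
        else:  # block soft-threshold: b <- b * max(0, 1 - step*lam/||b||)
            ids = vz.penalty_block_ids[m]
            vals = out[m]
            norms = np.sqrt(np.bincount(ids, vals * vals, minlength=vz.n_penalty_blocks))
            scale = np.maximum(0.0, 1.0 - step * lam / np.maximum(norms, 1e-300))
            out[m] = vals * scale[ids]
    if frozen is not None:
        out[frozen] = 0.0
    return vz.project(out)


def _penalty_value(vz: ParamVectorizer, v: np.ndarray, lam: float, penalty: str) -> float:
    if lam == 0:
        return 0.0
    m = vz.penalty_mask
    if penalty == "l1":
        return lam * float(np.abs(v[m]).sum())
    ids = vz.penalty_block_ids[m]
    vals = v[m]
    norms = np.sqrt(np.bincount(ids, vals * vals, minlength=vz.n_penalty_blocks))
    return lam * float(norms.sum())


def prox_step(
    params: MGMParameters,
    gradient: MGMParameters,
    step: float,
    lam: float,
) -> MGMParameters:
    """One proximal-gradient update on the structured parameters.

    Gradient step on everything, soft-threshold on edge parameters only,
    projection of the β diagonal, with symmetry and reference-zero
    constraints re-imposed exactly by the structured reconstruction.
    """
    if not step > 0:
        raise ValueError("step must be > 0")
    vz = ParamVectorizer(params.p, params.levels)
    v = vz.pack(params) - step * vz.pack(gradient)
    return vz.unpack(_prox_vec(vz, v, step, lam))


def _check_standardized(X: np.ndarray) -> None:
    if X.size == 0:
        return
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
    if np.any(np.abs(mu) > 0.01) or np.any(np.abs(sd - 1) > 0.01):
        warnings.warn(
            "continuous variables do not look standardized (|mean| > 0.01 or "
            "|sd - 1| > 0.01); the L1 penalty is scale sensitive",
            stacklevel=3,
        )


def _node_potential_start(X: np.ndarray, Z: np.ndarray, levels, vz: ParamVectorizer) -> np.ndarray:
    """Closed-form unpenalized optimum of the edge-free model (all edges zero)."""
    p = X.shape[1]
    params = MGMParameters.zeros(p, levels)
    if p:
        var = X.var(axis=0)  # MLE denominator: stationarity of the diagonal
        var = np.maximum(var, 1e-8)
        d = 1.0 / var
        params.beta = -np.diag(np.maximum(d, EPS_DIAG))
        params.alpha = X.mean(axis=0) * np.maximum(d, EPS_DIAG)
    if levels:
        off = np.concatenate([[0], np.cumsum(levels)]).astype(int)
        counts = Z.sum(axis=0)
        for j, L in enumerate(levels):
            c = counts[off[j] : off[j] + L]
            if np.any(c == 0):
                raise ValueError(
                    f"categorical variable {j} has an unobserved level; "
                    "edge-free optimum undefined"
                )
            params.theta[off[j] : off[j] + L] = np.log(c / c[0])
        params.theta[off[:-1]] = 0.0
    return vz.pack(params)


def fit_mgm(
    d,
    cfg: FitConfig | None = None,
    init: MGMParameters | None = None,
    _frozen: np.ndarray | None = None,
) -> tuple[MGMParameters, FitTrace]:
    """Fit the L1-penalized mixed graphical model on a complete dataset.

    ``d`` is a MixedDataset (continuous block ideally in standard units; a
    warning is issued otherwise).  Returns the fitted parameters (carrying
    the dataset's variable names/layers) and the iteration trace.
    """
    cfg = cfg or FitConfig()
    cfg.validate()
    X, Z = d.continuous_values, d.one_hot()
    levels = d.levels
    _check_standardized(X)
    vz = ParamVectorizer(X.shape[1], levels)

    meta = dict(
        cont_names=tuple(s.name for s in d.cont_specs),
        cat_names=tuple(s.name for s in d.cat_specs),
        cat_level_labels=tuple(s.levels for s in d.cat_specs),
        layers={s.name: s.layer for s in d.specs},
    )

    def smooth(v: np.ndarray) -> float:
        obj, _ = _objective(vz.unpack(v), X, Z, want_grad=False)
        return obj

    def smooth_grad(v: np.ndarray) -> tuple[float, np.ndarray]:
        obj, g = _objective(vz.unpack(v), X, Z, want_grad=True)
        return obj, vz.pack(g)

    def penalty(v: np.ndarray) -> float:
        return _penalty_value(vz, v, cfg.lam, cfg.penalty)

    if init is not None:
        x = vz.project(vz.pack(init))
    else:
        x = _node_potential_start(X, Z, levels, vz)
    if _frozen is not None:
        x[_frozen] = 0.0
    trace = FitTrace()
    try:
        F_x = smooth(x) + penalty(x)
    except FloatingPointError:
        raise FloatingPointError(
            "objective not finite at the starting point; check the data scaling"
        )
    y = x.copy()
    t = 1.0
    step = cfg.step_init
    x_prev = x.copy()

    for it in range(cfg.max_iter):
        restarted = False
        while True:
            f_y, g_y = smooth_grad(y)
            x_new, f_new, step = _backtrack(
                smooth, vz, y, f_y, g_y, step, cfg, _frozen
            )
            F_new = f_new + penalty(x_new)
            if (
                cfg.momentum
                and cfg.restart == "function"
                and F_new > F_x + 1e-15 * max(1.0, abs(F_x))
            ):
                # reject: drop momentum and redo as plain ISTA from x
                restarted = True
                t = 1.0
                y = x.copy()
                continue
            break

        if cfg.momentum and cfg.restart == "gradient":
            if float(g_y @ (x_new - x)) > 0:
                restarted = True
                t = 1.0

        x_prev = x
        x = x_new
        rel_change = abs(F_x - F_new) / max(1.0, abs(F_x))
        F_x = F_new

        if cfg.momentum:
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            mom = (t - 1.0) / t_new
            if restarted and cfg.restart == "gradient":
                mom = 0.0
                t_new = 1.0
            y = x + mom * (x - x_prev)
            t = t_new
        else:
            mom = 0.0
            y = x.copy()

        trace.record(F_new, step, restarted, mom)
        if rel_change < cfg.tol:
            trace.converged = True
            break
    trace.n_iter = len(trace.objective)

    params = vz.unpack(x, **meta)
    params.validate()
    return params, trace


def _backtrack(smooth, vz, y, f_y, g_y, step, cfg, frozen=None):
    """Halve the step until the proximal quadratic upper bound holds."""
    while True:
        x_new = _prox_vec(vz, y - step * g_y, step, cfg.lam, frozen, cfg.penalty)
        diff = x_new - y
        bound = f_y + float(g_y @ diff) + float(diff @ diff) / (2.0 * step)
        try:
            f_new = smooth(x_new)
        except FloatingPointError:
            f_new = np.inf
        if f_new <= bound + 1e-12 * max(1.0, abs(f_y)):
            return x_new, f_new, step
        step *= cfg.backtracking_factor
        if step < 1e-14:
            raise FloatingPointError(
                "line search failed (diverging objective); try a smaller step_init"
            )


def lambda_max(d) -> float:
    """Smallest λ for which the edge-free model is already optimal.

    Equals the largest absolute gradient over penalized parameters at the
    closed-form node-potential optimum with all edges at zero.
    """
    X, Z = d.continuous_values, d.one_hot()
    vz = ParamVectorizer(X.shape[1], d.levels)
    v0 = _node_potential_start(X, Z, d.levels, vz)
    _, g = _objective(vz.unpack(v0), X, Z, want_grad=True)
    gv = vz.pack(g)
    if not np.any(vz.penalty_mask):
        return 0.0
    return float(np.abs(gv[vz.penalty_mask]).max())


def default_lambda_grid(d, n_lambdas: int = 25, min_ratio: float = 0.02) -> np.ndarray:
    """Log-spaced grid from λ_max down to min_ratio · λ_max."""
    lmax = lambda_max(d)
    if lmax <= 0:
        return np.array([0.0])
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


def regularization_path(
    d, lambdas: Sequence[float], cfg: FitConfig | None = None
) -> list[tuple[float, MGMParameters, FitTrace]]:
    """Warm-started fits along a strictly decreasing positive λ sequence."""
    lambdas = [float(l) for l in lambdas]
    if any(l <= 0 for l in lambdas):
        raise ValueError("path lambdas must be positive")
    if any(b >= a for a, b in zip(lambdas, lambdas[1:])):
        raise ValueError("lambdas must be strictly decreasing")
    cfg = cfg or FitConfig()
    out = []
    init = None
    for lam in lambdas:
        c = dataclasses.replace(cfg, lam=lam)
        params, trace = fit_mgm(d, c, init=init)
        out.append((lam, params, trace))
        init = params  # warm start; momentum resets inside fit_mgm
    return out


def n_nonzero_edges(params: MGMParameters) -> int:
    """Number of nonzero penalized parameters (free-coordinate count)."""
    vz = ParamVectorizer(params.p, params.levels)
    v = vz.pack(params)
    return int(np.count_nonzero(v[vz.penalty_mask]))


def select_lambda(
    d,
    lambdas: Sequence[float] | None = None,
    method: str = "ebic",
    folds: int = 5,
    gamma: float = 0.5,
    seed: int = 0,
    cfg: FitConfig | None = None,
):
    """Choose λ by extended BIC (default) or K-fold cross-validation.

    ebic minimizes  n·loss + k·log n + 2·γ·k·log(#penalized params)  with k
    the number of nonzero penalized parameters; the loss of each candidate
    support is that of its unpenalized restricted refit (relaxed lasso), and
    the winning refit is returned, so reported edge weights are free of L1
    shrinkage bias.  ebic is deterministic.  cv minimizes mean held-out
    negative pseudo-log-likelihood and refits (penalized) on the full data
    at the winning λ.  Returns (chosen λ, fitted parameters).
    """
    if method not in ("ebic", "cv"):
        raise ValueError("method must be 'ebic' or 'cv'")
    cfg = cfg or FitConfig(tol=1e-6, max_iter=3000)
    if lambdas is None:
        lambdas = default_lambda_grid(d)
    lambdas = np.asarray(sorted(set(float(l) for l in lambdas), reverse=True))
    n = d.n

    if method == "ebic":
        path = regularization_path(d, lambdas, cfg)
        vz = ParamVectorizer(d.p, d.levels)
        n_pen = int(np.count_nonzero(vz.penalty_mask))
        best = None
        from .model import neg_pseudo_loglik

        seen: dict[tuple, tuple[float, MGMParameters]] = {}
        for lam, params, _ in path:
            v = vz.pack(params)
            support = vz.penalty_mask & (v != 0.0)
            key = tuple(np.where(support)[0])
            k = len(key)
            if key in seen:
                loss, refit = seen[key]
            else:
                # relaxed refit: unpenalized on the selected support only, so
                # shrinkage bias distorts neither the model-size trade-off nor
                # the reported edge weights
                refit, _ = fit_mgm(
                    d,
                    dataclasses.replace(cfg, lam=0.0),
                    init=params,
                    _frozen=vz.penalty_mask & ~support,
                )
                loss = neg_pseudo_loglik(refit, d)
                seen[key] = (loss, refit)
            score = n * loss + k * np.log(n)
            if n_pen > 0:
                score += 2.0 * gamma * k * np.log(n_pen)
            if best is None or score < best[0] - 1e-12:
                best = (score, lam, refit)
        return best[1], best[2]

    # cross-validation
    if folds < 2:
        raise ValueError("cv needs folds >= 2")
    from sklearn.model_selection import KFold

    from .model import neg_pseudo_loglik

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    idx = np.arange(n)
    splits = list(kf.split(idx))
    # refuse folds that lose a categorical level from training
    for tr, _ in splits:
        Ytr = d.categorical_values[tr]
        for j, L in enumerate(d.levels):
            present = np.unique(Ytr[:, j])
            if len(present) < L:
                raise ValueError(
                    f"degenerate fold: categorical variable "
                    f"{d.cat_specs[j].name!r} loses a level in a training fold; "
                    "use fewer folds or more data"
                )
    losses = np.zeros((len(splits), len(lambdas)))
    for f, (tr, te) in enumerate(splits):
        d_tr, d_te = d.take(tr), d.take(te)
        path = regularization_path(d_tr, lambdas, cfg)
        for i, (_, params, _) in enumerate(path):
            losses[f, i] = neg_pseudo_loglik(params, d_te)
    mean_loss = losses.mean(axis=0)
    i_best = int(np.argmin(mean_loss))
    lam = float(lambdas[i_best])
    path = regularization_path(d, lambdas[: i_best + 1], cfg)
    return lam, path[-1][1]


def kkt_violation(params: MGMParameters, d, lam: float) -> float:
    """Worst first-order optimality violation of the penalized problem.

    For zero penalized parameters: max(|g| − λ, 0); for nonzero ones:
    |g + λ·sign|; for unpenalized free parameters: |g| (β diagonal entries
    strictly inside the feasible region only).
    """
    from .model import grad_neg_pseudo_loglik

    vz = ParamVectorizer(params.p, params.levels)
    v = vz.pack(params)
    gv = vz.pack(grad_neg_pseudo_loglik(params, d))
    m = vz.penalty_mask
    viol = 0.0
    zero = m & (v == 0.0)
    nonzero = m & (v != 0.0)
    if np.any(zero):
        viol = max(viol, float(np.max(np.maximum(np.abs(gv[zero]) - lam, 0.0))))
    if np.any(nonzero):
        viol = max(viol, float(np.max(np.abs(gv[nonzero] + lam * np.sign(v[nonzero])))))
    un = ~m
    un_idx = np.where(un)[0]
    diag_idx = np.arange(vz.sl_diag.start, vz.sl_diag.stop)
    interior = np.ones(len(v), dtype=bool)
    interior[diag_idx] = v[diag_idx] < -EPS_DIAG - 1e-12
    free_un = un & interior
    if np.any(free_un):
        viol = max(viol, float(np.max(np.abs(gv[free_un]))))
    return viol
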