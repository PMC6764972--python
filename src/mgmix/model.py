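"""Pairwise mixed graphical model over continuous and categorical variables.

The joint density is an exponential-family pairwise model

    p(x, y; Theta) ∝ exp( 1/2 ΣΣ β_st x_s x_t  +  Σ α_s x_s
                          + ΣΣ ρ_sj(y_j) x_s  +  Σ θ_j(y_j)
                          + Σ_{r<j} φ_rj(y_r, y_j) )

with p continuous variables x and q categorical variables y (y_j taking one
of L_j levels).  β is symmetric with strictly negative diagonal (−β_ss is the
conditional precision of x_s), ρ_sj is a length-L_j vector coupling x_s with
y_j, φ_rj an L_r × L_j matrix coupling two categorical variables, and θ_j the
categorical node potential.  Identifiability uses reference-level coding: the
first level of every categorical variable carries parameter 0 exactly, so an
edge touching a binary variable is a single signed scalar.

The joint normalizing constant is intractable; estimation goes through the
pseudo-log-likelihood, the sum of each node's conditional log-density given
all other nodes.  Conditionals are Gaussian (continuous nodes) and softmax
(categorical nodes), so the pseudo-log-likelihood and its gradient are exact
and cheap.  Everything here is averaged over rows, making the L1 weight of
the optimizer comparable across sample sizes.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "EPS_DIAG",
    "MGMParameters",
    "ParamVectorizer",
    "log_potential",
    "conditional_continuous",
    "conditional_categorical",
    "neg_pseudo_loglik",
    "grad_neg_pseudo_loglik",
]

# lower bound on the conditional precision −β_ss
EPS_DIAG = 1e-4

_LOG_2PI = float(np.log(2.0 * np.pi))


def _offsets(levels: Sequence[int]) -> np.ndarray:
    """Start index of each categorical block in the stacked one-hot layout."""
    return np.concatenate([[0], np.cumsum(levels)]).astype(int)


@dataclasses.dataclass
class MGMParameters:
    """Parameter set Theta of the pairwise mixed graphical model.

    Shapes (D = sum of level counts):
      beta  : (p, p) symmetric, diagonal < 0
      alpha : (p,)
      rho   : (p, D) — column block j holds ρ_sj; reference columns are 0
      theta : (D,)   — categorical node potentials; reference entries are 0
      phi   : (D, D) symmetric, diagonal blocks 0, reference rows/cols 0

    Optional name/layer metadata travels with the parameters so a fitted
    model is self-describing (network export, prediction on new tables).
    """

    beta: np.ndarray
    alpha: np.ndarray
    rho: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    levels: tuple[int, ...]
    cont_names: tuple[str, ...] | None = None
    cat_names: tuple[str, ...] | None = None
    cat_level_labels: tuple[tuple[str, ...], ...] | None = None
    layers: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.levels = tuple(int(l) for l in self.levels)

    # ---- shape helpers -------------------------------------------------
    @property
    def p(self) -> int:
        return self.beta.shape[0]

    @property
    def q(self) -> int:
        return len(self.levels)

    @property
    def D(self) -> int:
        return int(sum(self.levels))

    @property
    def offsets(self) -> np.ndarray:
        return _offsets(self.levels)

    def block_slice(self, j: int) -> slice:
        off = self.offsets
        return slice(int(off[j]), int(off[j + 1]))

    @classmethod
    def zeros(
        cls,
        p: int,
        levels: Sequence[int] = (),
        diag: float = -1.0,
        **meta,
    ) -> "MGMParameters":
        D = int(sum(levels))
        return cls(
            beta=np.eye(p) * diag,
            alpha=np.zeros(p),
            rho=np.zeros((p, D)),
            theta=np.zeros(D),
            phi=np.zeros((D, D)),
            levels=tuple(levels),
            **meta,
        )

    def copy(self) -> "MGMParameters":
        return dataclasses.replace(
            self,
            beta=self.beta.copy(),
            alpha=self.alpha.copy(),
            rho=self.rho.copy(),
            theta=self.theta.copy(),
            phi=self.phi.copy(),
        )

    # ---- invariants ----------------------------------------------------
    def validate(self, eps: float = EPS_DIAG) -> None:
        p, D = self.p, self.D
        if self.beta.shape != (p, p):
            raise ValueError("beta must be square")
        if not np.array_equal(self.beta, self.beta.T):
            raise ValueError("beta must be symmetric")
        if p and np.any(np.diag(self.beta) > -eps):
            raise ValueError(f"diagonal of beta must be <= -{eps}")
        if self.rho.shape != (p, D) or self.theta.shape != (D,) or self.phi.shape != (D, D):
            raise ValueError("rho/theta/phi shapes inconsistent with levels")
        if not np.array_equal(self.phi, self.phi.T):
            raise ValueError("phi must be symmetric")
        off = self.offsets
        for j, L in enumerate(self.levels):
            if L < 2:
                raise ValueError("categorical variables need at least 2 levels")
            sl = self.block_slice(j)
            if np.any(self.phi[sl, sl] != 0.0):
                raise ValueError("diagonal blocks of phi must be zero")
        ref = off[:-1]
        if D:
            if np.any(self.rho[:, ref] != 0.0) or np.any(self.theta[ref] != 0.0):
                raise ValueError("reference-level entries of rho/theta must be zero")
            if np.any(self.phi[ref, :] != 0.0) or np.any(self.phi[:, ref] != 0.0):
                raise ValueError("reference-level rows/columns of phi must be zero")

    # ---- serialization -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "eps_diag": EPS_DIAG,
            "levels": list(self.levels),
            "beta": self.beta.tolist(),
            "alpha": self.alpha.tolist(),
            "rho": self.rho.tolist(),
            "theta": self.theta.tolist(),
            "phi": self.phi.tolist(),
            "cont_names": list(self.cont_names) if self.cont_names else None,
            "cat_names": list(self.cat_names) if self.cat_names else None,
            "cat_level_labels": [list(t) for t in self.cat_level_labels]
            if self.cat_level_labels
            else None,
            "layers": self.layers,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MGMParameters":
        doc = json.loads(text)
        p = len(doc["alpha"])
        D = int(sum(doc["levels"]))
        return cls(
            beta=np.asarray(doc["beta"], dtype=float).reshape(p, p),
            alpha=np.asarray(doc["alpha"], dtype=float),
            rho=np.asarray(doc["rho"], dtype=float).reshape(p, D),
            theta=np.asarray(doc["theta"], dtype=float),
            phi=np.asarray(doc["phi"], dtype=float).reshape(D, D),
            levels=tuple(doc["levels"]),
            cont_names=tuple(doc["cont_names"]) if doc.get("cont_names") else None,
            cat_names=tuple(doc["cat_names"]) if doc.get("cat_names") else None,
            cat_level_labels=tuple(tuple(t) for t in doc["cat_level_labels"])
            if doc.get("cat_level_labels")
            else None,
            layers=doc.get("layers"),
        )

    def var_names(self) -> tuple[list[str], list[str]]:
        """Continuous and categorical variable names (defaults if unset)."""
        cn = list(self.cont_names) if self.cont_names else [f"x{s + 1}" for s in range(self.p)]
        kn = list(self.cat_names) if self.cat_names else [f"y{j + 1}" for j in range(self.q)]
        return cn, kn


def edge_parameter_count(p: int, levels: Sequence[int]) -> int:
    """Number of free edge parameters under reference-level coding.

    Counts p(p−1)/2 continuous pairs, Σ_j (L_j − 1) free entries per
    continuous–categorical pair, and (L_r − 1)(L_j − 1) per categorical pair.
    The count is coding dependent: one-hot (non-reference) codings of the
    same model have more nominal parameters for the same edges.
    """
    levels = [int(L) for L in levels]
    n = p * (p - 1) // 2
    n += p * sum(L - 1 for L in levels)
    for i, Lr in enumerate(levels):
        for Lj in levels[i + 1 :]:
            n += (Lr - 1) * (Lj - 1)
    return n


def one_hot(y: np.ndarray, levels: Sequence[int]) -> np.ndarray:
    """Stack per-variable one-hot indicators into an (n, D) matrix."""
    y = np.asarray(y, dtype=int)
    n = y.shape[0]
    off = _offsets(levels)
    Z = np.zeros((n, int(off[-1])))
    for j, L in enumerate(levels):
        if np.any((y[:, j] < 0) | (y[:, j] >= L)):
            raise ValueError(f"categorical column {j} has level index outside [0, {L})")
        Z[np.arange(n), off[j] + y[:, j]] = 1.0
    return Z


# ---------------------------------------------------------------------------
# density pieces
# ---------------------------------------------------------------------------

def log_potential(params: MGMParameters, x: np.ndarray, y: np.ndarray) -> float:
    """Unnormalized log density at a single point (x, y)."""
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=int).reshape(-1)
    if x.shape[0] != params.p or y.shape[0] != params.q:
        raise ValueError("x/y lengths inconsistent with parameters")
    z = one_hot(y[None, :], params.levels)[0] if params.q else np.zeros(0)
    val = 0.5 * float(x @ params.beta @ x) + float(params.alpha @ x)
    if params.q:
        val += float(x @ params.rho @ z) + float(params.theta @ z)
        val += 0.5 * float(z @ params.phi @ z)
    return val


def _cont_linear(params: MGMParameters, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """A[i, s] = α_s + Σ_{t≠s} β_st x_it + Σ_j ρ_sj(y_ij); numerator of the mean."""
    beta_off = params.beta - np.diag(np.diag(params.beta)) if params.p else params.beta
    A = np.broadcast_to(params.alpha, (X.shape[0], params.p)).copy()
    if params.p:
        A += X @ beta_off
    if params.q:
        A += Z @ params.rho.T
    return A


def _cat_logits(params: MGMParameters, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Logits[i, c] for every categorical level c (block j = node j's logits)."""
    Logits = np.broadcast_to(params.theta, (Z.shape[0], params.D)).copy()
    if params.p:
        Logits += X @ params.rho
    Logits += Z @ params.phi  # diagonal blocks are zero: no self-contribution
    return Logits


def conditional_continuous(
    params: MGMParameters,
    s: int,
    x: np.ndarray,
    y: np.ndarray,
    eps: float = EPS_DIAG,
) -> tuple[float, float]:
    """Gaussian conditional of node s given all others; the s-th entry of x is ignored.

    Returns (mean, variance) with mean = A_s / (−β_ss), variance = 1 / (−β_ss).
    """
    d = -params.beta[s, s]
    if d < eps:
        raise ValueError(f"degenerate conditional: -beta[{s},{s}] = {d} < {eps}")
    x = np.asarray(x, dtype=float).reshape(1, -1)
    y = np.asarray(y, dtype=int).reshape(1, -1)
    Z = one_hot(y, params.levels) if params.q else np.zeros((1, 0))
    a = _cont_linear(params, x, Z)[0, s]
    return float(a / d), float(1.0 / d)


def conditional_categorical(
    params: MGMParameters, j: int, x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Softmax conditional of categorical node j; the j-th entry of y is ignored."""
    x = np.asarray(x, dtype=float).reshape(1, -1)
    y = np.asarray(y, dtype=int).copy().reshape(1, -1)
    y[0, j] = 0  # value irrelevant (diagonal block of phi is zero); keep index valid
    Z = one_hot(y, params.levels) if params.q else np.zeros((1, 0))
    logits = _cat_logits(params, x, Z)[0, params.block_slice(j)]
    w = np.exp(logits - logits.max())
    return w / w.sum()


# ---------------------------------------------------------------------------
# pseudo-log-likelihood
# ---------------------------------------------------------------------------

def _as_arrays(d) -> tuple[np.ndarray, np.ndarray]:
    """Accept a MixedDataset or a (X, Z) pair."""
    if isinstance(d, tuple):
        return d
    return d.continuous_values, d.one_hot()


def _objective(params: MGMParameters, X: np.ndarray, Z: np.ndarray,
               want_grad: bool) -> tuple[float, MGMParameters | None]:
    n = X.shape[0]
    p, q, D = params.p, params.q, params.D
    obj = 0.0
    E = np.zeros((n, 0))
    A = np.zeros((n, 0))
    d = np.zeros(0)
    if p:
        d = -np.diag(params.beta)
        if np.any(d < EPS_DIAG):
            raise ValueError("degenerate conditional: some -beta_ss below eps")
        A = _cont_linear(params, X, Z)
        M = A / d
        E = X - M
        obj += 0.5 * p * _LOG_2PI - 0.5 * float(np.log(d).sum())
        obj += 0.5 * float(np.mean(E * E * d, axis=0).sum())
    Delta = np.zeros((n, 0))
    if q:
        Logits = _cat_logits(params, X, Z)
        P = np.empty_like(Logits)
        for j in range(q):
            sl = params.block_slice(j)
            Lj = Logits[:, sl]
            lse = logsumexp(Lj, axis=1)
            obs = np.sum(Lj * Z[:, sl], axis=1)
            obj += float(np.mean(lse - obs))
            P[:, sl] = np.exp(Lj - lse[:, None])
        Delta = P - Z
    if not np.isfinite(obj):
        raise FloatingPointError("non-finite pseudo-log-likelihood")
    if not want_grad:
        return obj, None

    g = MGMParameters.zeros(p, params.levels)
    g.beta[:] = 0.0
    if p:
        g.alpha = -E.mean(axis=0)
        g.beta = -(E.T @ X + X.T @ E) / n
        gd = np.mean(0.5 * X * X - 0.5 * (A / d) ** 2, axis=0) - 0.5 / d
        np.fill_diagonal(g.beta, -gd)
    if q:
        g.theta = Delta.mean(axis=0)
        g.phi = (Z.T @ Delta + Delta.T @ Z) / n
        if p:
            g.rho = (X.T @ Delta - E.T @ Z) / n
        off = params.offsets
        ref = off[:-1]
        g.theta[ref] = 0.0
        if p:
            g.rho[:, ref] = 0.0
        g.phi[ref, :] = 0.0
        g.phi[:, ref] = 0.0
        for j in range(q):
            sl = params.block_slice(j)
            g.phi[sl, sl] = 0.0
    return obj, g


def neg_pseudo_loglik(params: MGMParameters, d) -> float:
    """Average (over rows) negative pseudo-log-likelihood of the dataset."""
    X, Z = _as_arrays(d)
    obj, _ = _objective(params, X, Z, want_grad=False)
    return obj


def grad_neg_pseudo_loglik(params: MGMParameters, d) -> MGMParameters:
    """Exact analytic gradient, in an MGMParameters-shaped container.

    Symmetry-tied parameters (off-diagonal β, φ) carry the *full* derivative
    of the tied parameter at each mirrored position; reference-level entries
    are forced to zero.
    """
    X, Z = _as_arrays(d)
    _, g = _objective(params, X, Z, want_grad=True)
    return g


# ---------------------------------------------------------------------------
# flat free-parameter view used by the optimizer
# ---------------------------------------------------------------------------

class ParamVectorizer:
    """Bijection between MGMParameters and a flat vector of free parameters.

    Layout: [alpha | beta diagonal | beta upper triangle | free rho entries |
    free theta entries | free phi entries (upper, cross-block, non-reference)].
    The penalty mask marks exactly the edge parameters (β off-diagonal, ρ, φ).
    """

    def __init__(self, p: int, levels: Sequence[int]):
        self.p = int(p)
        self.levels = tuple(int(l) for l in levels)
        self.q = len(self.levels)
        self.D = int(sum(self.levels))
        off = _offsets(self.levels)
        self.offsets = off
        ref = off[:-1]
        nonref = np.ones(self.D, dtype=bool)
        if self.D:
            nonref[ref] = False
        self.free_cols = np.where(nonref)[0]
        self.iu = np.triu_indices(self.p, 1)
        grp = np.repeat(np.arange(self.q), self.levels) if self.q else np.zeros(0, int)
        a, b = np.triu_indices(self.D, 1)
        keep = np.zeros(a.shape, dtype=bool)
        if self.D:
            keep = (grp[a] != grp[b]) & nonref[a] & nonref[b]
        self.phi_a, self.phi_b = a[keep], b[keep]

        n_alpha = self.p
        n_diag = self.p
        n_bu = len(self.iu[0])
        n_rho = self.p * len(self.free_cols)
        n_theta = len(self.free_cols)
        n_phi = len(self.phi_a)
        bounds = np.cumsum([0, n_alpha, n_diag, n_bu, n_rho, n_theta, n_phi])
        self.sl_alpha = slice(bounds[0], bounds[1])
        self.sl_diag = slice(bounds[1], bounds[2])
        self.sl_bu = slice(bounds[2], bounds[3])
        self.sl_rho = slice(bounds[3], bounds[4])
        self.sl_theta = slice(bounds[4], bounds[5])
        self.sl_phi = slice(bounds[5], bounds[6])
        self.size = int(bounds[6])
        self.penalty_mask = np.zeros(self.size, dtype=bool)
        self.penalty_mask[self.sl_bu] = True
        self.penalty_mask[self.sl_rho] = True
        self.penalty_mask[self.sl_phi] = True

        # block ids over penalized coordinates (for the group-L2 variant):
        # each beta pair is its own block, each rho_{sj} vector one block,
        # each phi_{rj} matrix one block; -1 marks unpenalized coordinates
        ids = np.full(self.size, -1, dtype=int)
        nxt = 0
        ids[self.sl_bu] = np.arange(nxt, nxt + n_bu)
        nxt += n_bu
        if self.p and len(self.free_cols):
            rho_block = np.repeat(
                np.arange(self.p * self.q).reshape(self.p, self.q),
                [l - 1 for l in self.levels],
                axis=1,
            )
            ids[self.sl_rho] = nxt + rho_block.ravel()
            nxt += self.p * self.q
        if len(self.phi_a):
            pair = grp[self.phi_a] * self.q + grp[self.phi_b]
            _, phi_block = np.unique(pair, return_inverse=True)
            ids[self.sl_phi] = nxt + phi_block
        self.penalty_block_ids = ids
        self.n_penalty_blocks = int(ids.max() + 1) if self.size else 0

    def pack(self, params: MGMParameters) -> np.ndarray:
        v = np.empty(self.size)
        v[self.sl_alpha] = params.alpha
        v[self.sl_diag] = np.diag(params.beta) if self.p else []
        v[self.sl_bu] = params.beta[self.iu]
        v[self.sl_rho] = params.rho[:, self.free_cols].ravel()
        v[self.sl_theta] = params.theta[self.free_cols]
        v[self.sl_phi] = params.phi[self.phi_a, self.phi_b]
        return v

    def unpack(self, v: np.ndarray, **meta) -> MGMParameters:
        params = MGMParameters.zeros(self.p, self.levels, **meta)
        params.alpha = v[self.sl_alpha].copy()
        beta = np.zeros((self.p, self.p))
        beta[self.iu] = v[self.sl_bu]
        beta = beta + beta.T
        np.fill_diagonal(beta, v[self.sl_diag])
        params.beta = beta
        params.rho = np.zeros((self.p, self.D))
        if self.p and len(self.free_cols):
            params.rho[:, self.free_cols] = v[self.sl_rho].reshape(self.p, len(self.free_cols))
        params.theta = np.zeros(self.D)
        params.theta[self.free_cols] = v[self.sl_theta]
        phi = np.zeros((self.D, self.D))
        phi[self.phi_a, self.phi_b] = v[self.sl_phi]
        params.phi = phi + phi.T
        return params

    def project(self, v: np.ndarray, eps: float = EPS_DIAG) -> np.ndarray:
        """Project the β diagonal onto the feasible set β_ss <= -eps (in place)."""
        v[self.sl_diag] = np.minimum(v[self.sl_diag], -eps)
        return v
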