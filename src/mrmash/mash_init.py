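"""Weight initialization for dense architectures via a mash-style pre-fit.

Empirical-Bayes weight updates inside the engine can over-shrink effects on
very polygenic traits (the weights on the null and small-variance components
get over-estimated).  The two-step remedy: estimate the mixture weights on a
set of semi-independent LD-pruned variants ignoring LD (the mash weight fit),
reset the null weight to 0.5 rescaling the rest proportionally, and hand the
weights to the engine constrained to update them for only the first 10
sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .engine import FitOptions, ModelFit, fit_mrmash_rss, _safe_log
from .priors import MixturePrior
from .sumstats import LDMatrix, SufficientStats

__all__ = [
    "PrunedSet",
    "ld_prune",
    "fit_mash_weights",
    "rescale_null",
    "constrained_fit",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class PrunedSet:
    """Indices of semi-independent variants after greedy LD pruning."""

    indices: list[int]
    r2_threshold: float


def ld_prune(
    ld: LDMatrix,
    r2_threshold: float = 0.1,
    priority: str = "position",
    z: Optional[np.ndarray] = None,
) -> PrunedSet:
    """Greedy LD pruning: keep a variant iff its squared correlation with
    every previously kept variant is at most ``r2_threshold``.

    ``priority="position"`` scans in index order; ``priority="max_z"`` scans
    by decreasing per-variant max |z| (ties broken by index), so the
    strongest signals are kept. Deterministic given inputs.
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must lie in (0, 1]")
    p = ld.p
    if priority == "position":
        order = np.arange(p)
    elif priority == "max_z":
        if z is None:
            raise ValueError("priority='max_z' requires z")
        z = np.asarray(z, dtype=float)
        if z.shape[0] != p:
            raise ValueError("z must have one row per variant")
        score = np.max(np.abs(np.atleast_2d(z.T).T), axis=1)
        order = np.argsort(-score, kind="stable")
    else:
        raise ValueError("priority must be 'position' or 'max_z'")

    R2 = ld.R**2
    kept: list[int] = []
    for j in order:
        if all(R2[j, k] <= r2_threshold for k in kept):
            kept.append(int(j))
    kept.sort()
    return PrunedSet(indices=kept, r2_threshold=float(r2_threshold))


def fit_mash_weights(
    bhat: np.ndarray,
    se: np.ndarray,
    S0: np.ndarray | Sequence[np.ndarray],
    w_init: Optional[np.ndarray] = None,
    max_iter: int = 20_000,
    tol: float = 1e-8,
) -> np.ndarray:
    """Maximum-likelihood mixture weights on (approximately) independent
    summary statistics, ignoring LD.

    Maximizes Σ_j log Σ_k w_k N(b̂_j; 0, S0_k + Ŝ_j) over the simplex with
    Ŝ_j = diag(se_j²) (errors independent across phenotypes at this step),
    by EM on the weights.  The component log-likelihood matrix is fixed, so
    each EM step is exact and the objective is monotone.  Warns and returns
    the current weights if not converged after ``max_iter`` iterations.
    """
    bhat = np.atleast_2d(np.asarray(bhat, dtype=float))
    se = np.atleast_2d(np.asarray(se, dtype=float))
    if bhat.shape != se.shape:
        raise ValueError("bhat and se must have the same shape")
    if np.any(se <= 0):
        raise ValueError("se must be strictly positive")
    S0 = np.asarray(S0, dtype=float)
    if S0.ndim == 2:
        S0 = S0[None]
    m, r = bhat.shape
    K = S0.shape[0]
    if K == 1:
        return np.ones(1)

    # fixed (m, K) log-likelihood matrix
    L = np.empty((m, K))
    for j in range(m):
        Shat = np.diag(se[j] ** 2)
        C = S0 + Shat[None]  # (K, r, r)
        Lc = np.linalg.cholesky(C)
        sol = np.linalg.solve(C, bhat[j])  # (K, r) via batched solve
        quad = np.einsum("kr,r->k", sol, bhat[j])
        logdet = 2.0 * np.sum(np.log(np.diagonal(Lc, axis1=1, axis2=2)), axis=1)
        L[j] = -0.5 * r * _LOG2PI - 0.5 * logdet - 0.5 * quad

    w = np.full(K, 1.0 / K) if w_init is None else np.asarray(w_init, dtype=float)
    w = w / w.sum()
    obj_prev = -np.inf
    for it in range(max_iter):
        logpost = L + _safe_log(w)
        logm = logsumexp(logpost, axis=1)  # (m,)
        obj = float(np.sum(logm))
        gamma = np.exp(logpost - logm[:, None])
        w = gamma.mean(axis=0)
        w = w / w.sum()
        if obj - obj_prev < tol * max(1.0, abs(obj)) and it > 0:
            return w
        obj_prev = obj
    warnings.warn(
        f"mash weight EM did not converge in {max_iter} iterations",
        RuntimeWarning,
    )
    return w


def rescale_null(w: np.ndarray, null_weight: float = 0.5) -> np.ndarray:
    """Pin the null component's weight, rescaling the rest proportionally.

    The null component is index 0; output[0] = ``null_weight`` and the
    remaining weights keep their relative proportions.  Idempotent.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("w must be a vector with at least two components")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-10:
        raise ValueError("w must be on the simplex")
    if not (0 < null_weight < 1):
        raise ValueError("null_weight must lie in (0, 1)")
    rest = w[1:].sum()
    if rest <= 0:
        raise ValueError("all non-null weights are zero; cannot rescale")
    out = np.empty_like(w)
    out[0] = null_weight
    out[1:] = (1.0 - null_weight) * w[1:] / rest
    return out


def constrained_fit(
    ss: SufficientStats,
    prior: MixturePrior,
    V_init: Optional[np.ndarray] = None,
    opts: Optional[FitOptions] = None,
    w0_update_max_iters: int = 10,
) -> ModelFit:
    """Engine fit with weight updates limited to the first few sweeps.

    Used after mash initialization: the externally estimated weights stay
    adaptive for ``w0_update_max_iters`` sweeps (default 10) and are frozen
    thereafter.
    """
    opts = opts or FitOptions()
    opts = replace(opts, update_w0=True, w0_update_max_iters=w0_update_max_iters)
    if w0_update_max_iters == 0:
        opts = replace(opts, update_w0=False)
    return fit_mrmash_rss(ss, prior, V_init=V_init, opts=opts)
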