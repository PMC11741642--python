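"""Coordinate-ascent variational empirical Bayes for mr.mash-rss.

The model is Y = XB + E with matrix-normal residuals (row covariance I_n,
column covariance V) and a mixture-of-multivariate-normals prior on the rows
of B.  The fit touches the data only through the sufficient statistics
(XᵀX, XᵀY, YᵀY, n).  The variational family factorizes over variants; each
coordinate update is the exact conjugate posterior of b_j given the current
residualized estimate

    b̂_j = (XᵀY_j − (XᵀX B̄)_j + d_j B̄_j) / d_j ,     b̂_j | b_j ~ N(b_j, V / d_j),

so per component k the posterior is Gaussian with

    Σ1_k = S0_k (S0_k + V/d_j)⁻¹ (V/d_j),   μ1_k = S0_k (S0_k + V/d_j)⁻¹ b̂_j,

and responsibilities γ_jk ∝ w0_k N(b̂_j; 0, S0_k + V/d_j).  Writing the prior
in the coordinates whitened by V (b → L⁻¹b with V = LLᵀ) and eigendecomposing
each whitened component turns every per-variant solve into elementwise
arithmetic, which also keeps rank-deficient components (null, singletons,
rank-1 data-driven) inversion-free.

The ELBO is exact: because each q_j is the exact conjugate posterior at the
b̂_j used when it was last updated, its KL to the prior is
E_q[log N(b̂_j; b_j, V/d_j)] − log Σ_k w0_k N(b̂_j; 0, S0_k + V/d_j), so the
ELBO can be assembled from per-variant terms plus the expected residual
sum of squares.  Coordinate ascent and the closed-form M-steps for w0 and V
each increase it, hence the nondecreasing-trace invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import logsumexp

from .priors import MixturePrior
from .sumstats import SufficientStats

__all__ = [
    "FitOptions",
    "ModelFit",
    "fit_mrmash_rss",
    "posterior_per_variant",
    "update_w0",
    "update_V",
    "compute_elbo",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))
ELBO_DECREASE_TOL = 1e-8
V_EIG_FLOOR = 1e-8


@dataclass
class FitOptions:
    """Knobs of the coordinate-ascent fit.

    ``w0_update_max_iters`` caps empirical-Bayes weight updates to the first
    so-many sweeps (None = every sweep); freezing the weights early guards
    against over-shrinkage on very polygenic traits when the weights were
    initialized externally. ``update_V`` requires YᵀY.
    """

    tol: float = 1e-6
    max_iter: int = 500
    update_w0: bool = True
    w0_update_max_iters: Optional[int] = None
    update_V: bool = False
    seed: int = 0
    update_order: str = "fixed"  # or "shuffled"

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.update_order not in ("fixed", "shuffled"):
            raise ValueError("update_order must be 'fixed' or 'shuffled'")


@dataclass
class ModelFit:
    """Result of a variational fit.

    ``M2_sum`` is Σ_j E_q[b_j b_jᵀ] and ``d_cov_sum`` the d-weighted posterior
    covariance sum Σ_j d_j (M2_j − b̄_j b̄_jᵀ) entering the residual update;
    per-variant r×r second moments are not stored, to bound memory at
    biobank-scale p. ``bhat`` records the residualized estimates each q_j was
    last formed from, which makes the variational state reconstructible.
    """

    B_bar: np.ndarray
    gamma: np.ndarray
    w0_fit: np.ndarray
    V_fit: np.ndarray
    elbo_trace: np.ndarray
    converged: bool
    n_iter: int
    M2_sum: np.ndarray
    d_cov_sum: np.ndarray
    bhat: np.ndarray
    variant_ids: Optional[list[str]] = None
    phenotype_ids: Optional[list[str]] = None


class _WhitenedPrior:
    """Prior components eigendecomposed in V-whitened coordinates."""

    def __init__(self, prior: MixturePrior, V: np.ndarray):
        r = prior.r
        V = (V + V.T) / 2.0
        try:
            L = cholesky(V, lower=True)
        except np.linalg.LinAlgError as e:  # pragma: no cover
            raise ValueError("V must be positive definite") from e
        self.V = V
        self.L = L
        self.Linv = solve_triangular(L, np.eye(r), lower=True)
        self.logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
        S0t = np.einsum("ab,kbc,dc->kad", self.Linv, prior.S0, self.Linv)
        S0t = (S0t + np.transpose(S0t, (0, 2, 1))) / 2.0
        lam, Q = np.linalg.eigh(S0t)
        self.lam = np.clip(lam, 0.0, None)  # (K, r)
        self.Q = Q  # (K, r, r), columns are eigenvectors
        self.r = r
        self.K = prior.K


def _variant_update(
    bt: np.ndarray, d: float, wp: _WhitenedPrior, logw0: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Exact conjugate update for one variant, in whitened coordinates.

    Returns (gamma_j, b̄_j whitened, M2_j whitened, log evidence,
    E_q log-likelihood of b̂_j) — the last two are the per-variant ELBO pieces.
    """
    s = 1.0 / d
    z = np.einsum("ksi,s->ki", wp.Q, bt)  # Qₖᵀ b̃
    denom = wp.lam + s  # eigenvalues of S̃0ₖ + I/d
    loglik = (
        -0.5 * wp.r * _LOG2PI
        - 0.5 * wp.logdetV
        - 0.5 * np.sum(np.log(denom), axis=1)
        - 0.5 * np.sum(z * z / denom, axis=1)
    )
    logpost = logw0 + loglik
    logm = float(logsumexp(logpost))
    gamma = np.exp(logpost - logm)

    shrink = wp.lam / denom  # eigenvalues of S̃0ₖ(S̃0ₖ + I/d)⁻¹
    mu_t = np.einsum("kir,kr->ki", wp.Q, shrink * z)  # (K, r)
    svar = shrink * s  # eigenvalues of Σ̃1ₖ
    btbar = gamma @ mu_t
    M2t = np.einsum("k,kir,kr,kjr->ij", gamma, wp.Q, svar, wp.Q)
    M2t += np.einsum("k,ki,kj->ij", gamma, mu_t, mu_t)

    resid = bt - btbar
    trace_cov = float(np.trace(M2t)) - float(btbar @ btbar)
    eqll = (
        -0.5 * wp.r * _LOG2PI
        - 0.5 * (wp.logdetV - wp.r * np.log(d))
        - 0.5 * d * (float(resid @ resid) + trace_cov)
    )
    return gamma, btbar, M2t, logm, eqll


def _safe_log(w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(w)


def _trace_vinv(Linv: np.ndarray, M: np.ndarray) -> float:
    """tr(V⁻¹ M) via the whitening factor."""
    return float(np.einsum("ij,jk,ik->", Linv, M, Linv))


def fit_mrmash_rss(
    ss: SufficientStats,
    prior: MixturePrior,
    V_init: Optional[np.ndarray] = None,
    opts: Optional[FitOptions] = None,
) -> ModelFit:
    """Fit the model by coordinate-ascent variational empirical Bayes.

    Starting from B̄ = 0, each sweep updates every variant's posterior in
    turn (maintaining residual cross-products incrementally), then optionally
    re-estimates the mixture weights and the residual covariance V by their
    closed-form M-steps.  Stops when the relative ELBO change drops below
    ``opts.tol`` or after ``opts.max_iter`` sweeps.  The recorded ELBO at
    sweep s reflects the variational state after that sweep's coordinate
    updates and before its M-steps, which keeps the trace nondecreasing.

    Without YᵀY the ELBO omits the constant −½ tr(V⁻¹YᵀY) term (V must then
    stay fixed); convergence and monotonicity are unaffected.
    """
    opts = opts or FitOptions()
    if prior.r != ss.r:
        raise ValueError(f"prior has r={prior.r} but sufficient stats r={ss.r}")
    if opts.update_V and ss.YtY is None:
        raise ValueError("update_V requires YtY; run with V fixed instead")
    p, r, K = ss.p, ss.r, prior.K
    d = ss.d
    if np.any(d <= 0):
        raise ValueError("XtX diagonal must be strictly positive")

    if V_init is None:
        V = ss.YtY / ss.n if ss.YtY is not None else np.eye(r)
    else:
        V = np.asarray(V_init, dtype=float)
    V = _floor_pd(V)
    w0 = prior.w0.copy()
    wp = _WhitenedPrior(prior, V)
    rng = np.random.default_rng(opts.seed)

    B_bar = np.zeros((p, r))
    Bt = np.zeros((p, r))  # whitened rows L⁻¹ b̄_j
    gamma = np.zeros((p, K))
    bhat = np.zeros((p, r))
    elbo_trace: list[float] = []
    converged = False
    M2_sum = np.zeros((r, r))
    d_cov_sum = np.zeros((r, r))

    for sweep in range(opts.max_iter):
        logw0 = _safe_log(w0)
        order = rng.permutation(p) if opts.update_order == "shuffled" else range(p)
        T = ss.XtY - ss.XtX @ B_bar  # residual cross-products, refreshed per sweep
        M2_sum.fill(0.0)
        d_cov_sum.fill(0.0)
        logm_sum = 0.0
        eqll_sum = 0.0
        for j in order:
            bhat_j = T[j] / d[j] + B_bar[j]
            bt = wp.Linv @ bhat_j
            g, btbar, M2t, logm, eqll = _variant_update(bt, d[j], wp, logw0)
            new_b = wp.L @ btbar
            delta = new_b - B_bar[j]
            if np.any(delta):
                T -= np.outer(ss.XtX[:, j], delta)
            B_bar[j] = new_b
            Bt[j] = btbar
            gamma[j] = g
            bhat[j] = bhat_j
            M2 = wp.L @ M2t @ wp.L.T
            M2_sum += M2
            d_cov_sum += d[j] * (M2 - np.outer(new_b, new_b))
            logm_sum += logm
            eqll_sum += eqll

        erss = _expected_rss(ss, B_bar, T, d_cov_sum)
        elbo = _assemble_elbo(ss, wp, erss, eqll_sum, logm_sum)
        if not np.isfinite(elbo):
            raise FloatingPointError(
                f"non-finite ELBO at sweep {sweep + 1}; check inputs for scale issues"
            )
        if elbo_trace:
            prev = elbo_trace[-1]
            if prev - elbo > ELBO_DECREASE_TOL * max(1.0, abs(prev)):
                raise RuntimeError(
                    f"ELBO decreased at sweep {sweep + 1} "
                    f"({prev:.10g} -> {elbo:.10g}); this indicates an update bug"
                )
        elbo_trace.append(elbo)
        logger.info("sweep %d: elbo=%.8f max|dB|=%.3e", sweep + 1, elbo,
                    float(np.max(np.abs(B_bar))) if p else 0.0)

        if len(elbo_trace) > 1:
            rel = abs(elbo_trace[-1] - elbo_trace[-2]) / max(1.0, abs(elbo_trace[-1]))
            if rel < opts.tol:
                converged = True
        if converged or sweep == opts.max_iter - 1:
            break  # keep (w0, V) as used in the last recorded sweep

        if opts.update_w0 and (
            opts.w0_update_max_iters is None or sweep < opts.w0_update_max_iters
        ):
            w0 = update_w0(gamma)
        if opts.update_V:
            V = _floor_pd(erss / ss.n)
            wp = _WhitenedPrior(prior, V)

    return ModelFit(
        B_bar=B_bar,
        gamma=gamma,
        w0_fit=w0,
        V_fit=V,
        elbo_trace=np.asarray(elbo_trace),
        converged=converged,
        n_iter=len(elbo_trace),
        M2_sum=M2_sum,
        d_cov_sum=d_cov_sum,
        bhat=bhat,
        variant_ids=list(ss.variant_ids) if ss.variant_ids else None,
        phenotype_ids=list(ss.phenotype_ids) if ss.phenotype_ids else None,
    )


def _expected_rss(
    ss: SufficientStats,
    B_bar: np.ndarray,
    T: np.ndarray,
    d_cov_sum: np.ndarray,
) -> np.ndarray:
    """E_q[(Y − XB)ᵀ(Y − XB)], using XᵀX B̄ = XᵀY − T.

    Without YᵀY the YᵀY term is omitted (an additive constant for fixed V).
    """
    erss = -ss.XtY.T @ B_bar - B_bar.T @ T + d_cov_sum
    if ss.YtY is not None:
        erss = erss + ss.YtY
    return (erss + erss.T) / 2.0


def _assemble_elbo(
    ss: SufficientStats,
    wp: _WhitenedPrior,
    erss: np.ndarray,
    eqll_sum: float,
    logm_sum: float,
) -> float:
    lik = (
        -0.5 * ss.n * ss.r * _LOG2PI
        - 0.5 * ss.n * wp.logdetV
        - 0.5 * _trace_vinv(wp.Linv, erss)
    )
    return lik - eqll_sum + logm_sum


def _floor_pd(V: np.ndarray) -> np.ndarray:
    """Symmetrize and floor eigenvalues so V stays positive definite."""
    V = (V + V.T) / 2.0
    w, Q = np.linalg.eigh(V)
    if w.min() < V_EIG_FLOOR:
        V = (Q * np.clip(w, V_EIG_FLOOR, None)) @ Q.T
        V = (V + V.T) / 2.0
    return V


def posterior_per_variant(
    b_hat: np.ndarray,
    d_j: float,
    V: np.ndarray,
    prior: MixturePrior,
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray], np.ndarray, np.ndarray]:
    """Reference per-variant conjugate update (direct matrix algebra).

    For b̂_j ~ N(b_j, V/d_j) with the mixture prior, returns
    (γ_j, [μ1_k], [Σ1_k], b̄_j, M2_j).  The S0_k (S0_k + V/d_j)⁻¹ factorization
    never inverts S0_k, so rank-deficient components are handled exactly.
    Mainly used as an independent cross-check of the whitened fast path.
    """
    b_hat = np.asarray(b_hat, dtype=float)
    r = b_hat.shape[0]
    if d_j <= 0:
        raise ValueError("d_j must be positive")
    V = np.asarray(V, dtype=float)
    S = V / d_j
    mu1: list[np.ndarray] = []
    Sigma1: list[np.ndarray] = []
    logliks = np.empty(prior.K)
    for k in range(prior.K):
        C = prior.S0[k] + S
        try:
            Lc = cholesky(C, lower=True)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                f"singular S0_k + V/d for component {k} ({prior.labels[k]})"
            ) from e
        # C^{-1} b̂ and C^{-1} S via triangular solves
        cib = solve_triangular(
            Lc.T, solve_triangular(Lc, b_hat, lower=True), lower=False
        )
        ciS = solve_triangular(Lc.T, solve_triangular(Lc, S, lower=True), lower=False)
        mu = prior.S0[k] @ cib
        Sg = prior.S0[k] @ ciS
        Sg = (Sg + Sg.T) / 2.0
        mu1.append(mu)
        Sigma1.append(Sg)
        logdet = 2.0 * float(np.sum(np.log(np.diag(Lc))))
        logliks[k] = -0.5 * r * _LOG2PI - 0.5 * logdet - 0.5 * float(b_hat @ cib)
    logpost = _safe_log(prior.w0) + logliks
    logm = float(logsumexp(logpost))
    gamma = np.exp(logpost - logm)
    b_bar = np.einsum("k,ki->i", gamma, np.stack(mu1))
    M2 = np.zeros((r, r))
    for k in range(prior.K):
        M2 += gamma[k] * (Sigma1[k] + np.outer(mu1[k], mu1[k]))
    return gamma, mu1, Sigma1, b_bar, M2


def update_w0(gamma: np.ndarray) -> np.ndarray:
    """M-step for the mixture weights: average responsibilities."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 2:
        raise ValueError("gamma must be p x K")
    w0 = gamma.mean(axis=0)
    return w0 / w0.sum()


def update_V(
    ss: SufficientStats,
    B_bar: np.ndarray,
    d_cov_sum: np.ndarray,
) -> np.ndarray:
    """M-step for the residual covariance: V = E_q[(Y−XB)ᵀ(Y−XB)] / n.

    ``d_cov_sum`` is Σ_j d_j (M2_j − b̄_j b̄_jᵀ).  Output is symmetrized with
    eigenvalues floored at 1e-8.
    """
    if ss.YtY is None:
        raise ValueError("updating V requires YtY; run with V fixed instead")
    B_bar = np.asarray(B_bar, dtype=float)
    erss = (
        ss.YtY
        - ss.XtY.T @ B_bar
        - B_bar.T @ ss.XtY
        + B_bar.T @ ss.XtX @ B_bar
        + np.asarray(d_cov_sum, dtype=float)
    )
    return _floor_pd(erss / ss.n)


def compute_elbo(
    ss: SufficientStats,
    bhat: np.ndarray,
    prior: MixturePrior,
    V: np.ndarray,
) -> float:
    """Evidence lower bound at a variational state.

    The state is fully determined by the per-variant residualized estimates
    ``bhat`` (each q_j is the exact conjugate posterior at bhat[j]), the
    mixture weights in ``prior`` and the residual covariance ``V``; the ELBO
    is a function of that state only, independent of the update path that
    produced it.  Without YᵀY the result omits the additive constant
    −½ tr(V⁻¹YᵀY).
    """
    bhat = np.asarray(bhat, dtype=float)
    p, r = bhat.shape
    if p != ss.p or r != ss.r:
        raise ValueError("bhat shape must match the sufficient statistics")
    wp = _WhitenedPrior(prior, np.asarray(V, dtype=float))
    logw0 = _safe_log(prior.w0)
    d = ss.d
    B_bar = np.empty((p, r))
    d_cov_sum = np.zeros((r, r))
    logm_sum = 0.0
    eqll_sum = 0.0
    for j in range(p):
        bt = wp.Linv @ bhat[j]
        _, btbar, M2t, logm, eqll = _variant_update(bt, d[j], wp, logw0)
        b = wp.L @ btbar
        B_bar[j] = b
        d_cov_sum += d[j] * (wp.L @ M2t @ wp.L.T - np.outer(b, b))
        logm_sum += logm
        eqll_sum += eqll
    erss = -ss.XtY.T @ B_bar - B_bar.T @ ss.XtY + B_bar.T @ ss.XtX @ B_bar + d_cov_sum
    if ss.YtY is not None:
        erss = erss + ss.YtY
    erss = (erss + erss.T) / 2.0
    elbo = _assemble_elbo(ss, wp, erss, eqll_sum, logm_sum)
    if not np.isfinite(elbo):
        raise FloatingPointError("non-finite ELBO")
    return elbo
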