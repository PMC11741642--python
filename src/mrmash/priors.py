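"""Mixture-of-multivariate-normals prior on cross-phenotype effects.

Effects b_j (one r-vector per variant) are modeled a priori as

    b_j ~ sum_k w0_k N_r(0, S0_k)

where the S0_k encode candidate patterns of effect sharing across phenotypes:
"canonical" patterns (no sharing, effect in a single phenotype, equal effects,
correlated shared effects) and "data-driven" patterns estimated from strong
signals.  Each base pattern is crossed with a grid of scales, and a point-mass
null (S0 = 0) is always component 0.  The weights w0 are later adapted to the
data by empirical Bayes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MixturePrior",
    "CovSpec",
    "canonical_covs",
    "scale_expand",
    "data_driven_covs",
    "auto_scale_grid",
    "build_prior",
]

PSD_TOL = 1e-10
DEDUP_TOL = 1e-12


def _check_psd(S: np.ndarray, name: str) -> None:
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh((S + S.T) / 2.0)
    if w.min(initial=0.0) < -PSD_TOL:
        raise ValueError(f"{name} is not PSD (min eigenvalue {w.min():.3e})")


def _psd_project(S: np.ndarray) -> np.ndarray:
    S = (S + S.T) / 2.0
    w, Q = np.linalg.eigh(S)
    return (Q * np.clip(w, 0.0, None)) @ Q.T


@dataclass
class MixturePrior:
    """K mixture weights on the simplex and K r×r PSD covariance components.

    By convention the point-mass null component (zero matrix) sits at index 0.
    """

    w0: np.ndarray
    S0: np.ndarray  # (K, r, r)
    labels: list[str]

    def __post_init__(self) -> None:
        self.w0 = np.asarray(self.w0, dtype=float)
        self.S0 = np.asarray(self.S0, dtype=float)
        if self.S0.ndim != 3 or self.S0.shape[1] != self.S0.shape[2]:
            raise ValueError("S0 must be a (K, r, r) array")
        K = self.S0.shape[0]
        if self.w0.shape != (K,):
            raise ValueError("w0 length must match the number of components")
        if np.any(self.w0 < 0) or abs(self.w0.sum() - 1.0) > 1e-12:
            raise ValueError("w0 must be nonnegative and sum to 1 (within 1e-12)")
        if len(self.labels) != K:
            raise ValueError("labels length must match the number of components")
        self.labels = [str(l) for l in self.labels]
        for k in range(K):
            _check_psd(self.S0[k], f"S0[{k}] ({self.labels[k]})")
        zero = [k for k in range(K) if np.all(self.S0[k] == 0)]
        if len(zero) > 1:
            raise ValueError("at most one null (zero) component is allowed")
        if zero and zero[0] != 0:
            raise ValueError("the null component must be component 0")

    @property
    def K(self) -> int:
        return self.S0.shape[0]

    @property
    def r(self) -> int:
        return self.S0.shape[1]

    @property
    def null_index(self) -> int:
        if not np.all(self.S0[0] == 0):
            raise ValueError("prior has no null component")
        return 0

    def with_weights(self, w0: np.ndarray) -> "MixturePrior":
        return MixturePrior(w0=np.asarray(w0, dtype=float), S0=self.S0.copy(),
                            labels=list(self.labels))


@dataclass
class CovSpec:
    """Which canonical covariance families and scales to include."""

    canonical_families: tuple[str, ...] = (
        "identity", "singletons", "shared_equal", "shared_het",
    )
    rho_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    scale_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-4, 0, 20)
    )
    data_driven: Optional[list[np.ndarray]] = None

    def __post_init__(self) -> None:
        self.scale_grid = np.asarray(self.scale_grid, dtype=float)
        if self.scale_grid.size == 0:
            raise ValueError("scale_grid must be non-empty")
        if np.any(self.scale_grid <= 0):
            raise ValueError("scale_grid must be strictly positive")
        if np.any(np.diff(self.scale_grid) <= 0):
            raise ValueError("scale_grid must be strictly increasing")


def _dedupe(
    covs: list[np.ndarray], labels: list[str], tol: float = DEDUP_TOL
) -> tuple[list[np.ndarray], list[str]]:
    out_c: list[np.ndarray] = []
    out_l: list[str] = []
    for C, lab in zip(covs, labels):
        if any(np.allclose(C, D, atol=tol, rtol=0.0) for D in out_c):
            continue
        out_c.append(C)
        out_l.append(lab)
    return out_c, out_l


def canonical_covs(
    r: int, spec: Optional[CovSpec] = None
) -> tuple[list[np.ndarray], list[str]]:
    """Unscaled canonical effect-sharing patterns for r phenotypes.

    identity (independent effects), one singleton per phenotype (effect in
    that phenotype only), shared_equal (identical effect in all phenotypes)
    and shared_het (unit diagonal, constant off-diagonal rho from the grid).
    Duplicates are removed (at r = 1 everything collapses to [[1]]).
    """
    if r < 1:
        raise ValueError("r must be at least 1")
    spec = spec or CovSpec()
    covs: list[np.ndarray] = []
    labels: list[str] = []
    fams = spec.canonical_families
    if "identity" in fams:
        covs.append(np.eye(r))
        labels.append("identity")
    if "singletons" in fams:
        for t in range(r):
            C = np.zeros((r, r))
            C[t, t] = 1.0
            covs.append(C)
            labels.append(f"singleton_{t + 1}")
    if "shared_equal" in fams:
        covs.append(np.ones((r, r)))
        labels.append("shared_equal")
    if "shared_het" in fams and r > 1:
        for rho in spec.rho_grid:
            C = np.full((r, r), float(rho))
            np.fill_diagonal(C, 1.0)
            covs.append(C)
            labels.append(f"shared_het_{rho:g}")
    covs, labels = _dedupe(covs, labels)
    for C, lab in zip(covs, labels):
        _check_psd(C, lab)
    return covs, labels


def scale_expand(
    covs: Sequence[np.ndarray],
    scale_grid: np.ndarray,
    labels: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, list[str]]:
    """Cross base covariances with a scale grid and prepend the null.

    Returns a (K, r, r) stack with K = 1 + |covs|·|grid| before
    deduplication; component 0 is the zero matrix.
    """
    scale_grid = np.asarray(scale_grid, dtype=float)
    if scale_grid.size == 0:
        raise ValueError("scale_grid must be non-empty")
    if np.any(scale_grid <= 0):
        raise ValueError("scale_grid must be strictly positive")
    covs = [np.asarray(C, dtype=float) for C in covs]
    if not covs:
        raise ValueError("need at least one base covariance")
    r = covs[0].shape[0]
    if labels is None:
        labels = [f"cov_{i + 1}" for i in range(len(covs))]
    out = [np.zeros((r, r))]
    out_labels = ["null"]
    for C, lab in zip(covs, labels):
        for s in scale_grid:
            out.append(s * C)
            out_labels.append(f"{lab}@{s:g}")
    out_c, out_l = _dedupe(out, out_labels)
    return np.stack(out_c), out_l


def data_driven_covs(
    Z: np.ndarray,
    n_components: int = 3,
    ed_iters: int = 50,
) -> list[np.ndarray]:
    """Covariance candidates estimated from strong-signal Z-scores.

    With Z_j ~ N(0, U + I) for the m selected strong signals, candidates are
    (a) rank-1 matrices from the top principal components of ZᵀZ/m − I
    (eigenvalues clipped at zero) and (b) those candidates refined by
    ``ed_iters`` extreme-deconvolution EM iterations, PSD-projected at each
    step. Callers select the strong signals upstream (LD pruning plus a |z|
    threshold).
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValueError("Z must be 2-D (signals x phenotypes)")
    m, r = Z.shape
    if m < r:
        raise ValueError(
            f"need at least r={r} strong signals, got {m}; "
            "consider a canonical-only prior"
        )
    emp = Z.T @ Z / m
    excess = emp - np.eye(r)
    w, Q = np.linalg.eigh(excess)
    order = np.argsort(w)[::-1][: max(1, min(n_components, r))]
    pca: list[np.ndarray] = []
    for i in order:
        lam = max(float(w[i]), 0.0)
        pca.append(lam * np.outer(Q[:, i], Q[:, i]))
    if ed_iters <= 0:
        return pca

    refined = [_ed_refine(U, emp, ed_iters) for U in pca]
    out: list[np.ndarray] = []
    for C in pca + refined:
        if not any(np.allclose(C, D, atol=1e-10) for D in out):
            out.append(C)
    return out


def _ed_refine(U: np.ndarray, emp: np.ndarray, iters: int) -> np.ndarray:
    """EM for U in z ~ N(0, U + I), given the empirical second moment of z."""
    r = U.shape[0]
    U = _psd_project(U)
    eye = np.eye(r)
    for _ in range(iters):
        if np.all(U == 0):
            break
        A = np.linalg.solve((U + eye).T, U.T).T  # U (U + I)^{-1}
        post_cov = A  # U - U (U+I)^{-1} U = U (U+I)^{-1} with unit error cov
        U = _psd_project(post_cov + A @ emp @ A.T)
    return U


def auto_scale_grid(
    betahat: np.ndarray, se: np.ndarray, mult: float = np.sqrt(2.0)
) -> np.ndarray:
    """Data-adaptive variance grid spanning the plausible effect scales.

    Geometric grid of prior standard deviations from min(se)/10 up to
    2·max|betahat| with ratio ``mult``, returned as variances. Mirrors the
    usual adaptive-shrinkage grid construction.
    """
    betahat = np.asarray(betahat, dtype=float)
    se = np.asarray(se, dtype=float)
    lo = float(np.min(se)) / 10.0
    hi = 2.0 * float(np.max(np.abs(betahat)))
    if not np.isfinite(lo) or lo <= 0:
        lo = 1e-4
    if not np.isfinite(hi) or hi <= lo:
        hi = lo * mult ** 10
    n = int(np.ceil(np.log(hi / lo) / np.log(mult))) + 1
    sd = lo * mult ** np.arange(n)
    return sd**2


def build_prior(
    r: int,
    spec: Optional[CovSpec] = None,
    w0: Optional[np.ndarray] = None,
) -> MixturePrior:
    """Canonical (plus optional data-driven) components crossed with the scale
    grid, null prepended, uniform weights unless given."""
    spec = spec or CovSpec()
    covs, labels = canonical_covs(r, spec)
    if spec.data_driven:
        for i, C in enumerate(spec.data_driven):
            C = np.asarray(C, dtype=float)
            if C.shape != (r, r):
                raise ValueError("data-driven covariances must be r x r")
            covs.append(C)
            labels.append(f"data_driven_{i + 1}")
        covs, labels = _dedupe(covs, labels)
    S0, all_labels = scale_expand(covs, spec.scale_grid, labels)
    K = S0.shape[0]
    if w0 is None:
        w0 = np.full(K, 1.0 / K)
    return MixturePrior(w0=w0, S0=S0, labels=all_labels)
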