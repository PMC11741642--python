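"""Summary-statistic data model and sufficient-statistic recovery.

The fitting engine consumes only the cross-product matrices (XᵀX, XᵀY, YᵀY)
of the underlying multivariate regression, together with the sample size n.
These can be computed directly from individual-level genotypes/phenotypes, or
recovered from per-variant simple-regression summary statistics (effect size,
standard error, sample size) and an LD correlation matrix.  XᵀY is recovered
exactly; XᵀX is exact only when the LD matrix comes from the same individuals
as the summary statistics, and is an approximation when it comes from a
reference panel.

The recovery algebra assumes the GWAS convention used throughout this
package: phenotypes variance-standardized (yᵀy = n − 1 after centering) and
genotypes centered but not scaled.  For a simple regression of y on x_j with
intercept,

    betahat_j = xⱼᵀy / xⱼᵀxⱼ,   se_j² = (yᵀy − betahat_j² xⱼᵀxⱼ) / ((n−2) xⱼᵀxⱼ)

which inverts to

    xⱼᵀxⱼ = yᵀy / (se_j² (n−2) + betahat_j²),   xⱼᵀy = betahat_j xⱼᵀxⱼ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GWASSummary",
    "LDMatrix",
    "SufficientStats",
    "suffstats_from_individual",
    "recover_suffstats",
    "apply_ld_structure",
    "block_bounds_by_span",
    "qc_consistency",
]


def _as_float_matrix(a, name: str) -> np.ndarray:
    out = np.asarray(a, dtype=float)
    if out.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got ndim={out.ndim}")
    return out


@dataclass
class GWASSummary:
    """Per-variant, per-phenotype marginal effect sizes and standard errors.

    ``n`` may be a single GWAS sample size or a per-phenotype vector (the
    latter arises when phenotypes have different complete-case counts, which
    violates the engine's complete-overlap assumption but is supported so the
    robustness scenarios can be expressed).
    """

    betahat: np.ndarray
    se: np.ndarray
    n: int | np.ndarray
    variant_ids: list[str]
    phenotype_ids: list[str]

    def __post_init__(self) -> None:
        self.betahat = _as_float_matrix(self.betahat, "betahat")
        self.se = _as_float_matrix(self.se, "se")
        if self.betahat.shape != self.se.shape:
            raise ValueError(
                f"betahat {self.betahat.shape} and se {self.se.shape} differ in shape"
            )
        if not np.all(np.isfinite(self.betahat)):
            raise ValueError("betahat contains non-finite values")
        if not (np.all(np.isfinite(self.se)) and np.all(self.se > 0)):
            raise ValueError("se must be finite and strictly positive")
        self.variant_ids = [str(v) for v in self.variant_ids]
        self.phenotype_ids = [str(v) for v in self.phenotype_ids]
        if len(self.variant_ids) != self.p:
            raise ValueError("variant_ids length does not match betahat rows")
        if len(self.phenotype_ids) != self.r:
            raise ValueError("phenotype_ids length does not match betahat columns")
        if len(set(self.variant_ids)) != self.p:
            raise ValueError("variant_ids are not unique")
        if len(set(self.phenotype_ids)) != self.r:
            raise ValueError("phenotype_ids are not unique")
        npp = self.n_per_phenotype
        if np.any(npp < 3):
            raise ValueError("sample size must be at least 3 for every phenotype")

    @property
    def p(self) -> int:
        return self.betahat.shape[0]

    @property
    def r(self) -> int:
        return self.betahat.shape[1]

    @property
    def n_per_phenotype(self) -> np.ndarray:
        """Sample size as an (r,) integer array (broadcast if scalar)."""
        n = np.asarray(self.n)
        if n.ndim == 0:
            return np.full(self.r, int(n))
        if n.shape != (self.r,):
            raise ValueError(f"n must be scalar or shape ({self.r},)")
        return n.astype(int)

    @property
    def z(self) -> np.ndarray:
        """Z-scores betahat / se."""
        return self.betahat / self.se


@dataclass
class LDMatrix:
    """Variant-by-variant correlation matrix with genetic-map metadata.

    ``structure`` records how the matrix was sparsified: ``"dense"``,
    ``"banded"`` (entries more than ``window_cm`` centimorgans apart, or on
    different chromosomes, are zero) or ``"block_diagonal"`` (``blocks`` is a
    list of half-open index ranges partitioning the variants).
    """

    R: np.ndarray
    positions_cm: np.ndarray
    chrom: np.ndarray
    structure: str = "dense"
    window_cm: Optional[float] = None
    blocks: Optional[list[tuple[int, int]]] = None

    def __post_init__(self) -> None:
        self.R = _as_float_matrix(self.R, "R")
        p = self.R.shape[0]
        if self.R.shape != (p, p):
            raise ValueError("R must be square")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("R must be symmetric")
        if np.any(np.abs(self.R) > 1 + 1e-8):
            raise ValueError("correlations must lie in [-1, 1]")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-8):
            raise ValueError("R must have unit diagonal")
        self.R = (self.R + self.R.T) / 2.0
        np.fill_diagonal(self.R, 1.0)
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        self.chrom = np.asarray(self.chrom).astype(str)
        if self.positions_cm.shape != (p,) or self.chrom.shape != (p,):
            raise ValueError("positions_cm and chrom must have length p")
        _check_positions_sorted(self.positions_cm, self.chrom)
        if self.structure not in ("dense", "banded", "block_diagonal"):
            raise ValueError(f"unknown LD structure {self.structure!r}")
        if self.structure == "banded" and self.window_cm is None:
            raise ValueError("banded structure requires window_cm")
        if self.structure == "block_diagonal":
            if not self.blocks:
                raise ValueError("block_diagonal structure requires blocks")
            self.blocks = [(int(a), int(b)) for a, b in self.blocks]
            _check_blocks(self.blocks, p)

    @property
    def p(self) -> int:
        return self.R.shape[0]


def _check_positions_sorted(positions_cm: np.ndarray, chrom: np.ndarray) -> None:
    for c in pd.unique(chrom):
        pos = positions_cm[chrom == c]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions_cm decreasing within chromosome {c}")


def _check_blocks(blocks: Sequence[tuple[int, int]], p: int) -> None:
    cursor = 0
    for a, b in blocks:
        if a != cursor or b <= a:
            raise ValueError("blocks must be contiguous half-open ranges covering 0..p")
        cursor = b
    if cursor != p:
        raise ValueError(f"blocks cover 0..{cursor}, expected 0..{p}")


@dataclass
class SufficientStats:
    """The triple (XᵀX, XᵀY, YᵀY) with sample size n.

    ``xtx_approximate`` is True when XᵀX was rebuilt from reference-panel LD
    rather than the genotypes that produced the summary statistics.
    """

    XtX: np.ndarray
    XtY: np.ndarray
    n: int
    YtY: Optional[np.ndarray] = None
    xtx_approximate: bool = False
    variant_ids: Optional[list[str]] = None
    phenotype_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.XtX = _as_float_matrix(self.XtX, "XtX")
        self.XtY = _as_float_matrix(self.XtY, "XtY")
        p = self.XtX.shape[0]
        if self.XtX.shape != (p, p):
            raise ValueError("XtX must be square")
        if self.XtY.shape[0] != p:
            raise ValueError("XtY rows must match XtX")
        if not np.allclose(self.XtX, self.XtX.T, atol=1e-8):
            raise ValueError("XtX must be symmetric")
        self.XtX = (self.XtX + self.XtX.T) / 2.0
        if np.any(np.diag(self.XtX) <= 0):
            bad = np.flatnonzero(np.diag(self.XtX) <= 0)
            raise ValueError(f"XtX has non-positive diagonal at indices {bad.tolist()}")
        self.n = int(self.n)
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.YtY is not None:
            self.YtY = _as_float_matrix(self.YtY, "YtY")
            if self.YtY.shape != (self.r, self.r):
                raise ValueError("YtY must be r x r")
            if not np.allclose(self.YtY, self.YtY.T, atol=1e-8):
                raise ValueError("YtY must be symmetric")
            if np.any(np.diag(self.YtY) <= 0):
                raise ValueError("YtY must have positive diagonal")
            self.YtY = (self.YtY + self.YtY.T) / 2.0

    @property
    def p(self) -> int:
        return self.XtX.shape[0]

    @property
    def r(self) -> int:
        return self.XtY.shape[1]

    @property
    def d(self) -> np.ndarray:
        """Per-variant diagonal d_j = (XᵀX)_jj."""
        return np.diag(self.XtX)


def suffstats_from_individual(
    X: np.ndarray,
    Y: np.ndarray,
    center: bool = True,
    standardize: bool = False,
) -> SufficientStats:
    """Cross-products from individual-level data (the oracle path).

    ``center`` subtracts column means from both X and Y (the with-intercept
    convention); ``standardize`` additionally scales X columns to unit sample
    variance. YᵀY is always available on this path.
    """
    X = _as_float_matrix(X, "X")
    Y = _as_float_matrix(Y, "Y")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n = X.shape[0]
    if n <= 1:
        raise ValueError("need more than one individual")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(Y)):
        raise ValueError(
            "missing values are not supported here; compute summary statistics "
            "on complete cases (e.g. via the simulator's MCAR pathway) instead"
        )
    if center:
        X = X - X.mean(axis=0)
        Y = Y - Y.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0)
            raise ValueError(f"zero-variance genotype column(s) {bad.tolist()}")
        X = X / sd
    XtX = X.T @ X
    if np.any(np.diag(XtX) <= 0):
        bad = np.flatnonzero(np.diag(XtX) <= 0)
        raise ValueError(f"zero-variance genotype column(s) {bad.tolist()}")
    return SufficientStats(
        XtX=XtX, XtY=X.T @ Y, YtY=Y.T @ Y, n=n, xtx_approximate=False
    )


def recover_suffstats(
    gwas: GWASSummary,
    ld: LDMatrix,
    yty_mode: str = "standardized",
    YtY: Optional[np.ndarray] = None,
    pheno_cor: Optional[np.ndarray] = None,
    ld_is_insample: bool = False,
) -> SufficientStats:
    """Rebuild (XᵀX, XᵀY, YᵀY) from summary statistics and LD.

    Per variant j and phenotype t the simple-regression identities give
    d_jt = yty_t / (se_jt² (n_t − 2) + betahat_jt²) with yty_t = n_t − 1 under
    the variance-standardized phenotype convention (``yty_mode="standardized"``)
    or the diagonal of a supplied YᵀY (``yty_mode="supplied"``).  Under
    complete sample overlap d_jt is constant across phenotypes up to noise;
    it is collapsed to a single d_j by the median over t (dispersion is
    reported by :func:`qc_consistency`).  Then XᵀY[j] = betahat_j · d_j and
    XᵀX = D^{1/2} R D^{1/2}.

    ``yty_mode="absent"`` uses the standardized convention for the d_j
    recovery but does not emit YᵀY, so the engine must run with V fixed.
    Under ``"standardized"`` the off-diagonal of the emitted YᵀY is taken
    from ``pheno_cor`` (phenotype correlation matrix) when given; when not
    given it is estimated from the cross-phenotype correlation of z-scores
    over variants, which under complete sample overlap approximates the
    phenotypic correlation (mostly-null variants dominate). Assuming zero
    off-diagonals instead makes the residual-covariance M-step badly
    misspecified for correlated phenotypes.
    """
    if yty_mode not in ("standardized", "supplied", "absent"):
        raise ValueError(f"unknown yty_mode {yty_mode!r}")
    if gwas.p != ld.p:
        raise ValueError(f"gwas has {gwas.p} variants but ld has {ld.p}")
    n_t = gwas.n_per_phenotype.astype(float)
    if yty_mode == "supplied":
        if YtY is None:
            raise ValueError("yty_mode='supplied' requires YtY")
        YtY = _as_float_matrix(YtY, "YtY")
        yty_diag = np.diag(YtY)
    else:
        yty_diag = n_t - 1.0

    denom = gwas.se**2 * (n_t - 2.0) + gwas.betahat**2
    d_jt = yty_diag / denom  # (p, r)
    if not np.all(np.isfinite(d_jt)) or np.any(d_jt <= 0):
        bad = np.flatnonzero(~np.all(np.isfinite(d_jt) & (d_jt > 0), axis=1))
        names = [gwas.variant_ids[j] for j in bad[:10]]
        raise ValueError(
            f"non-finite or non-positive recovered d for variant(s) {names}"
        )
    d = np.median(d_jt, axis=1)
    XtY = gwas.betahat * d[:, None]
    sqd = np.sqrt(d)
    XtX = ld.R * np.outer(sqd, sqd)

    n = int(round(float(np.median(n_t))))
    out_yty: Optional[np.ndarray] = None
    if yty_mode == "supplied":
        out_yty = YtY
    elif yty_mode == "standardized":
        if pheno_cor is None:
            pheno_cor = _null_z_correlation(gwas.z)
        else:
            pheno_cor = _as_float_matrix(pheno_cor, "pheno_cor")
        out_yty = np.sqrt(np.outer(yty_diag, yty_diag)) * pheno_cor
    return SufficientStats(
        XtX=XtX,
        XtY=XtY,
        YtY=out_yty,
        n=n,
        xtx_approximate=not ld_is_insample,
        variant_ids=list(gwas.variant_ids),
        phenotype_ids=list(gwas.phenotype_ids),
    )


def _null_z_correlation(z: np.ndarray, z_max: float = 2.0) -> np.ndarray:
    """Phenotype correlation estimated from z-scores of null-ish variants.

    Under complete sample overlap, z-scores of variants without signal are
    correlated across phenotypes exactly as the phenotypes are; restricting
    to rows with max |z| below ``z_max`` keeps shared genetic signal from
    inflating the estimate. Falls back to the identity when too few
    null-ish variants exist.
    """
    z = np.asarray(z, dtype=float)
    r = z.shape[1]
    if r == 1:
        return np.eye(1)
    keep = np.max(np.abs(z), axis=1) < z_max
    if keep.sum() < max(10, r + 1):
        return np.eye(r)
    C = np.corrcoef(z[keep], rowvar=False)
    return (C + C.T) / 2.0


def apply_ld_structure(
    R: np.ndarray,
    positions_cm: np.ndarray,
    chrom: np.ndarray,
    structure: str = "banded",
    window_cm: Optional[float] = None,
    blocks: Optional[list[tuple[int, int]]] = None,
) -> LDMatrix:
    """Sparsify a dense correlation matrix into banded or block-diagonal form.

    Banding zeroes entries strictly more than ``window_cm`` centimorgans
    apart (entries exactly at the window are retained) and all cross-
    chromosome entries.  Blocks are half-open index ranges; cross-block
    entries are zeroed.  Idempotent for a fixed structure.
    """
    R = _as_float_matrix(R, "R").copy()
    positions_cm = np.asarray(positions_cm, dtype=float)
    chrom = np.asarray(chrom).astype(str)
    _check_positions_sorted(positions_cm, chrom)
    if structure == "dense":
        return LDMatrix(R=R, positions_cm=positions_cm, chrom=chrom, structure="dense")
    if structure == "banded":
        if window_cm is None:
            raise ValueError("banded structure requires window_cm")
        dist = np.abs(positions_cm[:, None] - positions_cm[None, :])
        same_chrom = chrom[:, None] == chrom[None, :]
        keep = (dist <= window_cm) & same_chrom
        R = np.where(keep, R, 0.0)
        np.fill_diagonal(R, 1.0)
        return LDMatrix(
            R=R, positions_cm=positions_cm, chrom=chrom,
            structure="banded", window_cm=float(window_cm),
        )
    if structure == "block_diagonal":
        if not blocks:
            raise ValueError("block_diagonal structure requires blocks")
        _check_blocks(blocks, R.shape[0])
        mask = np.zeros_like(R, dtype=bool)
        for a, b in blocks:
            mask[a:b, a:b] = True
        R = np.where(mask, R, 0.0)
        np.fill_diagonal(R, 1.0)
        return LDMatrix(
            R=R, positions_cm=positions_cm, chrom=chrom,
            structure="block_diagonal", blocks=list(blocks),
        )
    raise ValueError(f"unknown structure {structure!r}")


def block_bounds_by_span(
    positions_cm: np.ndarray, chrom: np.ndarray, span_cm: float
) -> list[tuple[int, int]]:
    """Cut variants into contiguous blocks of at most ``span_cm`` centimorgans.

    A new block starts at every chromosome change and whenever the distance
    from the block's first variant exceeds ``span_cm``.
    """
    positions_cm = np.asarray(positions_cm, dtype=float)
    chrom = np.asarray(chrom).astype(str)
    p = len(positions_cm)
    if p == 0:
        return []
    bounds = []
    start = 0
    for j in range(1, p):
        if chrom[j] != chrom[start] or positions_cm[j] - positions_cm[start] > span_cm:
            bounds.append((start, j))
            start = j
    bounds.append((start, p))
    return bounds


def qc_consistency(
    gwas: GWASSummary,
    ld: LDMatrix,
    d_rtol: float = 0.1,
    z_dev_threshold: float = 4.0,
    ld_neighbor_min: float = 0.8,
) -> pd.DataFrame:
    """Consistency checks on summary statistics against each other and LD.

    Two reporting-only checks (inputs are never mutated):

    - ``d_dispersion``: under complete sample overlap the recovered per-
      phenotype d_jt agree up to noise; relative spread beyond ``d_rtol``
      is a symptom of sample non-overlap or allele mismatch.
    - ``z_ld_outlier``: a variant in strong LD (|r| >= ``ld_neighbor_min``)
      with a neighbor should have a z-score near r·z_neighbor; a deviation
      beyond ``z_dev_threshold`` flags a likely strand/sign error.

    Returns a flag table with columns (variant_id, check, phenotype_id, value);
    an empty frame means no flags. Thresholds are implementer defaults and
    both checks are disabled by setting their threshold to ``inf``.
    """
    if gwas.p != ld.p:
        raise ValueError("gwas and ld must cover the same variants")
    rows: list[dict] = []

    n_t = gwas.n_per_phenotype.astype(float)
    yty = n_t - 1.0
    d_jt = yty / (gwas.se**2 * (n_t - 2.0) + gwas.betahat**2)
    if gwas.r > 1 and np.isfinite(d_rtol):
        med = np.median(d_jt, axis=1)
        spread = (d_jt.max(axis=1) - d_jt.min(axis=1)) / med
        for j in np.flatnonzero(spread > d_rtol):
            rows.append(
                {"variant_id": gwas.variant_ids[j], "check": "d_dispersion",
                 "phenotype_id": "", "value": float(spread[j])}
            )

    if np.isfinite(z_dev_threshold) and gwas.p > 1:
        z = gwas.z
        absR = np.abs(ld.R - np.eye(ld.p))
        nbr = np.argmax(absR, axis=1)
        for j in range(gwas.p):
            m = nbr[j]
            r_jm = ld.R[j, m]
            if abs(r_jm) < ld_neighbor_min:
                continue
            dev = np.abs(z[j] - r_jm * z[m])
            for t in np.flatnonzero(dev > z_dev_threshold):
                rows.append(
                    {"variant_id": gwas.variant_ids[j], "check": "z_ld_outlier",
                     "phenotype_id": gwas.phenotype_ids[t], "value": float(dev[t])}
                )

    return pd.DataFrame(rows, columns=["variant_id", "check", "phenotype_id", "value"])
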