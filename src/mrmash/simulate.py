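"""Scenario simulator: LD-structured genotypes, sparse multi-phenotype
effects, GWAS scans, and LD computation.

The generator reproduces, at desk scale, the statistical structure of a
biobank simulation study: correlated 0/1/2 genotype dosages with a genetic-
map coordinate, r = 5 phenotypes with sparse causal effects drawn under six
effect-sharing scenarios, per-phenotype target genomic heritabilities
enforced in-sample, quantile-normalized per-variant simple-regression GWAS
scans, and MCAR phenotype missingness for the robustness settings.

Genotypes come from thresholded AR(1) Gaussians (two latent haplotypes per
individual, each dichotomized at the MAF quantile and summed), which gives
tunable local LD with a known latent correlation — fast and desk-scale,
standing in for real array genotypes which cannot ship with a package.

Default scenario sizes are scaled down from the study design (105,000
individuals / 595,071 variants / 5,000 causal) to n_train = 2,000,
p = 2,000, 50 causal variants, preserving the causal fraction's order of
magnitude; heritabilities and phenotype counts are kept as specified per
scenario. All sizes are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import lfilter
from scipy.stats import norm, rankdata

from .sumstats import GWASSummary, LDMatrix, apply_ld_structure, block_bounds_by_span

__all__ = [
    "ScenarioConfig",
    "SimOutput",
    "SCENARIOS",
    "scenario_config",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_phenotypes",
    "simulate_scenario",
    "quantile_normalize",
    "gwas_scan",
    "mcar_mask",
    "compute_ld",
]

SCENARIOS = (
    "equal_effects",
    "mostly_null",
    "shared_subgroups",
    "low_h2",
    "high_polygenicity",
    "more_phenotypes",
    "external_ld",
    "mcar_missingness",
)


@dataclass
class ScenarioConfig:
    """Parameters of one simulation scenario.

    ``h2`` is the per-phenotype target genomic heritability, enforced exactly
    in-sample on the training genotypes. ``rho_share`` is the within-group
    effect correlation of the shared-subgroups scenario (shared but unequal
    effects). ``residual_cor`` is the residual correlation across phenotypes
    (identity when None).
    """

    scenario: str = "equal_effects"
    n_train: int = 2000
    n_test: int = 1000
    p: int = 2000
    n_causal: int = 50
    r: int = 5
    h2: Optional[np.ndarray] = None
    residual_cor: Optional[np.ndarray] = None
    rho_share: float = 0.8
    ld_decay: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    map_density_cm: float = 0.05
    missing_frac: float = 0.0
    external_ld: bool = False
    n_ref: int = 503
    ld_decay_ref: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_causal > self.p:
            raise ValueError("n_causal cannot exceed p")
        if self.h2 is not None:
            self.h2 = np.asarray(self.h2, dtype=float)
            if self.h2.shape != (self.r,):
                raise ValueError("h2 must have one entry per phenotype")
            if np.any((self.h2 < 0) | (self.h2 > 1)):
                raise ValueError("h2 entries must lie in [0, 1]")
        if not (0 <= self.missing_frac <= 1):
            raise ValueError("missing_frac must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")


def scenario_config(name: str, **overrides) -> ScenarioConfig:
    """Preset configuration for a named scenario.

    Scenario targets: equal_effects h² = 0.5 everywhere; mostly_null h² = 0.5
    for phenotype 1 and 0 elsewhere; shared_subgroups h² = 0.3 for phenotypes
    1–3 and 0.5 for 4–5; low_h2 is equal effects at h² = 0.2;
    high_polygenicity is equal effects with the causal fraction raised
    tenfold; more_phenotypes is equal effects with r = 10.  external_ld and
    mcar_missingness reuse equal effects and flip the corresponding
    robustness switch.
    """
    base = dict(scenario=name)
    r = int(overrides.get("r", 10 if name == "more_phenotypes" else 5))
    p = int(overrides.get("p", 2000))
    if name in ("equal_effects", "more_phenotypes", "external_ld", "mcar_missingness"):
        base["h2"] = np.full(r, 0.5)
    elif name == "mostly_null":
        h2 = np.zeros(r)
        h2[0] = 0.5
        base["h2"] = h2
    elif name == "shared_subgroups":
        if r != 5:
            raise ValueError("shared_subgroups is defined for r = 5")
        base["h2"] = np.array([0.3, 0.3, 0.3, 0.5, 0.5])
    elif name == "low_h2":
        base["h2"] = np.full(r, 0.2)
    elif name == "high_polygenicity":
        base["h2"] = np.full(r, 0.5)
        # causal fraction ~ 50,000 / 595,071 of the full-scale design
        base["n_causal"] = max(1, round(p * 50000 / 595071))
    if name == "external_ld":
        base["external_ld"] = True
    if name == "mcar_missingness":
        base.setdefault("missing_frac", 0.2)
    base["r"] = r
    base["p"] = p
    base.update(overrides)
    if "h2" in base and base["h2"] is not None:
        base["h2"] = np.asarray(base["h2"], dtype=float)
    return ScenarioConfig(**base)


@dataclass
class SimOutput:
    """Everything one replicate produces, including the ground truth."""

    X_train: np.ndarray
    X_test: np.ndarray
    Y_train: np.ndarray
    Y_test: np.ndarray
    B_true: np.ndarray
    positions_cm: np.ndarray
    chrom: np.ndarray
    realized_h2: np.ndarray
    variant_ids: list[str]
    phenotype_ids: list[str]
    config: ScenarioConfig


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genotypes(
    n: int,
    p: int,
    ld_decay: float = 0.9,
    maf_range: tuple[float, float] = (0.05, 0.5),
    map_density_cm: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated 0/1/2 dosages with genetic-map positions.

    Two independent latent haplotype matrices with AR(1) correlation
    ``ld_decay`` along the variant axis are dichotomized at the per-variant
    MAF quantile and summed.  Positions are cumulative exponential gaps with
    mean ``map_density_cm`` centimorgans.  Deterministic given the seed.
    """
    if not (0 <= ld_decay < 1):
        raise ValueError("ld_decay must lie in [0, 1)")
    rng = _rng(seed)
    mafs = rng.uniform(maf_range[0], maf_range[1], size=p)
    thresh = norm.ppf(1.0 - mafs)  # carrier frequency = MAF per haplotype
    c = np.sqrt(1.0 - ld_decay**2)
    X = np.zeros((n, p), dtype=np.int8)
    for _hap in range(2):
        eps = rng.standard_normal((n, p))
        if ld_decay > 0:
            eps[:, 0] /= c  # so the first column keeps unit variance
            Z = lfilter([c], [1.0, -ld_decay], eps, axis=1)
        else:
            Z = eps
        X += (Z > thresh).astype(np.int8)
    positions = np.cumsum(rng.exponential(map_density_cm, size=p))
    return X.astype(float), positions


_SUBGROUPS = ([0, 1, 2], [3, 4])


def simulate_effects(
    cfg: ScenarioConfig, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """True effect matrix B (p × r) under the configured sharing scenario.

    Causal variants are sampled uniformly without replacement; non-causal
    rows are exactly zero.  equal_effects draws one standard normal per
    causal variant and copies it across phenotypes (low_h2,
    high_polygenicity, more_phenotypes and the robustness scenarios reuse
    this pattern); mostly_null puts effects in phenotype 1 only;
    shared_subgroups flips a fair coin per causal variant between phenotype
    groups {1,2,3} and {4,5} and draws correlated-but-unequal effects
    (correlation ``rho_share``) within the active group.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    B = np.zeros((cfg.p, cfg.r))
    causal = rng.choice(cfg.p, size=cfg.n_causal, replace=False)
    name = cfg.scenario
    if name in ("equal_effects", "low_h2", "high_polygenicity", "more_phenotypes",
                "external_ld", "mcar_missingness"):
        B[causal, :] = rng.standard_normal(cfg.n_causal)[:, None]
    elif name == "mostly_null":
        B[causal, 0] = rng.standard_normal(cfg.n_causal)
    elif name == "shared_subgroups":
        if cfg.r != 5:
            raise ValueError("shared_subgroups is defined for r = 5")
        for j in causal:
            group = _SUBGROUPS[int(rng.integers(2))]
            g = len(group)
            C = np.full((g, g), cfg.rho_share)
            np.fill_diagonal(C, 1.0)
            B[j, group] = np.linalg.cholesky(C) @ rng.standard_normal(g)
    else:  # pragma: no cover
        raise ValueError(f"unknown scenario {name!r}")
    return B


def simulate_phenotypes(
    X: np.ndarray,
    B_true: np.ndarray,
    h2: np.ndarray,
    residual_cor: Optional[np.ndarray] = None,
    rng: int | np.random.Generator = 0,
    scale_rows: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phenotypes with the target per-phenotype genomic heritability.

    Each column of B is rescaled so the genetic values G_t = (XB)_t have
    sample variance exactly h2_t on the rows in ``scale_rows`` (all rows by
    default); residuals are multivariate normal with per-phenotype variance
    1 − h2_t and cross-phenotype correlation ``residual_cor`` (identity by
    default), so the total variance is ~1 and Var(G)/Var(Y) ≈ h2.

    Returns (Y, B_scaled, realized_h2) with realized_h2 computed on the
    scaling rows.
    """
    rng = _rng(rng)
    X = np.asarray(X, dtype=float)
    B_true = np.asarray(B_true, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    n, r = X.shape[0], B_true.shape[1]
    if h2.shape != (r,) or np.any((h2 < 0) | (h2 > 1)):
        raise ValueError("h2 must be an r-vector in [0, 1]")
    rows = np.arange(n) if scale_rows is None else np.asarray(scale_rows)
    G = X @ B_true
    vg = G[rows].var(axis=0, ddof=1)
    scale = np.zeros(r)
    for t in range(r):
        if h2[t] > 0:
            if vg[t] == 0:
                raise ValueError(
                    f"phenotype {t + 1} has zero genetic variance but h2 > 0"
                )
            scale[t] = np.sqrt(h2[t] / vg[t])
    B_scaled = B_true * scale
    G = G * scale

    sd_e = np.sqrt(1.0 - h2)
    if residual_cor is None:
        E = rng.standard_normal((n, r)) * sd_e
    else:
        C = np.asarray(residual_cor, dtype=float)
        Lc = np.linalg.cholesky(C)
        E = (rng.standard_normal((n, r)) @ Lc.T) * sd_e
    Y = G + E
    vy = Y[rows].var(axis=0, ddof=1)
    realized = np.divide(
        G[rows].var(axis=0, ddof=1), vy, out=np.zeros(r), where=vy > 0
    )
    return Y, B_scaled, realized


def simulate_scenario(cfg: ScenarioConfig) -> SimOutput:
    """One full replicate: genotypes, effects, phenotypes, train/test split.

    Heritability is enforced on the training rows; the same scaled effects
    generate the test phenotypes.  MCAR missingness (when configured) is
    applied to the training phenotypes only, mirroring missingness in the
    GWAS cohort.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_train + cfg.n_test
    X, positions = simulate_genotypes(
        n, cfg.p, cfg.ld_decay, cfg.maf_range, cfg.map_density_cm, rng
    )
    B0 = simulate_effects(cfg, rng)
    h2 = cfg.h2 if cfg.h2 is not None else np.full(cfg.r, 0.5)
    Y, B, realized = simulate_phenotypes(
        X, B0, h2, cfg.residual_cor, rng, scale_rows=np.arange(cfg.n_train)
    )
    Y_train, Y_test = Y[: cfg.n_train], Y[cfg.n_train :]
    if cfg.missing_frac > 0:
        Y_train = mcar_mask(Y_train, cfg.missing_frac, rng)
    return SimOutput(
        X_train=X[: cfg.n_train],
        X_test=X[cfg.n_train :],
        Y_train=Y_train,
        Y_test=Y_test,
        B_true=B,
        positions_cm=positions,
        chrom=np.array(["1"] * cfg.p),
        realized_h2=realized,
        variant_ids=[f"v{j + 1}" for j in range(cfg.p)],
        phenotype_ids=[f"ph{t + 1}" for t in range(cfg.r)],
        config=cfg,
    )


def quantile_normalize(y: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Maps ranks (ties averaged) through Φ⁻¹((rank − 3/8) / (n + 1/4)); the
    output is order-isomorphic to the input.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 2:
        raise ValueError("need at least two observations")
    if np.all(y == y[0]):
        raise ValueError("cannot quantile-normalize a constant vector")
    ranks = rankdata(y, method="average")
    return norm.ppf((ranks - 0.375) / (n + 0.25))


def gwas_scan(
    X: np.ndarray,
    Y: np.ndarray,
    quantile_norm: bool = False,
    variant_ids: Optional[list[str]] = None,
    phenotype_ids: Optional[list[str]] = None,
) -> GWASSummary:
    """Per-variant simple-regression scan of each phenotype, one at a time.

    Each (variant, phenotype) pair is a univariate regression with intercept
    on that phenotype's complete cases (X must be complete; Y may have NaN).
    When missingness differs across phenotypes, per-phenotype sample sizes
    are emitted — the setting where the engine's complete-overlap assumption
    is deliberately violated.  ``quantile_norm`` applies the rank-based
    inverse-normal transform to each phenotype's complete cases first.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be complete (no missing genotypes)")
    n, p = X.shape
    r = Y.shape[1]
    betahat = np.empty((p, r))
    se = np.empty((p, r))
    n_obs = np.empty(r, dtype=int)
    for t in range(r):
        obs = np.isfinite(Y[:, t])
        n_t = int(obs.sum())
        if n_t < 3:
            raise ValueError(f"phenotype {t + 1} has fewer than 3 complete cases")
        n_obs[t] = n_t
        y = Y[obs, t]
        if quantile_norm:
            y = quantile_normalize(y)
        y = y - y.mean()
        Xc = X[obs] - X[obs].mean(axis=0)
        sxx = np.einsum("ij,ij->j", Xc, Xc)
        if np.any(sxx == 0):
            bad = np.flatnonzero(sxx == 0)
            raise ValueError(
                f"zero-variance genotype column(s) {bad.tolist()} "
                f"on phenotype {t + 1}'s complete cases"
            )
        sxy = Xc.T @ y
        b = sxy / sxx
        # explicit residuals avoid catastrophic cancellation when fits are
        # (near-)exact, so noise-free relations yield se ~ 0
        resid = y[:, None] - Xc * b[None, :]
        rss = np.einsum("ij,ij->j", resid, resid)
        s = np.sqrt(rss / ((n_t - 2) * sxx))
        betahat[:, t] = b
        se[:, t] = np.maximum(s, 1e-150)  # exact fits would give se = 0
    n_out: int | np.ndarray = int(n_obs[0]) if np.all(n_obs == n_obs[0]) else n_obs
    return GWASSummary(
        betahat=betahat,
        se=se,
        n=n_out,
        variant_ids=variant_ids or [f"v{j + 1}" for j in range(p)],
        phenotype_ids=phenotype_ids or [f"ph{t + 1}" for t in range(r)],
    )


def mcar_mask(
    Y: np.ndarray,
    frac_individuals: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Missing-completely-at-random phenotype masking.

    Selects ⌊frac·n⌋ individuals; each gets one of the 2^r − 1 nonempty
    missingness patterns with equal probability and the corresponding
    entries are set to NaN.  Returns a copy.
    """
    if not (0 <= frac_individuals <= 1):
        raise ValueError("frac_individuals must lie in [0, 1]")
    rng = _rng(seed)
    Y = np.asarray(Y, dtype=float).copy()
    n, r = Y.shape
    m = int(np.floor(frac_individuals * n))
    if m == 0:
        return Y
    rows = rng.choice(n, size=m, replace=False)
    patterns = rng.integers(1, 2**r, size=m)  # nonempty subsets as bit masks
    for row, pat in zip(rows, patterns):
        for t in range(r):
            if pat >> t & 1:
                Y[row, t] = np.nan
    return Y


def compute_ld(
    X_ref: np.ndarray,
    positions_cm: np.ndarray,
    chrom: Optional[np.ndarray] = None,
    structure: str = "dense",
    window_cm: Optional[float] = None,
    block_span_cm: Optional[float] = None,
    blocks: Optional[list[tuple[int, int]]] = None,
) -> LDMatrix:
    """Pearson LD matrix of reference genotype columns, then sparsified.

    ``block_span_cm`` derives block-diagonal bounds by cutting the genetic
    map into spans; alternatively pass explicit ``blocks``.  To emulate a
    mismatched reference panel, call with genotypes simulated at a perturbed
    LD decay and a small reference sample size.
    """
    X_ref = np.asarray(X_ref, dtype=float)
    if np.any(X_ref.std(axis=0) == 0):
        bad = np.flatnonzero(X_ref.std(axis=0) == 0)
        raise ValueError(f"zero-variance reference genotype column(s) {bad.tolist()}")
    positions_cm = np.asarray(positions_cm, dtype=float)
    chrom = (
        np.array(["1"] * X_ref.shape[1]) if chrom is None else np.asarray(chrom)
    )
    if X_ref.shape[1] == 1:
        R = np.ones((1, 1))
    else:
        R = np.corrcoef(X_ref, rowvar=False)
    if structure == "block_diagonal" and blocks is None:
        if block_span_cm is None:
            raise ValueError("block_diagonal requires blocks or block_span_cm")
        blocks = block_bounds_by_span(positions_cm, chrom, block_span_cm)
    return apply_ld_structure(
        R, positions_cm, chrom, structure=structure,
        window_cm=window_cm, blocks=blocks,
    )
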