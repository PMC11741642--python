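# Methods

## Model

`mrmash` fits the multivariate multiple regression

Y = XB + E, E ~ MN(0, I_n, V),

with Y the n × r phenotype matrix, X the n × p genotype matrix, B the p × r
effect matrix and V the r × r residual covariance across phenotypes. Rows of
B are i.i.d. a priori from a K-component mixture of r-variate normals,
b_j ~ Σ_k w0_k N(0, S0_k). The S0_k are fixed candidate covariance patterns;
the weights w0 (and optionally V) are estimated from the data by maximizing
the evidence lower bound (ELBO) — variational empirical Bayes.

### Sufficient statistics and the summary-data path

The likelihood depends on (X, Y) only through XᵀX, XᵀY, YᵀY and n, so the
engine (`mrmash.engine`) consumes a `SufficientStats` triple and nothing
else. On the summary-data path these are rebuilt from per-variant simple
regressions under the convention that phenotypes are variance-standardized
(yᵀy = n − 1 after centering) and genotypes centered:

- d_jt = yty_t / (se_jt²(n_t − 2) + betahat_jt²) recovers xⱼᵀxⱼ per
  phenotype; under complete sample overlap the d_jt agree across t, and are
  collapsed by the **median** over t (robust; dispersion is surfaced by
  `qc_consistency` as a sample-overlap/allele-mismatch symptom rather than
  silently averaged).
- XᵀY[j] = betahat_j · d_j (exact), XᵀX = D^{1/2} R D^{1/2} with R the LD
  correlation matrix (exact only when R is in-sample; a
  `xtx_approximate` flag records the reference-panel case).
- YᵀY: its diagonal is implied by the standardized convention (n − 1), but
  its off-diagonal is not identified by per-variant statistics. It is
  filled from a user-supplied phenotype correlation matrix when available,
  else estimated from the cross-phenotype correlation of z-scores at
  null-ish variants (max |z| < 2), as in adaptive-shrinkage practice; YᵀY
  can also be supplied whole, or omitted entirely, in which case V must
  stay fixed (default V: YᵀY/n when available, else the identity).

Estimating V by its M-step is sound only when YᵀY and XᵀX come from the
same data as the summary statistics: with an approximate YᵀY (the null-z
estimate is attenuated by its joint truncation) or a sparsified/panel XᵀX,
the expected residual second moment can go indefinite, collapsing V
against its eigenvalue floor and inflating the ELBO. The CLI therefore
fits with V fixed by default (`--update-v` opts in); the library default
(`FitOptions.update_V=False`) matches.

QC thresholds (`d_rtol` = 0.1 relative spread of d_jt; z-vs-LD deviation
threshold 4 within |r| ≥ 0.8 neighborhoods) are implementer defaults,
configurable, and reporting-only.

### Coordinate ascent and the ELBO

The variational family factorizes over variants. Each coordinate update
forms the residualized estimate b̂_j = (XᵀY_j − (XᵀXB̄)_j + d_j B̄_j)/d_j,
for which b̂_j | b_j ~ N(b_j, V/d_j) — a conjugate problem solved in closed
form per component using the S0(S0 + V/d)⁻¹ factorization, so rank-deficient
components (null, singletons, rank-1 data-driven) need no inversion.
Internally all components are eigendecomposed once per sweep in V-whitened
coordinates, reducing every per-variant solve to elementwise arithmetic;
the reference implementation `posterior_per_variant` (direct matrix
algebra) is kept as an independent cross-check and both paths are tested to
agree to 1e-10.

Because each q_j is the *exact* conjugate posterior at its b̂_j, its KL to
the prior equals E_q[log N(b̂_j; b_j, V/d_j)] − log Σ_k w0_k N(b̂_j; 0,
S0_k + V/d_j), and the ELBO assembles exactly from per-variant terms plus
the expected residual sum of squares — no quadrature or bound-on-a-bound.
The recorded ELBO at each sweep reflects the state after the coordinate
updates and before the M-steps, making the trace provably nondecreasing
(guard: error on any decrease beyond 1e-8 relative). The M-steps are the
closed forms w0_k = mean_j γ_jk and V = E_q[(Y − XB)ᵀ(Y − XB)]/n
(symmetrized, eigenvalues floored at 1e-8). Without YᵀY the ELBO omits the
additive constant −½tr(V⁻¹YᵀY).

Numerical/algorithmic choices:

- Convergence: relative ELBO change < 1e-6, max 500 sweeps (defaults).
- Update order: fixed ascending by default for reproducibility; per-sweep
  shuffling available behind a seed. The ELBO is a function of the
  variational state (reconstructible from the recorded b̂ matrix, w0, V),
  not of the update path — `compute_elbo` verifies this.
- Storage: per-variant r × r second moments are not retained; only the
  running sums Σ_j M2_j and Σ_j d_j(M2_j − b̄_j b̄_jᵀ) (plus the p × r b̂
  matrix), bounding memory at biobank p.
- Responsibilities are normalized in log space; zero weights are handled
  as −∞ log-weights.
- Per-chromosome fitting: the engine fits one LD block-set at a time;
  predictions add across parts (`pgs_score(per_chrom_parts=...)`).

### Prior construction

Canonical components: identity (independent effects), r singletons
(effect in one phenotype), all-ones (equal effects), and constant-ρ
matrices (shared, unequal; ρ ∈ {0.25, 0.5, 0.75} by default). Data-driven
components come from strong signals (default: LD-pruned variants with
max |z| > 4): rank-1 matrices from the top principal components of
ZᵀZ/m − I (clipped PSD), refined by 50 extreme-deconvolution EM iterations
for z ~ N(0, U + I) with PSD projection each step. Richer factorization-
based estimators exist; fixed-iteration ED was chosen as the simplest
member of that family with the identifiability the tests require. Each
base pattern is crossed with a scale grid — geometric, auto-ranged from
min(se)/10 to 2·max|betahat| on the standard-deviation scale (ratio √2) in
the CLI, mirroring adaptive-shrinkage practice; mixtures of 100+ components
are normal. The null (zero) component is always index 0, components are
deduplicated at 1e-12, and every construction path keeps eigenvalues ≥
−1e-10.

### mash initialization for dense architectures

Empirical-Bayes weight updates can over-shrink very polygenic traits. The
two-step strategy: (1) greedy LD pruning (default r² ≤ 0.1, priority by
max |z|), (2) maximum-likelihood mixture weights on the pruned variants
ignoring LD, with per-variant error covariance diag(se²) — because the
component covariances are fixed, the (m × K) log-likelihood matrix is
precomputed once and EM iterates on the weights only (exact and monotone);
(3) the null weight is reset to 0.5 with the rest rescaled proportionally
(the pruned-sample fit underestimates it); (4) the engine runs with weight
updates limited to the first 10 sweeps. The 0.5 and 10 are the method's
stated defaults, exposed as configuration. All pruned variants are used
for the weight fit (the sampling fraction is otherwise unspecified).

## Evaluation

Prediction accuracy is the R² from regressing true on predicted phenotypes
(with intercept) — equal to the squared Pearson correlation, invariant to
affine transforms of the score, and bounded above in expectation by the
genomic heritability h²_g. Zero-variance predictions return R² = 0 by
convention so null fits evaluate cleanly. R² is reported per phenotype; no
multivariate aggregate is defined.

## Simulator

`mrmash.simulate` emulates the study conditions at desk scale:

- **Genotypes**: two latent haplotype matrices with AR(1) correlation
  (default 0.9) along variants, dichotomized at per-variant MAF quantiles
  (MAF ~ U(0.05, 0.5)) and summed to 0/1/2 dosages; map positions are
  cumulative exponential gaps (mean 0.05 cM). This gives tunable,
  banded-decay LD with a known latent correlation, but not the long-range
  haplotype structure, allele-frequency spectrum or demography of real
  genotypes — conclusions from passing tests concern the statistical
  machinery, not population-genetic realism.
- **Effects**: causal variants sampled uniformly without replacement;
  Equal Effects copies one N(0,1) draw across phenotypes; Mostly Null puts
  effects in phenotype 1 only; Shared Effects in Subgroups flips a fair
  coin between phenotype groups {1,2,3} and {4,5} and draws within-group
  effects with correlation 0.8 ("shared but not equal"; the exact value is
  a documented choice). The effect-size family (normal) and the residual
  correlation across phenotypes (identity) are configurable defaults.
- **Heritability**: each column of B is rescaled so the genetic variance
  equals h² exactly in-sample on the training rows, with residual variance
  1 − h²; realized h² = Var(XB)/Var(Y) then matches the target up to the
  residual's sampling noise. Exact in-sample enforcement is a cleaner
  testing contract than calibrating the effect variance a priori.
- **Scenario targets**: h² = 0.5 (Equal Effects and variants), 0.5/0/0/0/0
  (Mostly Null), 0.3/0.3/0.3/0.5/0.5 (Shared Subgroups), 0.2 (Low h²);
  High Polygenicity multiplies the causal fraction tenfold; More
  Phenotypes uses r = 10. Defaults are scaled down from the full design
  (105,000 × 595,071, 5,000 causal) to 2,000 × 2,000 with 50 causal.
- **GWAS scan**: per-(variant, phenotype) simple regression with intercept
  on that phenotype's complete cases, optional rank-based inverse-normal
  transform (Blom offset 3/8); residuals are computed explicitly to avoid
  catastrophic cancellation for near-exact fits. **MCAR missingness**
  assigns ⌊frac·n⌋ individuals one of the 2^r − 1 nonempty missingness
  patterns uniformly. **LD** is the Pearson correlation of reference
  genotype columns, banded (entries > window cM apart zeroed; ties at the
  window retained) or block-diagonal; an external-panel mode draws the
  reference at a perturbed LD decay with a small sample (default 503).

Everything is deterministic given (config, seed).

## Problem sizes used in the checks

The shipped test suite and acceptance script run at desk scale, chosen so
the full battery completes in minutes on one CPU: heritability-recovery
checks at 2,000 × 2,000 (50 causal, 20 replicates), the
summary/individual equivalence at 500 × 50 × 3, ELBO monotonicity over 50
random instances, and the multivariate-vs-univariate comparison at
800/400 × 400 with 20 causal over 20 replicates. The causal-count check
runs the effect sampler at the full 595,071-variant design.

## Known limitations

- Complete sample overlap across phenotypes is assumed by the engine;
  MCAR missingness is supported only upstream (per-phenotype complete-case
  summary statistics), deliberately violating that assumption for
  robustness experiments.
- The off-diagonal of YᵀY is not identified from per-variant summary
  statistics; estimating V without phenotype-correlation information uses
  a diagonal YᵀY proxy.
- No allele harmonization, liftover or PLINK/BGEN parsing: genotypes enter
  via the simulator or plain matrices.
- Per-variant sample-size heterogeneity (meta-analysis summary statistics)
  and case-control phenotypes are out of scope.
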