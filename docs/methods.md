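# Methods

## Model

For a quantitative trait measured on `n` related individuals, the
package assumes the linear mixed model

    y = X α + h + b + ε

where `X` is the `n×p` covariate design (intercept first), `α` the fixed
effects, `b ~ N(0, σ_b² R)` a polygenic random effect structured by the
relationship matrix `R` (twice the kinship matrix), and
`ε ~ N(0, σ_e² I)` the residual.  The regional effect `h` has covariance
`τ K`, with `K` a kernel built from the `n×m` dosage matrix `G` of the
SNPs in one genomic region.  The null hypothesis of no regional effect
is `H₀: τ = 0`, so under the null

    y ~ N(X α, V),    V = σ_b² R + σ_e² I.

The association test is the variance-component score test: with the
projection `P = I − X (Xᵀ V⁻¹ X)⁻¹ Xᵀ V⁻¹` and `q = V⁻¹ P y`,

    Q = ½ qᵀ K q,

and under `H₀`, `Q ~ Σᵢ λᵢ χ²₁` where `λ` are the nonzero eigenvalues of
`½ V^(−1/2) P K Pᵀ V^(−1/2)`.  The factor ½ is a convention applied
consistently to both `Q` and the eigenvalue matrix; any consistent pair
gives identical p-values.  The test suite validates the pairing
distributionally: simulated null traits produce an empirical `Q`
distribution that matches `Σ λᵢ χ²₁` by Kolmogorov–Smirnov test.

## Two-step computation and its accelerations

Step 1 (once per trait): fit the null model and precompute every
genotype-independent quantity.  `R = U D Uᵀ` is eigendecomposed once;
rotating `y` and `X` by `Uᵀ` diagonalizes `V`, so the profile likelihood
in the heritability `h² = σ_b²/(σ_b²+σ_e²)` costs `O(n p²)` per
candidate.  `α` and the total variance are profiled in closed form and
`h²` is found on `[0, 1−1e−6]` by a 21-point grid scan followed by
bounded scalar minimization (tolerance 1e−8).  ML is the default; REML
is available.  The precomputed invariants are `q = V⁻¹ P y`, the
symmetric matrix `V⁻¹P`, and the Cholesky factor `L` of `V`.

Step 2 (per region) uses two algebraically equivalent routes:

* **Weighted linear kernel** `K = G W W Gᵀ` (`W = diag(w)`): `Q`
  collapses to `½ ‖W Gᵀ q‖²` without forming `K`, and the `n×n`
  whitened matrix is replaced by the `m×m` matrix `½ W Gᵀ (V⁻¹P) G W`,
  which has the same nonzero spectrum (cyclic-permutation argument,
  using `Pᵀ V⁻¹ P = V⁻¹ P` and idempotence of `P`).  Since regions
  typically hold far fewer SNPs than there are samples, this is the
  fast path; it is selected automatically for linear kernels and
  remains correct (merely not faster) when `m > n`.
* **General kernels** (polynomial, IBS): the whitened matrix
  `½ L⁻¹ P K Pᵀ L⁻ᵀ` simplifies to the symmetric form
  `½ Lᵀ (V⁻¹P) K (V⁻¹P) L`, again with unchanged nonzero spectrum.

Eigenvalues below `1e−10 × λ_max` are discarded: the numerical rank of
`GW` is at most `min(n, m)` and trailing noise eigenvalues destabilize
the tail computation.

## P-value engines

`P(Σ λᵢ χ²₁ > Q)` is computed two ways.

* **Characteristic-function inversion** (`davies_pvalue`): the exact
  Gil-Pelaez/Imhof integral
  `p = ½ + (1/π) ∫₀^∞ sin θ(u) / (u ρ(u)) du` with
  `θ(u) = ½ Σ arctan(λᵢ u) − Qu/2` and
  `ρ(u) = Π (1 + λᵢ² u²)^{1/4}`.  The integrand is integrated
  lobe-by-lobe between the zeros of `sin θ` with adaptive quadrature;
  the alternating tail series is summed by iterated averaging
  (Euler-type acceleration).  `acc` (default 1e−9, absolute) sets the
  convergence target and `lim` (default 10⁴) caps the number of tail
  lobes; non-convergence or a result outside (0, 1] is reported via
  `ifault` for the caller to fall back on.
* **Saddlepoint** (`kuonen_pvalue`): solve `K′(t̂) = Q` for the cumulant
  generating function `K(t) = −½ Σ log(1 − 2tλᵢ)` on
  `t < 1/(2λ_max)` by bracketed Brent iteration, then apply the
  classical two-term Lugannani–Rice formula
  `p = 1 − Φ(w) − φ(w)(1/w − 1/v)` with
  `w = sign(t̂)√(2(t̂Q − K(t̂)))`, `v = t̂√(K″(t̂))`.  The two-term form
  is used because it is markedly more accurate than the exponentiated
  r* variant in the heavily skewed few-eigenvalue regime (measured
  worst relative error against exact chi-square: 6.9% at one
  eigenvalue, ~1/k decay with k equal eigenvalues; the r* variant is
  kept only as a positivity fallback at extreme tails).  The removable
  singularity at `Q = Σλᵢ` is handled by symmetric evaluation one
  milli-standard-deviation to either side, which cancels the
  first-order error and keeps the result stable to ~1e−7.

The default policy is exact inversion with saddlepoint fallback,
recorded in the per-region flags.

## Kinship construction

* **Pedigree**: recursive (tabular) kinship over a topological order —
  `Φ_ii = ½(1 + Φ_fm)`, `Φ_ij = ½(Φ_jf + Φ_jm)` — doubled to give `R`.
  Founders are assumed non-inbred and unrelated, so disconnected
  families yield exact zero blocks.  The matrix is nevertheless carried
  as a full dense `n×n` matrix in the analysis; no block-structure
  shortcuts are taken.
* **Genomic**: a VanRaden-type centered-and-scaled cross-product,
  `R_ij = (1/m′) Σ_k (g_ik − 2p_k)(g_jk − 2p_k) / (2p_k(1−p_k))` over
  markers passing a minor-allele-frequency floor (default 0.01), with
  missing dosages imputed to `2p_k`.  The literature offers several
  genomic-relationship estimators; this one is chosen for being the
  field's most common default and for matching the pedigree expectation
  (unit diagonal, zero off-diagonal mean in unrelated samples), which
  the tests verify by moment checks and by correlating it against
  pedigree kinship on gene-dropped data.

## Weights and cleaning

Default SNP weights are the Beta(1, 25) density evaluated at the sample
minor-allele frequency — the rare-variant-emphasizing convention of the
kernel-association literature — with Madsen–Browning
(`1/√(maf(1−maf))`), uniform and custom weights available.  Dosages are
alternate-allele counts as read; alleles are not re-polarized, and the
weight argument is always `min(p, 1−p)`.  Region cleaning imputes
missing dosages to the column mean, drops monomorphic columns, and
optionally applies an inclusive MAF window (off by default).  A region
losing all columns is flagged untestable, never raised.

## Synthetic data

The simulator generates what the method consumes, with known truth:

* **Pedigrees**: replicated disconnected blocks; the default template
  is an 18-member three-generation family (2 grandparents, 4 children
  with married-in founder spouses, 8 grandchildren), mimicking
  family-study designs where a cohort of a few hundred to a few
  thousand individuals is composed of such blocks.
* **Genotypes**: unlinked SNPs gene-dropped from founder alleles
  (Bernoulli(p), fair meiosis).  No linkage disequilibrium is modelled:
  LD realism is irrelevant to validating the test's algebra and null
  distribution, so passing tests say nothing about LD-driven effects in
  real data.  Founder frequencies default to an exome-like 0.001–0.5
  spread.
* **Traits**: drawn forward from the mixed model with residual
  heritability 0.44 by default (a realistic mid-range value for a
  complex quantitative trait) and optional fixed SNP effects; the
  polygenic term uses the pedigree-derived `R`, so variance-component
  recovery is an exact-model check.
* **Regions**: contiguous partitions with a right-skewed size law
  clipped to [2, 102] and median 4, the shape of exome region files.

A single integer seed expands to per-component substreams through
`numpy.random.SeedSequence`.

## Study sizes used in validation

The heavier checks use: type-I error — 2000 null replicates on a
7-family sample (n = 126), each replicate refitting the null model;
heritability recovery — 100 replicates on 56 families (n = 1008);
distributional self-consistency — 5000 null traits per fixture on three
regions; covariate-mode comparison — 50 regions at n = 504; engine
agreement — 200 random mixtures.  An exome-scale smoke test runs ~1550
regions over 9868 SNPs at n = 504.

## Numerical and design notes

* `R = I` makes `h²` unidentifiable (`V ∝ I` for every `h²`); the
  fitter detects the flat profile and reports `h² = 0` with a flag
  instead of an arbitrary interior value.  In this limit the test
  reduces exactly to ordinary (unrelated-sample) SKAT, which the suite
  verifies against an independently coded OLS-based implementation.
* A trait fitting the covariates exactly (zero residual variance) is
  reported with a `degenerate_fit` flag rather than an error.
* Pre-adjustment mode replaces the trait by its OLS residuals on the
  covariates and tests with an intercept-only design.  It gives
  p-values close but not identical to carrying the covariates in the
  mixed model; both modes are exposed and the suite bounds their
  disagreement.
* Parallel region analysis partitions work by region (joblib); results
  are reduced in input order and are bit-identical to sequential runs.
* Sample alignment is always by id.  Phenotyped samples missing from
  the genotypes are an error; genotyped samples missing from the
  phenotypes are dropped with a log line.

## Known limitations

Quantitative traits only (no binary-trait score test); a single
polygenic random effect (no GxE, no multiple variance components); no
small-sample moment corrections or optimal-rho kernel combination; the
saddlepoint engine's accuracy degrades to a few percent relative when
the spectrum is dominated by one or two eigenvalues (the exact-inversion
engine is the default for this reason).
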