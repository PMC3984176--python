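# Methods

## Model and scope

`phylopls` tests for evolutionary integration between two blocks of
continuous traits measured across N species related by a rooted phylogeny
with branch lengths.  The evolutionary model throughout is multivariate
Brownian motion (BM): trait change along a branch is Gaussian with mean
zero and covariance proportional to branch length, so tip values follow a
matrix-normal distribution with among-species covariance C (the N×N matrix
of shared root-to-MRCA path lengths) and among-dimension covariance R (the
p×p evolutionary rate matrix).  Non-Brownian processes
(Ornstein–Uhlenbeck, rate shifts), within-species variation and missing
data are out of scope.  Polytomies are supported everywhere except the
independent-contrasts route, which requires a strictly bifurcating tree.

## Estimators

* Phylogenetic (root) mean: `a = (1'C⁻¹1)⁻¹ 1'C⁻¹Y`, the GLS estimate of
  the multivariate state at the root.
* Evolutionary covariance: `R = (Y − 1a')' C⁻¹ (Y − 1a') / (N−1)`.  The
  N−1 denominator makes the estimate unbiased; on a star tree (C ∝ I) it
  reduces to the ordinary sample covariance matrix.
* Phylogenetic transformation: `Y_phy = D (Y − 1a')` with
  `D = E Λ^{−1/2} E'` from the eigen-decomposition `C = E Λ E'`.  The
  symmetric inverse square root is the unique symmetric choice for which
  `Y_phy' Y_phy / (N−1) = R` holds exactly; that identity is asserted in
  the test suite at 1e−10.
* Two-block PLS: R is partitioned by the block specification and
  `R₁₂ = U diag(d) V'` decomposed by SVD.  First-axis scores are
  `s₁ = Y_phy,1 u₁` and `s₂ = Y_phy,2 v₁`.

C⁻¹ is applied through factorized solves or the eigenbasis; the only
explicitly formed matrix is D, which is needed for projection.

## The r_PLS statistic

r_PLS is the correlation of the two score vectors **about the origin**,
`r = s₁'s₂ / √(s₁'s₁ · s₂'s₂)`.  The scores are deviations from the
fitted mean — the GLS root state after transformation — so the origin is
the natural centre, and `s₁'s₂/(N−1)` equals the leading singular value
d₁ ≥ 0, which makes r_PLS non-negative by construction whenever the
blocks covary at all.  Two consequences motivated this choice:

* For ordinary PLS the centered columns give mean-zero scores, so the
  definition coincides with the Pearson correlation, and the star-tree
  reduction (phylogenetic ≡ ordinary when C = σ²I) is exact to machine
  precision.
* The contrasts-based route computes scores from standardized contrasts,
  which have expectation zero under BM and are conventionally not
  re-centered; with the origin-centered definition both routes return the
  same number to ~1e−15, turning the GLS/contrasts equivalence into an
  exact cross-check rather than an approximate one.

Only the first axis pair defines the statistic and the test; all axes and
singular values are retained in the result object.

## Permutation test

Significance is assessed by permutation of one block with the statistic
recomputed per permutation, p = (#{r_perm ≥ r_obs} + 1)/(B + 1) with
B = 999 by default (199 in study mode, where thousands of datasets are
processed).  The comparison is one-sided (≥) because r_PLS is
non-negative by construction.

What is shuffled matters.  Under the Brownian null hypothesis of no
between-block covariation the raw tip values are *not* exchangeable —
each block is still correlated across species through C — and permuting
raw rows across the tips produces null datasets whose phylogenetic
structure has been destroyed.  Measured at N = 32, p = 6, α = 0.05
(199 permutations, 200 datasets), that scheme yields a Type I error near
0.21.  The exchangeable units are instead the rows of the transformed
data `Y_phy` (standardized contrasts in the contrasts route), which under
the null are i.i.d.; permuting those rows and recomputing the cross-block
covariance, SVD, scores and correlation gives an empirical Type I error
of 0.045–0.055 across several thousand simulated datasets, matching the
nominal level.  `phylopls` therefore permutes transformed block-2 rows.
Because the GLS route permutes N transformed rows and the contrasts route
permutes N−1 contrast rows, their p-values agree statistically but not
replication-for-replication; the observed r_PLS remains identical.

The permutation stream is a seeded NumPy generator; the seed is a
mandatory API argument (defaulted and logged in the CLI), and identical
seeds give bit-identical null distributions.

## Synthetic data and the calibration study

The simulation module emulates the standard operating-characteristics
design for a comparative-methods test:

* **Trees**: pure-birth (Yule) bifurcating trees, unit speciation rate,
  grown to N tips plus one extra exponential waiting time (so terminal
  sister branches have positive length), rescaled to unit root-to-tip
  depth.  The pure-birth model is the neutral default for such studies;
  depth rescaling decouples the evolutionary rate from tree size.
* **Input covariance**: isotropic rates σ² = 1 on the diagonal; every
  off-diagonal entry equal to the integration level b (equicorrelation).
  Eigenvalues are 1 + (p−1)b and 1 − b, so the matrix is positive
  definite for all 0 ≤ b < 1 at any p, and b = 0 gives fully independent
  dimensions (the Type I condition).  The equicorrelated structure
  concentrates the shared signal on one direction, so cross-block
  covariance accumulates with dimensionality; an alternative structure
  with covariance only between matched cross-block pairs spreads the
  signal across p/2 equal singular values and measurably *loses* power as
  p grows, contrary to the behaviour this test is known for.
* **Traits**: `Y = L_C Z L_Σ'` with Cholesky factors of C and Σ and Z
  i.i.d. standard normal — the exact matrix-normal law implied by BM on
  the tree.  The root state is zero; location invariance of all
  statistics is property-tested.
* **Study loop**: per dataset a fresh tree, fresh data, fresh permutation
  seed, all drawn from one deterministic per-cell stream, so the entire
  study reproduces bit-identically from a single master seed.  Failures
  are counted per cell, never silently dropped.

Default study grid: N ∈ {16, 32, 64, 128}, p ∈ {6, 8, 10, 16, 20, 30}
split equally between blocks, b ∈ {0, 0.1, …, 0.9}, α = 0.05.  The test
suite and the acceptance script run deliberately reduced slices of this
grid — 300–500 datasets per cell with 199 permutations, the cells
(N = 32, p = 6) for calibration, b ∈ {0.2, 0.6} for the effect-size
ordering, N ∈ {16, 64} and p ∈ {6, 20} for the sample-size and
dimensionality orderings — sizes chosen so Monte-Carlo error is small
relative to the effects being demonstrated.

What the generator does **not** emulate: measurement error and
within-species sampling, non-ultrametric or empirically shaped trees,
non-isotropic within-block covariance, selection-driven (non-BM)
covariation, and the Procrustes superimposition step that produces real
geometric-morphometric variables (which induces mild dependence among
coordinates).  Passing calibration under the generator therefore shows
the test is valid for BM data on random ultrametric trees, not that real
shape data satisfy those assumptions.

## Numerical choices

* C is declared numerically singular when its smallest eigenvalue is
  ≤ 1e−12 × the largest; estimation then raises an error rather than
  regularizing, since a silent ridge term would change R.  Zero-length
  branches are permitted with a warning (they only matter if they make C
  singular).
* SVD sign convention: within each left singular vector the
  largest-magnitude entry is made positive (ties → lowest index) and the
  paired right vector flipped with it; r_PLS is invariant to this.
* Degenerate inputs — a block with zero variance after transformation, or
  an all-zero cross block — raise explicit errors instead of propagating
  NaN.
* Taxon order is canonicalized by lexicographic sort during alignment, so
  no statistic depends on file row order.
* The `D·D = C⁻¹` identity is verified relative to the magnitude of C⁻¹,
  whose entries grow without bound as terminal branches shorten.
* Non-ultrametric trees are accepted without comment: C is well-defined
  and the GLS machinery does not require equal tip depths.

## Known limitations

* The permutation test is calibrated empirically, not exact: estimating
  the root mean introduces slight dependence among transformed rows, and
  the observed Type I error (~0.045–0.05) is marginally conservative.
* Power values depend on the (unknowable in general) structure of the
  input covariance; the package's study reproduces orderings — power
  rising with b, N and p — not any particular power value.
* High-dimensional data (p approaching N) make R rank-deficient; the SVD
  and r_PLS remain defined, but R itself is a poor estimate of the true
  rate matrix in that regime and no shrinkage is offered.
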