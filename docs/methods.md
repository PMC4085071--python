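# Methods

## Model

All measures operate on two objects: a species × assemblage abundance
matrix *z_ik* (any importance measure — counts, biomass, cover, relative
abundance) and a symmetric, nonnegative S×S distance matrix [*d_ij*] with
intraspecific distances on the diagonal (zero unless supplied).  Sums run
over all S² ordered species pairs, diagonal included, so nonzero
intraspecific variability is honoured when trait data support it.

Single assemblage, order *q* ≥ 0:

* quadratic entropy *Q* = Σ *d_ij p_i p_j*;
* functional Hill number *ᵠD(Q)* = [Σ (*d_ij*/*Q*)(*p_i p_j*)ᵠ]^{1/(2(1−q))};
* mean functional diversity *ᵠMD* = *Q·D*; total functional diversity
  *ᵠFD* = *Q·D²*.

Decomposition over N assemblages (gamma from the pooled relative
abundances *z_i₊/z_₊₊*; in the alpha formula *Q* is always the *pooled*
quadratic entropy):

* *FD_γ* = *Q*·[Σ_ij (*d_ij*/*Q*)(*z_i₊z_j₊*/*z_₊₊*²)ᵠ]^{1/(1−q)};
* *FD_α* = (*Q*/N²)·[Σ_ij (*d_ij*/*Q*) Σ_km (*z_ik z_jm*/*z_₊₊*²)ᵠ]^{1/(1−q)};
* *FD_β* = *FD_γ*/*FD_α* ∈ [1, N²]; *D_β* = *MD_β* = √*FD_β* ∈ [1, N].

The assemblage double sum in the alpha factorizes,
Σ_km (*z_ik z_jm*)ᵠ = (Σ_k *z_ik*ᵠ)(Σ_m *z_jm*ᵠ) (and analogously for the
q→1 entropy term), so the implementation is O(S² + SN) rather than the
literal O(S²N²); the brute-force quadruple loop survives only as the test
oracle.  Beta components for *D* and *MD* are reported as √*FD_β* rather
than recomputed, which makes the identity *D_β* = *MD_β* exact by
construction.

Overlap transforms of *FD_β* (local *C\**, regional *U\**, homogeneity
*S\**, turnover complement *V\**) and of the ordinary Hill beta (*C_qN*,
*U_qN*) are pure functions of (beta, N, q); inputs outside [1, N²] (resp.
[1, N]) beyond 1e-9 raise, because they can only come from an upstream
inconsistency, and values inside the tolerance band are clamped.  Algebra
note: *S\** coincides with *C\** at q = 2 and with *U\** at q = 0, while
*V\** coincides with *C\** at q = 0 and *U\** at q = 2; the tests assert
exactly these pairings.

Legacy comparison measures: additive quadratic-entropy excess
(*Q_γ* − *Q_α*)/*Q_γ*; the maximum-distance effective number
*De* = 1/(1 − *Q*/*d_max*) with its two normalizations
(1 − *α_e*/*γ_e*)/(1 − 1/N) and (*γ_e*/*α_e* − 1)/(N − 1).  *d_max*
defaults to the maximum of the distance matrix restricted to the species
actually present (the scale on which those measures normalize distances to
[0, 1]); the full-matrix maximum is available via `d_max_scope="matrix"`.

## Parameters and defaults

* **q grid** — profiles default to 0:5 in steps of 0.05; beyond q ≈ 4 the
  curves change little.  q = 1 always dispatches to the closed-form limit
  at equality, never an epsilon window.
* **Pooling scheme** — `relative` (equal-weight; each column rescaled to
  sum 1, z₊₊ = N) is the default and is what every worked example uses;
  `absolute` pools raw abundances (size-weighted).  When columns already
  sum to one the two coincide, which is tested.
* **Symmetry tolerance** — matrices must be symmetric to a relative 1e-10;
  asymmetric input is an error unless `symmetrize="mean"` is requested
  explicitly.
* **Gower distance** — equal trait weights by default; quantitative traits
  scaled by their range over the whole table (not per pair); categorical /
  binary traits contribute 0–1 mismatch; missing values handled by
  pairwise deletion with renormalization over jointly observed traits
  (the standard Gower convention; chosen here because mixed-trait sources
  rarely state their handling).  Ordinal traits are accepted but treated
  as categorical with a warning — rank interpolation is out of scope.

## Degenerate inputs and numerical choices

* A single species with zero intraspecific distance has Q = 0; the
  functional Hill number returns 1 with a warning (MD = FD = 0).  Q = 0
  with several species present is an error — the measures are undefined
  and no convention is imposed.
* Pairs with zero joint abundance contribute nothing for q > 0 and are
  excluded at q = 0 (presence requires positive abundance); 0·log 0 := 0.
* The legacy *De* raises for Q ≥ d_max rather than clamping, so domain
  violations surface instead of being silently absorbed.
* Continuity across q = 1 is verified numerically
  (|D(1 ± 1e-6) − D(1)| < 1e-4 on random instances).

## Synthetic data

`funchill.datasets` generates every input the tests need:

* the exact four-species desk example (ultrametric and non-ultrametric
  matrices, two completely distinct two-species assemblages).  The
  within-assemblage distance of 0.1 is a reconstruction uniquely forced by
  the stated alpha quadratic entropy of 0.05 under equal abundances.
* the 20+20-species layout with 12 shared species, equal abundances by
  default; the heterogeneous variant draws seeded log-normal (σ = 1)
  relative abundances per assemblage — a generic right-skewed abundance
  model, not a transcription of any published table.
* the two 28×28 distance-matrix recipes: all off-diagonal pairs beta(4,4),
  versus uniform(0.8, 1) for the 8×8 block of non-shared cross pairs and
  uniform(0, 0.2) elsewhere.  These reproduce the *distributional* recipes
  only; any particular draw differs from any particular published draw,
  so tests assert distribution-level facts (mean ≈ 0.5; relative
  gamma–alpha entropy difference > 40%), not table values.  An exact
  reproduction of published tables requires ingesting the original
  spreadsheet, for which `funchill.io.convert_xlsx_matrices` and the
  `fixtures --from-xlsx` flag exist.
* the replication construction: N relabeled copies of a base assemblage
  with every S×S block of the pooled distance matrix equal to the base
  matrix, which makes all within/cross quadratic entropies equal — the
  hypothesis of the replication principle (D and MD scale with N, FD with
  N²), verified for N ∈ {2, 3, 4}.
* seeded random instances (uniform distances, gamma abundances,
  controllable sparsity with row/column repair) for the oracle and
  property suites.

What the generators do *not* emulate: sampling error (abundances are
parameters, not draws from a finite sample), trait measurement noise, or
phylogenetic correlation among distances.  Passing tests therefore
establish mathematical correctness of the measures, not robustness to
undersampled field data — no sampling-bias correction is implemented.

## Verification strategy

Every vectorized kernel is checked against an independent plain-Python
brute-force oracle (double loop for single-assemblage measures, quadruple
loop over species and assemblage pairs for the alpha) at small sizes
(S ≤ 6, N ≤ 3, 200 random instances), alongside the closed-form anchors:
q = 0 forms (D = √(FAD/Q), FD = FAD), constant-distance reduction to
ordinary Hill numbers, the order-2 identity FD·(Q − GS_D) = Q² with the
distance-weighted Gini–Simpson index, and gamma ≥ alpha with the beta
ranges.  The Gower implementation is cross-checked against
`cluster::daisy` in R on a mixed table.  Problem sizes in the test and
acceptance runs (S ≤ 28, N ≤ 4) were chosen as the smallest that exercise
every code path and published desk value.

## Known limitations

* No sampling-theoretic bias correction; all formulas are plug-in.
* Negative orders q < 0 are rejected.
* The dendrogram-based and similarity-matrix-based diversity families are
  out of scope, as are ordination bridges and bootstrap intervals for the
  differentiation measures.
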