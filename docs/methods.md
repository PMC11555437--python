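# Methods

## Model and hypotheses

For n subjects with response y (continuous or binary), treatment T, covariates
Z and a p-column variant matrix X (p possibly ≫ n), the model is a kernel
machine regression with main and treatment-interaction variant effects:

    y = α₁ + T α₂ + Z α₃ + f(X) β₁ + (f(X) ⊙ T) β₂ + ε            (continuous)
    logit E(y) = α₁ + T α₂ + Z α₃ + f(X) β₁ + (f(X) ⊙ T) β₂       (binary)

where f is an arbitrary (possibly unknown) transformation and ⊙ is the
row-wise Hadamard product with T. The global null is β₁ = β₂ = 0, i.e.
β₁ᵀβ₁ = 0 and β₂ᵀβ₂ = 0, against alternatives with main effects, interaction
effects, or both.

The key point is that the analysis never needs f(X). Any PSD kernel K is the
gram matrix of some transformed variant matrix; its eigendecomposition
K = U D² Uᵀ yields **surrogate variants** X\* = U D (an n × df matrix,
X\* X\*ᵀ = K) that stand in for the unknown f(X). This is what lets the
method work with ecological kernels — Jaccard, Bray–Curtis, and the UniFrac
family — whose underlying variants cannot be written down.

## Test construction

Per input kernel h:

1. **Null model.** y = α₁₀ + T α₂₀ + Z α₃₀ (+ ε) fitted by OLS (gaussian) or
   ML logistic regression (binomial); response residuals r = y − ŷ₀ for both
   families.
2. **Endogenous kernels.** K^M = X\*X\*ᵀ, K^I = (X\*⊙T)(X\*⊙T)ᵀ,
   K^B = K^M + K^I (the gram matrix of the concatenation (X\* | X\*⊙T)).
3. **Score statistics.** T^M = rᵀK^M r, T^I = rᵀK^I r, T^B = rᵀK^B r —
   variance-component score statistics estimating β₁\*ᵀβ₁\*, β₂\*ᵀβ₂\* and
   their sum without fitting the effects.
4. **Permutation null.** One plan of R rearrangements of r is drawn per
   analysis and shared by *every* statistic (all targets, all kernels); each
   p-value is P = (1/R) Σ_r 1[T(r) ≥ T_obs], with no +1 continuity
   correction, so the resolution is 1/R and p = 0 is attainable.
5. **Per-kernel min-P.** T_h = min(P^M, P^I, P^B) is recalibrated against its
   own permutation null: each rearrangement's statistics are converted to
   leave-one-out p-values over the other R−1 rearrangements, the three are
   minimized per rearrangement, and P_h = (1/R) Σ 1[T_h(r′) ≤ T_h].

Across kernels (**OmniK**), the same recipe is applied twice more: per target
e ∈ {M, I, B}, the observed statistic is min_h P^e_(h) with null values
min_h of the leave-one-out p-values, giving P^e_OmniK; then
T_OmniK = min(P^M_OmniK, P^I_OmniK, P^B_OmniK) is recalibrated against the
leave-one-out ranks of the level-one null minima. No second permutation pass
is ever needed — all levels reuse the cached null arrays. The second level is
implemented as a rank transform of the level-one null minima: ranking keeps
the observed and null quantities on the same (calibrated-p) scale, which is
what makes the final p-value uniform under the null; taking raw nested minima
instead would compare a min of 3 calibrated p-values against a min of 3|Γ|
raw ones and is visibly miscalibrated.

### Numerical conventions

- Ties in the permutation counts follow the definitions (≥ for statistics,
  ≤ for minima). Score statistics are snapped to a relative ~1e-12 grid
  (scale rounded to a power of two) before rank comparisons so that
  mathematically tied rearrangements — e.g. the identity rearrangement vs the
  observed statistic — count as ties regardless of floating-point summation
  order. The grid is ~10⁴ times finer than any statistical resolution.
- Surrogate extraction drops eigenvalues ≤ 1e-10 · λ_max ("exactly zero" up
  to floating point); column signs are fixed (largest-magnitude entry
  positive) for determinism. Downstream gram matrices are invariant to sign.
- The treatment enters the Hadamard product untransformed (no centering), so
  with T ∈ {0,1} the interaction kernel is supported on treated pairs. This
  follows the reformulated model literally; whether T should be centered for
  unbalanced designs is left open.
- Binomial residuals are response residuals y − p̂ permuted directly — one
  recipe for both families. For binary responses this is known to make the
  interaction component conservative (rejection ≈ 2–3% at nominal 5%), which
  the type-I study reproduces; it is expected behavior, not a defect. Raw
  residuals are permuted (not a covariate-preserving scheme such as
  Freedman–Lane), which is a validity caveat for observational designs.
- Quadratic forms over all rearrangements are computed as stacked matrix
  products on the permuted-residual matrix, O(R·n·df) per kernel target.

## Ecological kernels

Counts are converted to per-sample proportions before Bray–Curtis and all
UniFrac weights (no rarefaction); presence means count > 0 exactly. The
UniFrac family is computed from one taxa-by-edge incidence pass over the
tree: unweighted = unique/observed branch length; generalized (Chen et al.
branch weights (p_A + p_B)^α, α ∈ [0,1]) ; weighted = the normalized variant,
identical to generalized at α = 1 (asserted to 1e-10 and cross-checked
against scikit-bio's implementation). A distance matrix becomes a kernel by
Gower double centering of the element-wise squared distances,
K = −½ (I − 11′/n) Δ² (I − 11′/n); negative eigenvalues (Jaccard and
Bray–Curtis are semimetrics, not Euclidean-embeddable) are clipped to zero
and the clip recorded. The default kernel set Γ holds the seven candidates:
Jaccard, Bray–Curtis, unweighted UniFrac, generalized UniFrac (0.25, 0.5,
0.75) and weighted UniFrac.

## Naive combiners (comparison methods)

Fisher (−2 Σ ln p vs χ²(2m)), Simes (min_k m·p_(k)/k) and Brown (Fisher's
statistic vs a scaled χ² moment-matched with the covariance of −2 ln p
estimated empirically from the permutation-null p-value matrix) are provided
as the comparison omnibus methods. They combine each kernel's min-P statistic
T_h across the |Γ| kernels — treating an un-recalibrated minimum of three
p-values as if it were a p-value, which is exactly the naive-combination
error the comparison illustrates: Fisher and Simes inflate the family-wise
error well above 5%, Brown's dependence adjustment removes most but not all
of the inflation (its moment matching still assumes uniform marginals).
P-values of exactly 0 (below permutation resolution) are replaced by 1/R
with a warning before log transforms.

## Synthetic data generator

The generator emulates the structure of a 16S microbiome association study:

- **Counts.** Dirichlet-multinomial with mean proportions π, overdispersion
  θ (θ = 1/(1+Σγ); θ → 0 recovers the multinomial), total 10 000 reads per
  sample. Defaults: p = 100 taxa, π a descending-sorted flat Dirichlet draw
  (a few dominant taxa, a long rare tail), θ = 0.02 — chosen once as a
  realistic upper-respiratory/gut-like composition; the harness also accepts
  parameters estimated from a real table by the classic weighted
  method-of-moments estimator.
- **Tree.** A random coalescent-style bifurcating tree over the p taxa with
  positive branch lengths, fixed once per experiment.
- **Affected taxa.** One of five PAM (k-medoids, BUILD+SWAP, deterministic
  lowest-index tie-breaking) clusters of the leaf cophenetic distance matrix,
  so effects are phylogenetically coherent. Clusters are labeled P1..P5 by
  ascending medoid position.
- **Covariates/treatment/response.** z₁ ~ Bern(0.5); z₂ = 0.5 · (row mean of
  the standardized proportions of a random 10% taxon subset) + N(0,1) — the
  row mean resolves the otherwise ill-typed "matrix × scalar" coupling;
  T ~ Bern(0.5) (randomized) or Bern(expit(0.5(z₁ˢ + z₂ˢ))) with standardized
  covariates (observational; standardization fixes the arbitrary z₂ scale).
  Responses follow the model above with α₁ = 0, α₂ = 1, α₃ = 0.5, ε ~ N(0,1);
  f standardizes the affected taxa's proportions (linear signal) or takes
  presence indicators (discrete nonlinear signal). Effect sizes: main-only
  β₁ = 2; interaction-only β₂ = 1 (continuous) / 3 (binary); both:
  β₁ = 2, β₂ = −1 (continuous) / β₁ = −1.5, β₂ = 3 (binary), with the
  cluster split in half — first half main, second half interaction.

What the generator does **not** emulate: real phylogenetic signal in the
composition (taxa are exchangeable given π), sequencing-depth variation,
zero inflation beyond the DM's own, or taxon-taxon ecological interactions.
Calibration results transfer to real data because the permutation test's
validity is distribution-free under exchangeability of residuals; power
magnitudes and the exact inflation of the naive combiners do depend on the
composition and on how correlated the seven kernels are, and differ between
generators (they differ between the two real datasets' parameter sets too).

## Study sizes and defaults in the shipped experiments

Type-I studies: 1000 null replicates (tests) / 2000 at n=100 and 1000 at
n=200 (acceptance script), R = 1000 rearrangements, seven kernels, both
response families sharing each replicate's counts and kernels. Power
studies: 300 replicates, R = 500, n = 100. Power comparisons use cluster P3
(the largest cluster of the default generator's tree): pilot runs showed
the reference effect sizes saturate power for several clusters, and P3
keeps the component comparisons informative; per-cluster power is known to
be unpredictable, so only orderings — never per-cluster values — are
asserted. Tolerances on empirical rates are three binomial standard errors
at the study's replicate count.

## Limitations

- Permutation p-values only; no asymptotic (Davies / mixture-of-χ²)
  approximations, so resolution is 1/R and very small p-values need large R.
- No estimation of effect sizes β₁\*, β₂\*; the framework tests, it does not
  estimate.
- Variant-by-variant interactions are out of scope.
- Binary-response interaction tests are conservative (see above).
- BIOM support covers the common v1 (JSON) and v2 (HDF5) table layouts with
  a deliberately minimal reader.
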