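# Methods

This note documents the statistical models behind `oryzaqg`, the choices
made where the methodology was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Phenotypic selection analysis

Selection is measured at the individual level: each plant record in one
varietal-group panel × environment is one observation.  The analysis
order is fixed and matters: individuals with zero fecundity (no filled
grains) are removed **first**, relative fitness w′ = w/mean(w) is computed
over the survivors, and traits are then standardized (mean 0, SD 1, with
the n−1 sample-SD denominator) over that same post-filter population.

Selection differentials come from univariate linear mixed models
`w′ ~ z + (1|block)`; quadratic differentials add a `z²` term.  The mixed
model is fit by REML, profiling the likelihood over the variance ratio
λ = σ²_block/σ²_e and optimizing the one-dimensional criterion on the log
scale (bounded Brent, tolerance 1e−8).  When λ hits the zero boundary the
fit reduces exactly to OLS, which the tests assert.  p-values use t
references with n − p residual degrees of freedom.

Linear gradients β are reported from the **joint** mixed regression of w′
on all standardized traits; the point estimates coincide with β = P⁻¹S
(P the covariance matrix of the standardized traits) — an algebraic
identity in the no-random-effect case that is tested to 1e−8 — while the
joint fit supplies SEs and p-values directly.  The P⁻¹S route is retained
as a cross-check (`gradients_from_differentials`).

Quadratic gradients γ = P⁻¹CP⁻¹ use a diagonal C by default (one
quadratic mixed model per trait); correlational (bilinear) terms are
opt-in via `cross_terms`.  The convention of doubling the fitted quadratic
coefficient (so the diagonal estimates the surface curvature rather than
the regression coefficient) is a flag, `double_diagonal`, **off** by
default; both conventions are exercised in the tests.

For the binary flowering-success component, logistic regression (blocks
as fixed covariates) yields slopes α that are mapped to the
selection-gradient scale with the average-gradient transformation
β = α · mean[W(1−W)]/mean(W), W being the fitted success probabilities.
Complete separation is flagged and the p-value set missing.  Gradients
for total fitness over the two multiplicative components are the sums of
the per-component β, with SEs **summed** (not added in quadrature); that
summation rule is deliberate and recorded in the output metadata.

## Kinship, REML and the G-matrix

The genomic relationship matrix is VanRaden's K = WWᵀ/(2Σpᵢ(1−pᵢ)) with
dosages column-centered by 2pᵢ; monomorphic markers are excluded.  Before
GRM construction the marker set is thinned to one randomly chosen SNP per
non-overlapping 1000-bp bin (bins anchored at position 1), seeded for
reproducibility.

Variance components of y = Xb + u + e, u ~ (0, σ²_g K), e ~ (0, σ²_e I)
are estimated by spectral REML: with K = UDUᵀ, the rotated model is
diagonal and the REML criterion is profiled over δ = σ²_e/σ²_g, searched
on a 64-point log₁₀ grid over [−8, 8] and refined locally.  Ratios
outside that range are indistinguishable from the boundaries at panel
sizes of a few hundred; boundary solutions are clamped so pseudo-h² =
1/(1+δ) always lies in [0, 1].  A full-matrix (naive V⁻¹) likelihood
implementation exists purely as a validation oracle and agrees with the
spectral path to 1e−8.

**Kinship scaling.**  Inside the REML engine K is rescaled to unit mean
diagonal.  Fully inbred panels have VanRaden diagonals near 2, and
without rescaling σ²_g/(σ²_g+σ²_e) would understate the fraction of
phenotypic variance tagged by the markers by roughly a factor of two.
With the rescaling, pseudo-h² is directly interpretable as that fraction,
and planted heritabilities are recovered unbiasedly in simulation.  The
GRM itself is reported unscaled.

Genetic covariance between standardized traits uses the
variance-of-the-sum identity cov_g = [V_g(y₁+y₂) − V_g(y₁) − V_g(y₂)]/2
with V_g(y) = h²(y)·var(y), which needs only the univariate engine, makes
cov_g(y, y) = h²(y) exact, and on the standardized scale returns
co-heritabilities — so the assembled G-matrix carries pseudo-h² on the
diagonal and co-heritabilities off it.  Significance of each covariance
is a 1-df likelihood-ratio test comparing bivariate ML fits (Cholesky
parameterization, Nelder–Mead over 5–6 parameters in the spectral basis)
with free vs zero genetic covariance.  Traits unmeasured in an
environment are masked — excluded from the matrix — never zero-filled.

## Breeder's equation and constraint detection

Δz = Gβ is decomposed as direct_i = G_ii·β_i and
indirect_i = Σ_{j≠i} G_ij·β_j, with direct + indirect = total exact by
construction.  A trait is flagged as evolutionarily constrained when the
direct and indirect components have opposite signs **and** |indirect|
exceeds SE(β_i) — the SE itself, not a multiple of it.  Zero components
never flag.  Reconstructing all four shipped panels (both varietal groups
× both environments) from the 3-decimal printed inputs reproduces every
direct/indirect/total cell within ±0.005, the rounding of the inputs.

## Association scans

The GWAS tests each marker inside the kinship mixed model with the top
four dosage principal components as fixed covariates.  Null-model
variance components are estimated once and reused across markers (the
population-parameters-previously-determined approximation), which makes a
4×10⁵-marker scan tractable on a desktop; per-marker statistics are then
closed-form GLS regressions in the spectral basis.  Null scans on
structured synthetic panels give uniform p-values (KS-tested).  The
forward-only stepwise mode adds the most significant marker as a cofactor
and rescans, up to a configured cap; a backward pass is deliberately out
of scope since the quantities this package validates (thresholds, null
calibration, planted-QTL detection) do not require it.

Multiple-testing thresholds: Bonferroni α/n_loci, and SimpleM α/Meff,
where Meff sums, over per-chromosome windows of 1000 markers, the
smallest k whose top-k eigenvalues of the marker correlation matrix reach
C = 0.995 of the total variance.  C and the window size are configurable;
0.995 is the conventional default.  Candidate genes are those whose
1-based inclusive span intersects ±50 kbp around a peak (window clipped
at position 1) — chosen conservatively relative to LD decay ranges of
75–125 kbp in Indica rice.

Transcript–trait scans are simple per-transcript regressions (p-values
identical to correlation tests); significance uses the relaxed rule
p < 10 × (α/n_transcripts), i.e. within an order of magnitude of
Bonferroni.  TGW is excluded by default (a harvest trait; transcripts are
sampled at the vegetative stage).  Overlap sets between traits are
reported for all pairs and triples.

## Genomic prediction

gBLUP solves û = σ²_g K V⁻¹(y − Xb̂), V = σ²_g K + σ²_e I, after REML;
PEVs come from the prediction covariance σ²_g K − σ²_g K P σ²_g K with P
the fixed-effect-adjusted projection of V⁻¹, and reliability is
1 − PEV/(σ²_g K_ii).  At h² = 0 all BLUPs are zero; as h² → 1 they
approach the centered phenotypes.  Cross-environment stability ranks each
environment's BLUPs descending (best fitness = rank 1, ties averaged —
the tie rule is unstated in the source convention, averaging is this
package's choice) and sums them; the lowest cumulative rank is the most
stable high-fitness accession.

## Synthetic-data generator

Genotypes: ancestral allele frequencies ~ U(0.05, 0.95); two (by default)
subpopulations at F_ST = 0.1 under the Balding–Nichols Beta model — the
simplest model that produces realistic PCA clusters and kinship block
structure; accessions are fully inbred (dosage 0/2) with optional
residual heterozygosity.  Phenotypes: breeding values drawn with
covariance K ⊗ G via Cholesky factors, replicate records adding
incomplete-block effects (block SD 0.5) and residual noise scaled so the
planted h² is what the *accession-mean* (LS-mean) pipeline recovers —
pseudo-h², not replicate-level h², being the estimated quantity.
Fecundity uses a log-link count surface exp(1 + zβ + ½zᵀγz + ε) scaled to
a mean of 1200 filled grains (a realistic per-plant figure for irrigated
rice), zeroed for plants failing to flower; flowering success is
Bernoulli-logistic with baseline success ≈ 90%.  The default desk layout
is 10 blocks × 10 plots × 3 replicates for ~100 accessions; the
field-scale preset uses 22 × 10 × 3 for 216.

What the generator does **not** emulate: linkage disequilibrium beyond
subpopulation structure (positions are exchangeable within chromosomes),
genotyping error and missingness patterns, environment-specific G×E
beyond separate draws per environment, non-Gaussian trait distributions,
and spatial field gradients beyond block effects.  Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
models, not robustness to those real-data features.

## Numerical choices and problem sizes

Tolerances: REML 1-D optimization xatol 1e−8; symmetry checks 1e−10;
oracle equivalences asserted at 1e−4 (grid vs optimizer), 1e−8 (spectral
vs naive REML; P⁻¹S vs regression) and 1e−12 (GRM formula).  Stochastic
calibration tests run at desk scale — panels of 100–250 accessions,
300–5000 SNPs, 50–100 replicates — sizes at which every recovery
criterion is comfortably resolved while the whole suite runs in about two
minutes.  Degenerate inputs are handled explicitly: constant traits pass
through LS means unchanged, constant fitness yields zero differentials,
monomorphic markers get missing GWAS p-values, rank-deficient designs
fall back to arithmetic means with a warning, and empty panels raise.

## Known limitations

- The genetic-covariance LRT uses ML (not REML) in the bivariate fits;
  with a single fixed intercept the difference is negligible at these
  panel sizes.
- The SimpleM Meff depends on the windowing scheme; published effective
  test counts can be supplied directly when reproducing threshold
  arithmetic.
- The stepwise GWAS has no backward elimination and no information-
  criterion stopping rule beyond the cofactor cap.
- Accession-level analyses assume the LS means are estimated without
  error; no weighting by LS-mean precision is performed.
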