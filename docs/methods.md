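# Methods

## Genotype handling and quality control

Genotypes are A1-allele dose codes in {0, 1, 2} with an explicit missing
mask, read from and written to PLINK 1 SNP-major binary triplets (the 2-bit
encoding with 01 = missing; individual-major files are rejected).  Allele
frequencies are estimated per marker from the non-missing calls of the
current sample.

QC applies, in order: individual missingness (> 10% removed), SNP call rate
(< 95% removed), minor allele frequency (< 1% removed), Hardy-Weinberg exact
test (p < 1e-6 removed), and autosome restriction.  The order matters for
borderline counts (an individual removed early changes downstream call rates
and frequencies), so it is fixed, configurable, and every removal is counted
against the first stage that triggers it.  The Hardy-Weinberg test is the
exact conditional test on the heterozygote count given the allele counts —
the same test PLINK uses by default — computed in log space and verified in
the test suite against exact-integer enumeration for all sample sizes up to
40.  Monomorphic markers get p = 1 by convention (the MAF filter handles
them).  Residual missing genotypes are mean-imputed (`2pᵢ`), which leaves the
centred additive design at zero for imputed cells; the dominance coding
assigns missing cells their Hardy-Weinberg expectation, zero.

Frequencies are frozen once, after QC, and reused for both design matrices
and both denominators.  `pᵢ` is the frequency of the counted (A1) allele, not
forced to the minor side: both matrices are invariant to allele relabelling
(an allele swap flips the sign of a `W₁` column and permutes the dominance
codes symmetrically), which the suite checks property-wise.

## Relationship matrices

`G = W₁W₁ᵀ / 2Σpq` and `D = W₂W₂ᵀ / 4Σp²q²`, accumulated in marker blocks so
the full n×m design never needs to be resident (block size changes results
only at float-reassociation level, asserted at 1e-10).  Both codings have
zero mean under Hardy-Weinberg proportions, so in an unrelated HWE population
the expected diagonal of either matrix is 1 and the expected off-diagonal 0;
paternal half-sibs average 0.25 in G.  These calibrations are recomputed by
the acceptance script.  A ridge (default 1e-6) is added to each diagonal
before model fitting because in desk-scale data n can exceed the effective
marker rank; the applied ridge is carried in the matrix metadata and reports.
Matrices can be exported as dense delimited text (header row of IDs) or as
GCTA binary GRM triplets (float32 lower triangle + `.grm.id`).

One caveat the half-sib driver output illustrates: with frequencies estimated
from the sample itself, `W₁` columns sum to zero, so relationship estimates
are centred within the sample — with few families, between-family values go
slightly negative and within-family values land slightly below the pedigree
expectation.  This is a property of the estimator, not an error.

## REML

The restricted log-likelihood is
`ℓ(θ) = −½[log|V| + log|XᵀV⁻¹X| + yᵀPy + (n−p) log 2π]` with
`V = Σₖ θₖKₖ + θₑI` and `P = V⁻¹ − V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹`.  Optimisation uses
average-information (AI) updates: score `−½[tr(PKₖ) − yᵀPKₖPy]`, AI matrix
`½ yᵀPKᵢPKⱼPy`.  When a Newton step proposes a negative component, that
component is sent to the boundary region and the step re-solved for the
remaining ones; if the step still fails to improve the likelihood after
step-halving, an EM-REML update (`θₖ ← θₖ + θₖ²[yᵀPKₖPy − tr(PKₖ)]/n`) is
taken instead, which is ascent-guaranteed.  A genetic component that falls
below 1e-6 × the phenotypic variance while its score points outward is pinned
to exactly 0 and removed from the active set, and is reported as 0 with a
standard error taken from the unconstrained AI matrix at the final parameters
(so boundary estimates still carry an uncertainty statement).

Starting values put half the OLS residual variance on the residual and split
the other half equally across genetic terms.  Convergence requires both a
log-likelihood change below 1e-8 and a maximum relative component change
below 1e-6, within 200 iterations; non-convergence is reported on the fit
(with the full iteration trace), never raised.

Fixed effects use an intercept plus treatment coding with the
lexicographically first level as reference; a single-level factor contributes
no columns (warned).  BLUPs are `ûₖ = θₖKₖPy`, which solve Henderson's
mixed-model equations at the final components — asserted in the tests by
plugging the solutions back into the explicitly assembled MME.

Standard errors of variance ratios (h², d²) use the delta method on the
inverse AI matrix.  Confidence intervals for the components themselves are
asymmetric: lower bound `max(0, θ − z·se)` (Wald truncated at the boundary,
since variance components are non-negative), upper bound `θ·exp(z·se/θ)`
(log-scale Wald, the usual construction for right-skewed positive
parameters).  Symmetric Wald intervals measurably undercover here — 82–86%
empirical coverage at the study design even though the AI standard errors
match the numerical observed information — while the asymmetric interval
attains 92–100% across the recovery scenarios the acceptance suite runs.

Verification is two-route throughout: the restricted likelihood against a
naive dense-inverse implementation on small instances (1e-8); AI against pure
EM iteration on the same data; and the whole fit against statsmodels'
MixedLM on random-intercept problems, where a block kinship `ZZᵀ` makes the
two parameterisations identical (agreement at the reference optimiser's own
precision: log-likelihood 1e-6, components ~1e-3 relative).  A literal
identity kinship with one record per animal is *not* used as an oracle: `V =
(σ²ₐ+σ²ₑ)I` leaves the two components unidentifiable.

## Cross-validation

Individuals are partitioned uniformly at random into k folds whose sizes
differ by at most one (498 animals, k = 5 → 100/100/100/99/99), with a fresh
partition per repeat; k = 5 with 2 repeats gives the 10 accuracy values per
trait × model whose mean and standard error are reported.  For each fold,
variance components and fixed effects are re-estimated from the training
records only; kinship matrices are built once on all animals, and predictions
flow to the validation fold through the cross blocks, `û = σ̂²ₐ K[:,train]
P_t y_t`.  A fixed-effect level unobserved in training is merged into the
reference with a warning.

Accuracy is the Pearson correlation between the predicted breeding value and
the validation phenotype adjusted by the training-fold fixed-effect estimates
(`y − Xb̂`).  This is the most common definition in GBLUP cross-validation
and is the default; correlation with the raw phenotype and division by √h²
are available behind the `method` flag, and for the dominance model the total
genetic value `û + v̂` is scored alongside the breeding value.  A fold whose
predictions are constant (e.g. the additive component pinned at zero under a
null trait) has undefined accuracy; it is recorded as missing and the summary
covers the remaining folds.

## Synthetic populations

The generator emulates a single-generation half-sib design: founder sires and
dams drawn from Hardy-Weinberg proportions at frequencies uniform on
[maf_min, 0.5] (default maf_min = 0.05), offspring formed by independent
Mendelian transmission at unlinked loci, herds and sexes assigned at random.
Defaults mirror the study population: 498 offspring of 26 sires, 7 herds,
59% males, a 10% full-sib fraction (created by letting some dams bear two
offspring of the same sire), and a desk-scale panel of 5,000 markers.

Phenotypes come from the generative counterpart of the fitted model: marker
effects `aᵢ ~ N(0, σ²ₐ/2Σpq)` and `dᵢ ~ N(0, σ²_d/4Σp²q²)` use the same
codings and denominators as the relationship matrices, so `Var(u) = σ²ₐG`
exactly and the scenario variances are the estimands of the REML fit — this
makes parameter recovery a sharp test rather than an approximation.  Default
trait settings are a staple-length-like trait (σ²ₐ = 40, σ²ₑ = 40, h² = 0.5)
with sex and herd effects of about half a phenotypic SD; the dominance
scenario (σ²ₐ = 0, σ²_d = 22.29, σ²ₑ = 8.07) mirrors a fleece-extension-like
architecture with d² = 0.73.

What the generator does **not** emulate: linkage and LD (loci are unlinked,
which makes analytic expectations exact but removes the LD structure real
SNP panels have), maternal structure beyond the full-sib device (dams are
otherwise unrelated and ungenotyped), selection, genotyping error, and
multi-generation pedigrees.  Passing tests therefore demonstrate correctness
of the estimators under the stated model, not robustness to LD or population
stratification.

## Problem sizes and numerical choices

Recovery checks run 50 replicates at the study design (n = 498, m = 5,000),
where one MAG fit takes well under a second and one MADG fit a few seconds at
worst; the cross-validation checks run 5×2 folds on the same design.  Unit
tests use smaller populations (60–300 animals, a few hundred markers).
Degenerate inputs are handled explicitly: fixed markers are rejected by the
design builders (the MAF filter removes them in practice), all-missing
markers get undefined frequency and fail call-rate QC, zero-variance accuracy
is missing-with-warning, and an empty post-QC panel raises rather than
returning an empty matrix.
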