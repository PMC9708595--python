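# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `gsconverge`, in the spirit of the methods documentation
of packages like statsmodels or msprime: what is computed, under which
assumptions, and what the tests do and do not establish.

## Gene-set construction

* **PI (constraint) set.** Genes with pLI strictly greater than the
  threshold (default 0.9). The inequality is strict: a gene at exactly 0.9
  is excluded.
* **Cell-type sets.** For each cell type, genes below `min_expr` (default
  0.1) in that type are excluded ("sporadic"/low-expression filter), the
  rest are ranked by specificity — expression in the type divided by the
  mean over all types plus a pseudocount (default 0.01) — and the top
  `top_n` (default 1600) are kept. Ties break lexicographically by gene id
  so output is reproducible. In strict mode fewer than `top_n` qualifying
  genes is an error; lenient mode returns all qualifying genes with a
  warning. The ranking statistic for "differentially expressed" is a
  package choice (mean-ratio specificity); it is configurable and recorded
  with the output rather than asserted as the only defensible definition.
* **Mouse translation.** Mouse sets are built on the mouse expression
  matrix, then mapped to human ids. A mouse gene with more than one human
  target is dropped (prevents set inflation); unmapped genes are dropped;
  convergent targets are collapsed. Dropped counts are logged.
* **Synaptic sets.** Ontology sets are retained when they hold at least
  `min_synaptic` genes (default 50, inclusive).
* **Intersections.** One set per brain cell set: members in both the cell
  set and PI, named `<cell>_x_PI`. Empty intersections are retained and
  flagged; downstream tests skip sets below `min_set_genes` (default 10)
  with an explicit `skipped_small` status rather than silent omission.
* **Backgrounds.** Brain-expressed genes (expression ≥ `min_expr` in ≥ 1
  cell type) and the top 50/20/10% of them by overall mean expression.
  These condition the analyses and are never counted as analysed sets.

With 14 human + 24 mouse cell types, 35 surviving synaptic sets, and one
intersection per cell set, the analysed inventory is 112 sets.

## Common-variant arm

**QC.** All copies of a duplicated SNP id are removed (the conservative
reading of "duplicates excluded"; keeping one copy is the alternative and
is flagged for real-data users). SNPs with INFO < 0.8 are removed; the
comparison is strict, INFO = 0.8 is kept.

**Gene statistic.** SNPs map to genes by 1-based closed-interval position
with no window. Per SNP, χ² = [Φ⁻¹(p/2)]² (two-sided inversion); the gene
statistic is T = Σχ². Under the null, z-scores within a gene are MVN(0, R),
so T ~ Σᵢ λᵢ χ²₁ with λᵢ the eigenvalues of R. The tail probability is
computed by Imhof's inversion integral

    P(T > t) = 1/2 + (1/π) ∫₀^∞ sin θ(u) / (u ρ(u)) du,

evaluated with composite Gauss–Legendre panels sized to the oscillation
phase plus a first-order integration-by-parts correction for the truncated
tail (absolute accuracy ~1e-9 across the tested regimes). Two regimes are
delegated: equal eigenvalues (R = I up to scale) use the exact scaled-χ²ₖ
tail, and p below ~1e-8 — where the ½ + integral form loses all relative
precision to cancellation — falls back to a three-cumulant χ² match
(Satterthwaite-type, ν = c₂³/c₃²). The method used is recorded per gene.
Gene p-values are clamped to [1e-300, 1 − 1e-16] and the probit z to
|z| ≤ 37, the double-precision limit.

**Competitive test.** OLS of gene z on the set-membership indicator, an
intercept, and gene-level covariates (gene length, SNP count and their
logs; constant covariates are absorbed by the intercept). The reported p is
one-sided for β > 0, the usual convention for enrichment; two-sided is
available by flag. Conditional analyses add conditioning-set indicators as
covariates; a conditioning set identical to the focal membership raises an
explicit collinearity error.

**Inference model.** OLS standard errors are valid here because the
synthetic design places one independent LD block per gene, making gene
z-scores independent. Real data have correlated neighbouring genes; for
that use the set test accepts a user-supplied gene correlation structure
only insofar as the user pre-whitens z — a full GLS path was considered and
deferred (limitation, see below).

## Rare-variant arm

**Classes.** Allele frequency uses the combined denominator
AC/(2·`panel_total_n`), with `panel_total_n` the cohort plus reference
panels (default 188,023 individuals). Flags: singleton ⇔ AC = 1 (the
ultra-rare class); rare ⇔ AF < 0.1% and AC ≥ 1; rare-excluding-singletons ⇔
AF < 0.1% and AC ≥ 2. Each crosses with consequence (PTV, synonymous). The
AF denominator choice (combined vs cohort-only) is configurable; combined
is the default and is logged.

**Sample QC.** Per frequency class, individuals more than k = 4 unscaled
median absolute deviations from the cohort median synonymous count of that
class are excluded ("more than" is strict). The MAD carries no 1.4826
normal-consistency factor. Edge case, documented: if MAD = 0 (more than
half the cohort shares one count), any nonzero deviation excludes.

**Burden regression.** The burden score is a per-individual count of
qualifying alleles (not a carrier indicator). Logistic regression of case
status on burden + sex + PC1..10 (+ the exome-wide qualifying count of the
same class when enabled); β is the per-allele log-odds with a two-sided
Wald p. The exome-wide covariate is class-matched by default (pooling
classes is the configurable alternative). On separation or non-convergence
the fit falls back to Firth's Jeffreys-penalized likelihood and the row is
flagged `firth`. Conditional fits add other sets' burden scores; an
all-zero conditioning score is dropped with a warning, exact collinearity
is an explicit error. Intersection and PI burdens in one model share
variants by construction; this is inherent to the design and surfaces as
inflated conditional variances.

## FDR and convergence

Benjamini–Hochberg at q = 0.05 runs within each variant-frequency family,
across all 112 analysed sets (synaptic included), on the unconditioned
rows; failed/skipped sets carry NaN p-values and neither reject nor count
toward the family size. Convergence between two arms is the correlation of
per-set betas: Pearson and Spearman are both reported (the field's usage
slides between "rank correlation" and plain correlation, so the output
carries both rather than resolving the ambiguity silently), plus weighted
Pearson with weights wᵢ = 1/(SE_a,ᵢ·SE_b,ᵢ), normalized to sum to one —
the estimate is invariant to weight rescaling, so normalized vs raw inverse
products is immaterial. Weighted Spearman has no canonical form and is not
offered. Overlap sets are those BH-significant in both arms.

## Synthetic data: what it emulates, and what it does not

The generator produces *structure*, not realism. All randomness flows from
one seed through per-stage child streams, so identical configurations are
bit-identical.

* **Gene table.** Non-overlapping intervals on 22 synthetic chromosomes;
  lengths log-normal (median ~11 kb). pLI from a two-component Beta mixture
  (Beta(0.5, 8) for tolerant, Beta(8, 0.5) for constrained, mixing weight
  0.15) — bimodal like real constraint scores, with ~13% of genes above
  0.9, near the real fraction (3063 of ~20k).
* **GWAS.** One AR(1) LD block per gene (default 8 SNPs, ρ = 0.7,
  N = 105,318). Per-SNP effects b ~ N(0, τ²) with τ² = 5e-6 in planted
  sets vs 1e-6 elsewhere (mean per-SNP χ² ≈ 1.5 vs 1.1 at this N — a
  polygenic scale); observed z ~ MVN(Rb√N, R). Optional injection of
  duplicate SNPs and low-INFO records exercises QC.
* **Exome cohort.** Qualifying PTV and synonymous allele counts per gene
  and individual are Poisson (defaults give ~1.2 PTVs and ~6 synonymous
  qualifying alleles exome-wide per individual, study-like levels). Disease
  is a *prospective* logistic model: logit P(case) = α + 0.3·(causal-set
  PTV count, centred) + small sex/PC1 effects, so the planted per-allele
  log-odds is exactly the estimand of the burden regression — this is what
  makes exact parameter-recovery tests possible (a liability-threshold
  model would plant a different estimand). Synonymous variants never enter
  the predictor, making them null by construction. Reference-panel allele
  counts are Poisson with half the variants forced to AC_ref = 0 so true
  singletons exist.
* **Not emulated:** real allele-frequency spectra, real LD maps, gnomAD's
  pLI calibration, population substructure, relatedness, variant-level
  annotation error. Passing tests therefore establish the *statistical
  machinery* (calibration, recovery, conditioning, FDR, convergence
  algebra) — they are not evidence about any real cohort.

## Problem sizes used in the shipped runs

The analysis scripts and the acceptance script run the full 112-set
inventory at 12,000 genes, 96,000 SNPs and 8,000 exome individuals;
calibration uses 1,000 null replicates of 1,000 genes; burden recovery uses
2,000 genes at 4,000 cases / 4,000 controls with rates scaled to hold
per-individual exome-wide counts at the levels above; Monte-Carlo checks of
the gene-statistic tail use 10⁶ draws. These sizes were chosen to give each
check clear statistical margins while keeping a complete run in minutes on
one core.

## Known limitations

* The competitive test's OLS inference assumes independent genes; correct
  for the synthetic design, approximate for real data with inter-gene LD.
* Firth penalization is the only separation fallback; exact conditional
  logistic regression is not offered.
* The specificity ranking and the "sporadic gene" filter are package
  definitions of under-specified field conventions; both are configurable.
* Deep-tail gene p-values (< 1e-8) come from the three-moment
  approximation, accurate enough for ranking and probit transformation but
  not for extreme-tail inference per se.
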