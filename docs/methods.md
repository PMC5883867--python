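# Methods

## The model

All prediction in this package is genomic BLUP:

    y = W α + u + e,    u ~ N(0, G σ²_g),    e ~ N(0, I σ²_e)

with `y` the per-dog mean of the left and right Norberg-angle scores (an
ordinal 0–6 variable treated as continuous, the standard practice for this
trait), `W` a fixed-effect design holding the intercept, sex and origin
(origin is dropped automatically when a training set contains a single
origin, where it would alias the intercept), and `G` the VanRaden Method 1
genomic relationship matrix

    G = Z Z′ / (2 Σᵢ pᵢ(1 − pᵢ)),   Z = dosage − 2pᵢ,

with allele frequencies `pᵢ` computed once on the full joint cohort and a
ridge of 0.01 added to the diagonal so that every training block is
invertible.  Missing dosages are mean-imputed only inside the GRM (the raw
matrix keeps its missing values).

### AI-REML

Variance components maximise the restricted likelihood.  The training block
of `G` is eigendecomposed once, `G = U D U′`; rotating `y` and `W` by `U′`
makes `V = σ²_g G + σ²_e I` diagonal, so an iteration costs `O(n k²)`.
Updates use the average-information matrix
`AI_ij = ½ y′ P V_i P V_j P y` with these safeguards, none of which change
the optimum:

* an AI proposal with a negative component is replaced by one EM step
  `σ²ᵢ ← σ²ᵢ + σ⁴ᵢ (y′PVᵢPy − tr(PVᵢ))/n`;
* any step that would lower the restricted likelihood is halved (up to 30
  times), so the likelihood trace is non-decreasing;
* components are floored at `10⁻⁸ · var(y)`;
* when `y` lies in the column span of `W` (no residual variance at all) the
  fit returns immediately at the floor with the boundary flag set.

Convergence is declared when the normalised components
`θ = (σ²_g, σ²_e)/(σ²_g + σ²_e)` change by less than `10⁻⁵` in maximum
absolute difference.  Normalising by the component sum is our reading of
"normalised variance components"; the convergence decision is insensitive to
the scale convention because the tolerance applies to a ratio.

The inverse of the final AI matrix estimates the sampling covariance of
`(σ̂²_g, σ̂²_e)`.  Heritability is `h² = σ²_g/(σ²_g + σ²_e)` with the
delta-method standard error using `∂h²/∂σ²_g = σ²_e/(σ²_g+σ²_e)²` and
`∂h²/∂σ²_e = −σ²_g/(σ²_g+σ²_e)²`.  On small or genetically thin training
sets the AI matrix can be near-singular (flat likelihood); the results object
carries a boundary/identifiability flag (AI condition number above 10⁸, or a
component at the floor).

### Prediction

Unphenotyped individuals are predicted by the conditional-expectation form

    û_val = G[val, train] · G[train, train]⁻¹ · û_train,

plus the fixed-effect part for their covariates.  This is algebraically
identical to solving Henderson's equations with the validation records
missing; the equivalence (and the SNP-BLUP/ridge-regression duality at
matched shrinkage `λ = c σ²_e/σ²_g`) are asserted in the test suite rather
than exposed as alternative code paths.

## Cross-validation designs

Folds are drawn uniformly at random *within origin* and cut into k
near-equal blocks, larger blocks first (1,179 ids give 236/236/236/236/235;
242 give 49/49/48/48/48).  Training sets per scheme: `joint` (both origins'
non-validation folds), `pop1-only`, `pop2-only`, and `balanced-subset`
(an equal random draw per origin per fold).  Variance components are
re-estimated inside every training set; `G` is built once and sub-blocked.
Quality per validation origin: Pearson ρ, MSE, and the slope of observed
regressed on predicted (1 unbiased, >1 predictions under-dispersed, <1
over-dispersed).  Aggregation is mean over folds within replicate, then mean
and min–max range over replicates; replicate r redraws folds with seed
`base + r`.  Non-converged fits are counted and excluded, never imputed.

## GWAS preselection

The single-SNP model adds one dosage covariate to the GBLUP model.  The
variance ratio `λ = σ²_g/σ²_e` is fixed at the null-model REML estimate of
the same training set; each SNP then reduces to weighted least squares with
weights `1/(λ dⱼ + 1)` in the eigenbasis, and significance is the Wald χ²₁
test on `(β̂/se)²`.  A per-SNP λ re-optimisation exists behind a flag but is
off by default: the scan is used only to *rank* SNPs, and ranking is
insensitive to that refinement at these scales.  `σ²_β` (the nominal prior
variance of a SNP effect) is not estimated — the test treats β as fixed,
matching standard mixed-model GWAS software.  Ties in p break by genome
order.  Within cross-validation the scan sees training records only; the
subset GRM is rebuilt from the selected SNPs with the cohort-wide
frequencies restricted to the subset, which is the leakage-avoiding protocol
(permuted-phenotype accuracy stays at the null at every fraction — asserted
in the tests).

## Haplotype blocks and coverage

Blocks follow a simplified Gabriel et al. procedure: for every
intra-chromosome pair within 200 kb, two-SNP haplotype frequencies come from
an EM that only has to resolve double heterozygotes; |D′| gets a one-sided
90% confidence interval by normalising the multinomial profile likelihood on
a 201-point |D′| grid with allele frequencies held at their sample values.
Strong LD: CI ∈ [0.70, 0.98]; strong recombination: upper CI < 0.90; a
candidate span is a block when its outermost pair is strong-LD and ≥95% of
its informative pairs are; acceptance is greedy longest-first, leftmost on
ties.  All thresholds are configuration.  Coverage of a SNP subset is the
summed span of blocks containing at least one subset SNP divided by the
total block span (not the chromosome length) — so coverage(∅)=0 and
coverage is monotone in subset growth.

## The synthetic cohort generator

The generator emulates a two-country cohort of one breed:

| parameter | default | rationale |
|---|---|---|
| n_pop1 / n_pop2 | 600 / 150 | desk-scale 4:1 ratio of the two cohorts |
| n_snps / n_chromosomes | 2,000 / 38 | autosome count of the dog; REML is O(n³), so the marker panel is thinned |
| chrom_length_bp | 60 Mb | mid-sized dog autosome |
| recomb rate | 1e-8 /bp | 1 cM/Mb |
| effective_size, drift_generations | 100, 6 | `E[F_ST] ≈ 1 − (1−1/(2Nₑ))^g ≈ 0.03`, the target divergence |
| target_h2 | 0.3 | moderate heritability typical of hip traits |
| lr_correlation | 0.70 | liability-scale left/right correlation; yields ≈0.60 between the *derived scores* after discretisation |
| angle_mean / angle_sd | 104° / 9° | matches the reported angle distribution and places ≥70% of dogs at mean score ≤2 |
| sex_effect / origin_effect | 0.05 / 0.0 score units | small female excess; no systematic origin shift |

Founder haplotypes: 40 ancestral haplotypes with independent alleles are
dropped through 20 generations of random mating with recombination.  The
limited ancestral pool creates background LD at all distances; recombination
erodes it at rate `(1−c)ᵍ`, so LD decays with distance.  Loci fixed by
drift are rescued once, at the end, with a single low-frequency variant so
every frequency lies in (0,1).  Populations then drift independently
(binomial resampling with re-pairing and recombination each generation) and
are expanded by one random-mating generation to their final sizes.

Trait: `n_qtl = 200` markers get i.i.d. normal effects, rescaled so the
realized genetic variance hits the target; the residual is split into a
dog-level and a hip-level part so that simultaneously (i) the heritability of
the left/right *mean* equals `target_h2` on the liability (angle) scale and
(ii) the liability correlation between hips is `lr_correlation`.  Larger
liability maps linearly to a smaller angle (26/6 degrees per score unit),
and angles discretise through the scoring scale.  A `hidden_qtl` flag drops
the QTL from the marker panel to emulate imperfect marker–QTL LD; by default
QTL are markers, making GBLUP correctly specified.

What the generator does **not** emulate: pedigree structure and recent
selection, X-linked inheritance, genotyping error and missingness patterns,
site-specific scoring noise, and the real LD spectrum of array data (our
panel is sparse, so within-population LD is weaker than on a 100k array).
Consequently, passing tests show the estimators and designs behave correctly
under the assumed model, not that any particular real-data accuracy is
attainable.

Heritability recovery is asserted on the underlying mean-angle phenotype.
The discretised score carries less genetic variance — the floor at score 0
censors about a third of hips — so score-scale estimates sit around 0.15–0.25
when the liability h² is 0.3.  That attenuation is a property of the trait
definition, faithfully reproduced, not an estimator bias; the recovery test
therefore targets the scale on which the parameter is defined.

## Numerical and design choices

* Score scale: only the endpoints of the UK scheme (0 above 105°, 6 below
  79°) are universally documented; intermediate bands default to six equal
  widths over (79, 105] and are configurable.  Angles exactly on a breakpoint
  take the healthier score.
* One side of the hip missing: the available side's score is used, flagged.
* Merge key is (chromosome, position); allele pairs that neither match nor
  swap are dropped with a count.  The first input's genome order is kept.
* MAF filter is strict (`maf > threshold`) and recomputes frequencies on the
  current sample set.
* PCA for stratification uses PLINK-style per-SNP variance standardisation;
  the VanRaden-scaled eigendecomposition is available as an option and is
  the one that matches the GRM spectrum exactly.
* F_ST is Weir–Cockerham θ with ratio-of-averages aggregation
  (`Σa / Σ(a+b+c)`), the PLINK convention.
* LD-consistency defaults (1 Mb window, MAF floor 0.05, signed genotype r)
  are declared choices; the upstream protocol they emulate is not fully
  documented, so all three are knobs.
* Problem sizes in tests and examples (hundreds of dogs, 1–2k SNPs) were
  chosen so the whole suite runs on a laptop in minutes; every routine
  accepts full-scale inputs.

## Known limitations

* Univariate only: the cross-population genetic correlation (a bivariate
  GBLUP quantity) is out of scope.
* Dense linear algebra throughout; comfortable to n ≈ 5,000, not beyond.
* The Wald χ²₁ test is asymptotic; at very small n its type-I error drifts
  above nominal (the calibration test uses n = 500).
* Two-SNP EM phasing only; no multi-marker phasing, no recombination-map
  aware block definitions.
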