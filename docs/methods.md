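# Methods

## The measurement

Allelic imbalance at a heterozygous autosomal site is summarized as
`ase = ln((ref + 1)/(alt + 1))` — the natural-log reference/alternate read
ratio with a pseudocount of 1 on both alleles. The pseudocount keeps sites
where one allele is unobserved and maps `ref == alt` (including 0/0) to 0;
it also shrinks the statistic slightly toward 0 at low coverage (about
0.02 log-units at total depth 100 for a true imbalance of 0.75). Sites
enter the analysis when total coverage is *strictly greater* than the
cutoff (default 5) and the chromosome is autosomal; heterozygosity is
taken as established upstream (genotyping is out of scope).

On the logit scale the log-ratio is approximately the true allelic
fraction's logit plus noise of variance ≈ 1/(n·p(1−p)) at depth n, so at
typical exonic depths (tens of reads) count noise contributes a standard
deviation of roughly 0.2–0.3 — comparable to biological effect sizes.
Modeling all conditions of a unit jointly lets the linear model estimate
this noise from replication instead of relying on a parametric count model.

## ASE: whole-model ANOVA against the zero model

The unit of analysis is one SNP in one individual, observed across cell
types, treatments, and replicate plates. The full model is

    ASE ~ Control + CellType + Treatment + CellType:Treatment

with every factor categorical; `Control` is the vehicle label attached to
every observation (each treatment carries its solvent; the two vehicle
controls carry their own label, so one design table covers both). The
reduced model is the zero model — fitted values identically 0, zero
parameters — so the F statistic is

    F = ((Σ ase² − RSS_full)/df1) / (RSS_full/df2),

with df1 the number of *estimable* parameters (intercept included) and
df2 = n − df1. This literal zero-null tests "any allelic imbalance in any
condition", not just condition differences.

Designs are routinely rank-deficient: the vehicle factor is a function of
the treatment factor, and a treatment may be observed in only one cell
type. The model matrix is reduced by a sequential left-to-right
Gram-Schmidt sweep (tolerance 1e-9 relative) that keeps each column only
if it is independent of the columns already kept — the behaviour of R's
pivoting `lm`, which this class of ASE scan was built on. Earlier terms
therefore absorb shared degrees of freedom; the whole-model F is invariant
to this ordering, and per-term results report dropped columns as
inestimable rather than silently omitting them.

Eligibility: a unit is testable when ASE was measured in at least 5
conditions in every required cell type, every control label has at least
one observation, and at least 5 residual degrees of freedom remain after
aliasing. Degenerate outcomes are flagged: all-zero observations give
p = 1; an exact fit with nonzero data gives p at the smallest positive
float.

Multiple testing uses Benjamini–Hochberg step-up q-values (default level
10%). The implementation mirrors the standard ECDF-factor formulation so
q-values agree bit-for-bit with statsmodels' `fdr_bh`, which the test
suite uses as the independent reference. The combined-model scan is one
correction family; each per-cell-type scan is its own family.

## cASE: per-coefficient tests

ASE-significant units (which must also have each control observed in each
cell type they cover) are refit with the same model and each coefficient
is t-tested on the residual degrees of freedom. Treatment contrasts are
anchored at the control condition: the reference level of the treatment
and vehicle factors is the first control label (alphabetical; `ethanol`
under the default panel), so a treatment coefficient reads as that
treatment's ASE shift from baseline, and an interaction coefficient as the
cell-type-specific deviation of that shift. BH correction is applied
within term class — all cell-type coefficients across units form one
family, all treatment coefficients another, all interactions a third —
matching how the three interaction classes are reported separately. An
*instance* is one significant coefficient in one SNP-individual
regression; summaries count instances, unique SNPs, and unique genes
(via a SNP→gene map; unmapped SNPs count toward SNP but not gene tallies).

Power at this granularity is intrinsically limited: with duplicate plates,
a treatment main effect is identified from 2 replicate libraries against
controls in the reference cell type, so its standard error is about the
full residual standard deviation. The calibration runner
(`casekit.evaluate.treatment_effect_recovery`) quantifies this: a 0.75
log-unit effect at depth 100 with extra-binomial noise 0.25 is recovered
essentially without bias (mean estimate within a few hundredths), but
per-coefficient detection at BH-FDR 10% within the treatment family is of
order 10–20%, because the per-coefficient noncentrality is ≈ 2.3. Users
should read the instance counts accordingly: estimates are trustworthy,
per-instance significance is conservative.

## Variance decomposition

Per unit, the design factors are modeled as independent random intercepts:

    ASE ~ (1|Control) + (1|CellType) + (1|Treatment) + (1|CellType:Treatment)

(combined scope; the per-cell-type scope uses Control, Batch/Plate,
Treatment; expression matrices use Individual, CellType, Plate, Treatment,
or drop CellType and add Individual:Treatment within one cell type). The
factor set is configurable because the combined ASE formula is used in the
literature both with the vehicle covariate and with batch; the default here
is {Control, CellType, Treatment, CellType:Treatment}, with Plate available
as an optional factor.

Estimation is REML, profiled over the variance ratios γ_k = σ²_k/σ²_e with
the residual variance solved in closed form; each criterion evaluation
costs one q×q Cholesky factorization (q = total random levels), so a unit
with 84 observations and ~60 levels fits in milliseconds. Non-negativity
is enforced by the box constraint γ_k ≥ 0 (truncation at zero), optimized
by L-BFGS-B with a Nelder-Mead polish. On balanced designs the interior
REML solution equals the classical ANOVA (Henderson) method-of-moments
estimator; the test suite checks agreement to 1e-6 and cross-checks
against statsmodels MixedLM's variance-components route. Factors with a
single observed level are dropped and recorded. Reported fractions are
σ²_k / (Σσ²_k + σ²_e) and sum to one with the residual fraction.

Two estimation facts shape how recovery should be read. First, with only
3 cell-type levels the *population* cell-type variance is not consistently
estimable from one unit (the estimator is roughly a scaled χ²₂); what a
unit's data carry is the *realized* spread of its drawn level effects, so
the recovery experiments score estimates against realized (ddof-1)
fractions, which the balanced estimator is conditionally unbiased for.
Second, at 84 observations per unit the per-unit estimation noise puts the
median absolute error of each fraction at about 0.04–0.05 — the
calibration runner reports the realized values.

Residual ASE variance partly reflects sequencing depth, so every unit
carries its mean log10 total coverage, and the annotation regression

    Variance ~ Annotation + SNPexpression

always includes that coverage covariate (this is the depth adjustment; no
separate pre-correction is applied). Annotations may be numeric, boolean,
or categorical (expanded to indicator contrasts — e.g. a 3-level
differential-expression class). Gene-level variance for ranking the top
and bottom quantiles is the median over the gene's units; ties at the cut
resolve by stable gene-ID order. Whether variances are compared before or
after depth adjustment is analysis-dependent, so both the raw components
and the coverage covariate are exported.

## Directional splicing shifts

Input is a per-intron ΔΨ table (change in percent-spliced-in vs control)
with cluster-level significance flags, as produced by intron-excision
differential-splicing tools. Introns in significant clusters with
ΔΨ ≠ 0 are counted (a zero has no sign and is excluded from numerator and
denominator); per condition the count of positive introns out of tested is
compared against p0 — the *unweighted* mean of per-condition positive
proportions — by an exact two-sided binomial test using the
minimum-likelihood mass convention (sum of outcome probabilities no larger
than the observed outcome's), as in R's `binom.test`; the doubled-tail
variant is available behind a flag. Conditions are BH-corrected together.
Because p0 is estimated from the conditions themselves, strong shifts in a
few conditions pull the reference point and can make unshifted conditions
register opposite-direction shifts; the test is explicitly relative to the
global tendency.

## Overlap statistics

2×2 tables are always built inside the intersected tested universe — genes
untested in either study never enter a margin. The reported odds ratio is
the sample (ad)/(bc) value, with the Haldane-Anscombe 0.5 correction
applied and flagged when any cell is zero; significance always comes from
the exact conditional (hypergeometric) two-sided p-value, verified in the
tests against a full enumeration oracle. The one-sample proportion
statistic Z = (P − P0)/√(P0(1−P0)/N) supports both comparison axes
(average over treatments within a trait, or over traits within a
treatment); the axis must be chosen explicitly. Printed replication
percentages round half-up on the 0–100 scale.

## The synthetic-data generator

`simulate_truth`/`simulate_counts` emulate the motivating study design:
6 individuals × 3 cell types × (12 treatments + 2 vehicle controls) × 2
plates, fully crossed. Per SNP, a logit-scale predictor
β₀ + β_cell + β_treat + β_int is drawn with configurable effect-class
proportions and effect-size SDs (controls carry no treatment effect — they
define the baseline); per observation, extra-binomial noise N(0, σ_resid)
is added on the logit scale (default σ_resid = 0.15), total coverage is
negative binomial (default mean 60, dispersion 0.3 — typical exonic
heterozygous-site coverage at bulk depths; the dispersion is a documented
assumption, as allelic-count overdispersion is rarely reported), and the
reference count is binomial. Noise is additive on the logit scale because
the downstream models treat noise additively on the log-ratio scale; a
beta-binomial option with matched overdispersion is exposed for robustness
checks. ΔΨ tables draw signs with probability 0.5 + shift and magnitudes
Uniform(0.01, 0.3) (only the sign matters downstream); overlap gene sets
solve the per-gene joint membership probabilities from the marginal set
sizes and a target odds ratio. Everything is a pure function of
(parameters, seed).

What the generator does *not* emulate: read-level artifacts (mapping bias,
duplicates), haplotype structure across SNPs in a gene, correlated effects
between SNPs, missing conditions, or batch-by-condition confounding.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated model, not robustness to alignment
artifacts — those are handled (or not) upstream of the count table.

## Calibration experiments and problem sizes

`casekit.evaluate` packages the standing experiments; the test suite and
`scripts/acceptance.py` run them at these sizes, chosen to make Monte-Carlo
error small relative to the bands being checked while keeping a laptop-scale
runtime:

- Type-I error: 2000 null units (full 84-observation design, depth 50);
  empirical size of the ANOVA and of the per-coefficient tests at α = 0.05
  is expected in [0.03, 0.07]. For per-term size all units are fit: under
  the null almost none would pass the ASE pre-filter, and the size is a
  property of the coefficient test itself.
- Effect recovery: 500 units with a single 0.75 treatment effect,
  σ_resid = 0.25, depth 100; reports the mean coefficient estimate and the
  detection rate at BH-FDR 10% (see the power discussion above).
- Variance recovery: 200 units with variances 0.4/0.2/0.1 for cell type /
  treatment / interaction and 0.3 residual; reports per-factor median
  absolute error of fractions against the realized per-unit fractions.
- Direction test: exactness against the enumeration oracle for every
  n ≤ 500; 200 replicates each of a 36-condition null (expected clean — no
  significant condition — in ≥ 90% of replicates, the BH global-null rate)
  and of a 10-of-36 shifted scenario (shift 0.3, 1000 introns; near-certain
  detection).
- Elementary references: 1000 random p-vectors against the reference BH
  implementation (exact equality), 200 random 2×2 tables against the
  hypergeometric enumeration (margins ≤ 200).

## Known limitations

- One regression per SNP-individual; no pooling across individuals or
  across SNPs in a gene, and no meta-analysis when individuals disagree in
  effect direction — summaries count each individually.
- The zero-null ANOVA conflates a constant imbalance with condition
  dependence by design (that is what "any ASE" means here); cASE calls come
  only from the per-coefficient tests.
- Heteroskedasticity across observations (coverage varies) is ignored by
  the equal-variance linear model; at the default depths the size
  calibration stays within the nominal band, but extreme depth gradients
  within a unit would distort it.
- The variance decomposition assumes independent Gaussian level effects;
  components are truncated at zero, so fractions are biased upward for
  truly-zero components in small designs.
- Gene-level summaries depend entirely on the supplied SNP→gene map;
  overlapping genes or intergenic SNPs are whatever the map says.
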