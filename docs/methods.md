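# Methods

## Study design being modeled

A pediatric NDD case series is compared with a much larger population
control panel at rare predicted loss-of-function (LoF) variants.  The
analysis has two independent arms:

* **Cohort description / diagnostic yield**: counts of patients with a
  reportable WES finding, overall and by NDD subgroup (ID, ASD, GDD, SLD),
  with two-tailed Fisher exact comparisons between subgroups.
* **Gene-burden discovery scan**: per-gene CAST collapsing of qualifying
  LoF variants, tested by a right-tailed Fisher exact test and by Firth
  logistic regression with covariate adjustment, BH-corrected at
  FDR 0.5%.

The patient-level genotypes behind the scan are not public, so the scan's
guarantees are demonstrated on synthetic cohorts whose construction is
described below; the yield arm runs on the study's printed tables, which
ship with the package as TSV fixtures.

## Variant filters

* **Depth**: genotype calls with read depth < 20× are set to missing
  (boundary kept: exactly 20× passes).  Missing calls count as non-carrier
  everywhere.
* **Frequency**: sites with gnomAD AF ≥ 0.05 are removed ("below 5%" read
  strictly); sites absent from gnomAD are treated as rare and kept.
* **Consequence**: the default LoF vocabulary is {stop_gained,
  frameshift_variant, splice_acceptor_variant, splice_donor_variant,
  start_lost, stop_lost}; it is configurable because the source analysis
  never enumerates its own set.  Unknown terms warn and count as non-LoF
  (strict mode raises).
* **Penetrant-model filter**: any site carried by ≥ 1 case and ≥ 1 control
  (any zygosity) is removed; control-only and carrier-free sites are
  dropped too, since they cannot contribute to any case's indicator — the
  per-gene tables are identical either way, which a test verifies.
  Variant identity is the exact chrom:pos:ref:alt key.
* **Eligibility**: genes with ≥ 5 distinct qualifying LoF *sites*,
  assessed after QC but before the penetrant filter (the filter is part of
  the test's conditioning, not of the gene universe).  A config switch
  counts carrier *individuals* instead, since the "at least 5 rare LoF
  variants" rule admits either reading.

Filter order: the site-level filters commute with the penetrant filter;
depth masking does not, because the penetrant filter cannot know the depth
threshold.  The pipeline therefore always applies QC first.

## Burden tests

CAST reduces a gene to the binary indicator "carries ≥ 1 qualifying
allele" — presence/absence, not a dosage sum, so duplicated sites and hom
calls do not double-count.

**Fisher arm.** Right tail P(X ≥ a) of the margin-conditional
hypergeometric.  Point masses are computed as log-pmfs and combined with
logsumexp; the two-sided variant (used only in the yield arm) sums all
tables whose point probability is ≤ the observed one, with a 1e-7 relative
slack on the comparison to absorb round-off ties.  This is the standard
probability-mass definition — not tail-doubling, not mid-p.

**Firth arm.** The regression of case status on [intercept, carrier, sex,
standardized age, family history] maximizes l(β) + ½ log det I(β).
Newton iterations on the modified score start at β = 0; leverages are
recomputed every iteration from the weighted design; steps are halved (up
to 5 times) when the penalized log-likelihood does not increase, a step
onto a numerically singular information is never accepted, and a
stall-triggered damping of the expected-information step handles the rare
oscillation where that step overshoots the true penalized-Hessian step
(visible in one-observation intercept fits).  Convergence is
max|U*| < 1e-6 within 100 iterations by default.  Zero-variance and
collinear columns are dropped with a warning — e.g. a control panel in
which nobody has a family history would otherwise make the information
singular.

Per-gene significance uses the **penalized likelihood-ratio test** of the
carrier term against a covariate-only null fit (shared across genes).
Under the complete separation the penetrant filter produces, the Wald
statistic is deflated because the standard error grows with the estimate
(Hauck–Donner behavior): on a planted six-case/zero-control gene the Wald
p is ~10⁻³ while the LRT p is ~10⁻⁸–10⁻¹⁰.  Wald machinery still provides
the reported odds ratio and 95% CI, and is the fallback when the LRT is
unavailable (non-nested designs after column dropping).  Note the odds
ratios a Firth fit produces for such genes are O(10²–10³): the Jeffreys
penalty acts like adding half a count to each cell, so astronomically
large reported ORs are not reproducible from this (or any standard Firth)
implementation.

Both p-value columns are BH-adjusted (step-up, computed over eligible
genes only) and thresholded at q ≤ 0.005 inclusive.

## Synthetic cohorts

The generator emulates the statistical structure the scan assumes, not
exome sequencing itself:

* **Sizes**: 94 cases vs 1246 controls by default (the discovery-scan
  demonstrations use 60 cases, matching a negative-case subset being
  rescanned).
* **Planted genes**: an exact number of case carriers (default 6, the
  upper range of the reported per-gene counts is 5–8) and control carriers
  (default 0), each on a private heterozygous site — rare LoF variants are
  overwhelmingly het, and private sites are what survives the penetrant
  filter.  Options plant hom calls and case/control-shared sites to
  exercise the filter adversarially.
* **Background genes**: every sample is independently a carrier with
  probability 0.005 per gene (a typical per-gene rare-LoF carrier rate for
  an average-sized gene); carriers land on one of 8 candidate sites per
  gene, so sites can be shared and only carried sites are emitted, as in a
  jointly called VCF.
* **Covariates**: case sex ~ Bernoulli(61/94 male), ages uniform on 1–168
  months, family history Bernoulli(0.27), subgroups drawn at the cohort's
  observed proportions.  The control panel's covariates are unpublished;
  controls default to 50% male, 5% family history, and ages drawn from the
  *case* range.  The last choice is deliberate: with disjoint age ranges
  (e.g. adult controls), standardized age perfectly separates cases from
  controls, the age term absorbs the penalized likelihood, and the carrier
  effect becomes unidentifiable — an age-separated design cannot support
  the age-adjusted regression the analysis specifies.
* **Depth**: constant 100× by default (the stated mean target);
  a variable-depth option draws Poisson(100) with 5% of calls pushed below
  20× to exercise the depth filter.
* Everything is driven by one numpy Generator: a (config, seed) pair
  reproduces the cohort byte-identically.

What the generator does **not** model: linkage disequilibrium,
relatedness, population structure, non-LoF variant classes, annotation
error, and sequencing artifacts.  Passing tests therefore demonstrate the
statistical machinery (power under planted enrichment, FDR behavior,
filter contracts), not robustness to real-data confounding — the source
design handles relatedness and ancestry by sample exclusion upstream.

## Diagnostic yield conventions

* A case is diagnosed if it has ≥ 1 reported finding of any class
  (pathogenic, likely pathogenic, or VUS — the printed 39.4% = 37/94 is
  only consistent with VUS cases included); a compound-het case with two
  variant rows counts once.
* Subgroup yields are reported with the **whole-cohort denominator**
  (7/94, 21/94, 9/94 reproduce the printed 7.4/22.3/9.6%) and, alongside,
  within-group (7/36, 21/39, 9/13) for interpretability.
* Pairwise comparisons build within-group diagnosed/undiagnosed 2×2
  tables, two-tailed Fisher, for all subgroup pairs plus a pooled ID/GDD
  group.  The source's printed pairwise p-values cannot be regenerated
  from any table constructible from its printed counts (e.g. ID/GDD 30/52
  vs ASD 7/36 gives p ≈ 4×10⁻⁴, far from the printed 0.0028), so they are
  reported as computed, not matched.
* Demographic percentages are recomputed from printed counts.  Two
  internal inconsistencies of the source tables are preserved rather than
  resolved: the ID/GDD counts differ between the text (40/12) and the
  summary table (39/13 — the fixtures follow the table), and the table's
  printed ID share (42%) does not equal its own count ratio
  (39/94 = 41.5%).

## Null calibration

The penetrant filter conditions the analysis set on "zero control
carriers"; under the null this *selects* case-skewed sites and is
enrichment-inducing by construction.  Calibration of the right-tailed
Fisher test (empirical rejection ≤ nominal, measured at 0.05 on 500
unplanted genes) is therefore assessed on the unfiltered scan; the
filtered scan's specificity is assessed instead at the decision level
(no unplanted gene flagged at q ≤ 0.005 in the large majority of
simulations).  Both properties are exercised by the test suite at the
sizes above, chosen to keep the full suite under a minute of runtime
while leaving the binomial noise on each measured rate well inside the
asserted margins.

## Known limitations

* The expert prioritization step that reduced the source's 57 significant
  genes to 8 is curation, not computation, and is out of scope; the scan
  emits the full significant list.
* Compound heterozygosity is not reconstructed from phase; any nonzero
  dosage makes a sample a carrier, which subsumes the filter's intent.
* Wald CIs under near-separation are wide and asymmetric on the log scale;
  profile-likelihood intervals are not implemented.
* The two-sided Fisher definition is the probability-mass dialect; other
  software using tail-doubling or mid-p will differ on asymmetric tables.
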