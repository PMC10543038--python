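# Methods

This note documents the statistical procedures implemented in `ibspanel`,
the parameter defaults and why they were chosen, what the synthetic cohort
generator does and does not emulate, and the decisions taken where the
design was genuinely open.

## Data model

Genotypes are held as a samples × variants matrix of alternate-allele
dosages (0/1/2, with an explicit missing code) plus optional per-call
allele depths. Coordinates are 1-based as in VCF. Multiallelic VCF records
are split into biallelic records at read time and flagged with their
origin; the common-variant QC stage removes flagged records, so the
splitting is lossless while the analysis still operates on biallelic sites
only. Half-missing genotype calls (`0/.`) are treated as missing for both
dosage and call rate. Missing categorical metadata (ethnicity, sex) is a
first-class value, never dropped at read time, because the summary and
concordance operations apply their own exclusion rules.

## Quality control

The common-variant cascade applies, in order: multiallelic removal, the
Hardy-Weinberg exact test (exclude p < 1e-6), minor allele frequency (keep
MAF ≥ 0.01), call rate (keep > 0.95), and LD pruning. The filter log
records each removed variant once, under the first failing filter, so the
reasons partition the removed set.

**HWE exact test.** The standard two-sided conditional exact test: with
allele counts fixed, the p-value sums the probabilities of all heterozygote
counts (same parity) whose conditional probability does not exceed the
observed configuration's. The mid-out recurrence keeps the computation
stable for large counts; no mid-p correction is applied, matching the
default of the standard QC tool family. HWE is computed on the full cohort
(cases + controls) by default; a controls-only switch exists in
`QcThresholds` because the field is split on this practice.

**LD pruning.** Windows are counted in *variants* (window 50, step 5,
r² < 0.2) rather than base pairs: over a sparse targeted panel a 50-bp
window is nearly empty, and "50 5 0.2" is the canonical windowed-pruning
parameterization. Within each window, while any kept pair has r² at or
above threshold, the later-positioned member is removed (a deterministic
tie-break); passes repeat until a fixpoint so pruning is idempotent —
a single pass is not, because removals can shift distant variants into a
common window.

**Allelic ratio.** For rare-variant work, heterozygous calls must have an
alternate-read fraction in [0.30, 0.70] (boundaries inclusive); homozygous
calls must be within 0.30 of their expected fraction. Failing calls are
masked to missing rather than dropped with the variant. Cohort MAF is used
for the common-variant filter; gnomAD frequency (missing treated as rare,
as for variants absent from the reference database) defines rarity for the
prioritization stage.

## Ancestry

Identity-by-state distance between two samples is one minus the mean
shared-allele fraction (1 − |dᵢ − dⱼ|/2 per variant) over jointly called
variants. Classical (Torgerson) MDS embeds the distances: double-center the
squared distances, take the top-k eigenpairs, scale eigenvectors by root
eigenvalues, and fix each component's sign so its largest-magnitude loading
is positive (a determinism convention only). The cohort is embedded
*jointly* with the labelled reference panel, not projected afterwards.
Ten components are computed; the first two serve as association
covariates, up to six in sensitivity refits, and the first three for
ancestry assignment — the component counts used at each step in the
original analysis design.

Assignment is to the nearest superpopulation measured as Euclidean
distance to the group *centroid* over the first three components. The
alternative reading (nearest member) is available via configuration;
the centroid was chosen as the default because it is robust to reference
outliers and deterministic. Ties break lexicographically by label and are
flagged. Concordance maps self-reported ethnicity to superpopulations
(Asian counts as concordant with either EAS or SAS); unreported and
Multiple/Other samples are excluded from the denominator.

## Common-variant association

Each variant is fit by maximum-likelihood logistic regression (Newton/IRLS,
tolerance 1e-8, at most 50 iterations) of case status on minor-allele
dosage plus covariates (sex coded female = 1, plus MDS components).
The minor allele is defined on the pooled cohort so dosage coding is
identical across the overall and subtype scans. Wald 95% intervals
(exp(β ± 1.96·SE)) are reported rather than profile-likelihood intervals,
matching the convention of standard association tools. Complete or
quasi-complete separation yields a flagged non-converged result, never a
spurious estimate. No multiple-testing correction is applied by default
(results are reported at raw p < 0.01, with the flagged set refit using up
to six MDS components as a sensitivity analysis). Subtype scans restrict
cases to one Rome subtype and keep all controls, excluding other-subtype
cases. The genomic inflation factor is the median observed χ²₁ statistic
over the null median.

## Rare-variant prioritization

**Voting matrices.** Six damage assessments vote: CADD (damaging iff
strictly > 12) and the categorical calls of SIFT, PolyPhen2, LRT, FATHMM
and PROVEAN (damaging iff the call is "damaging", "possibly damaging",
"probably damaging" or "disease causing"). Four conservation scores vote
with strict thresholds: SiPhy > 12, GERP > 4.4, phyloP > 1.6,
phastCons > 0.5. Scores are reported as votes / *available* assessments
(two decimals): denominators vary with missingness — reported score
matrices contain values like 0.7 that are impossible with a fixed
denominator of six — while the classification cutoffs stay absolute:
damaging requires ≥ 4 damaging votes, conserved requires ≥ 2 conservation
votes, regardless of how many assessments were available.

**Qualification routes.** Both routes require a missense or splice-region
consequence and allelic-ratio-passing genotypes. The *matrix* route
additionally requires gnomAD MAF < 0.01 plus the damaging-and-conserved
classification. The *seqr* route requires MAF ≤ 0.05 and, for missense
variants, CADD ≥ 10 **or** REVEL ≥ 0.3 — disjunctive, because reported
qualifying variants include REVEL values well below 0.3 alongside high
CADD, which a conjunctive reading would exclude (a conjunctive mode is
available). For splice and intronic variants, where REVEL is undefined,
the fallback is CADD ≥ 10 or TRaP ≥ 0.1; the TRaP floor is configurable
because the reported splice variants carry TRaP values of 0.127–0.336 but
no explicit cutoff is stated.

**Biallelic screening.** Without parental data, phase cannot be resolved;
all co-occurring pairs are treated as potentially compound heterozygous.
A sample is biallelic in a gene if it carries ≥ 2 qualifying heterozygous
variants there or ≥ 1 qualifying homozygous-alternate variant (the
homozygous case is required by the recessive model even though two-variant
cases dominate reports). Monogenic candidates are retained only when no
control shows the same biallelic pattern over the same variant set — a
deliberately conservative false-positive control. The oligogenic screen
emits an event whenever a sample's qualifying variants span ≥ 2 genes,
tiering combinations confined to established deficiency genes (*SI*,
*LCT*, *TREH*, *SLC5A1*, *SLC2A5*, *ALDOB*) apart from those involving the
candidate genes (*MGAM*, *SLC5A2*); control events are emitted flagged
rather than silently suppressed, so case-exclusivity is reported.

**Symptoms.** Rome 0-4 severity ratings are rescaled to a 0-10 scale via
the monotone table {0:0, 1:4, 2:6, 3:8, 4:10}; the endpoints are fixed
(0 → 0, 4 → 10) and the interior is configurable. The default interior
produces the even-valued scores (6/8/10) that appear in carrier reports.

## Kernel burden test

For a marker set G (n × m) with weights w, the score statistic is
Q = (y − μ̂)' G W² G' (y − μ̂), with μ̂ from a logistic null model containing
the covariates only. Under the null, Q is a mixture Σ λᵢ χ²₁ with λᵢ the
eigenvalues of W G' P G W, where P = V − VX(X'VX)⁻¹X'V is the projected
variance of the null residuals. P-values use Liu-Tang-Zhang moment
matching by default; with a single positive eigenvalue the mixture is
exactly a scaled chi-square and the exact tail is used (this makes the
one-variant marker set agree with the per-variant score test to machine
precision); an Imhof characteristic-function inversion ("davies") and a
residual-permutation mode are available. Default weights are the
Beta(1, 25) density at each variant's cohort MAF — the canonical choice
that up-weights rarer variants; flat weights reduce Q to the unweighted
linear-kernel statistic. Marker sets per gene: *full* (all variants),
*rare* (cohort MAF ≤ 0.05), *deleterious* (rare ∩ seqr-qualified). MAFs
for set membership and weights come from the analysis cohort, not gnomAD.
Covariates default to sex plus the first two MDS components, the same
adjustment as the common-variant model, and are recorded in the output.
Missing genotypes are mean-imputed per variant, the standard convention
for score tests.

## Synthetic cohort generator

The generator's defaults emulate the structure of the study cohort this
pipeline was designed around: 687 cases and 439 controls from three sites
(proportions 359/470/297 of 1,126), 74.5% female, case subtypes in
proportions 206 IBS-D : 124 IBS-C : 47 IBS-M : 186 IBS-U : 124 unspecified,
predominantly European ancestry (AFR 0.05, AMR 0.10, EAS 0.03, EUR 0.79,
SAS 0.03) and deep targeted coverage (mean 450×).

Population allele frequencies follow a Balding-Nichols model: each
variant's ancestral frequency is uniform on (0.05, 0.5) and population
frequencies are Beta(p(1−F)/F, (1−p)(1−F)/F) draws with F the divergence
parameter (default 0.1, giving clearly separated MDS clusters; F = 0
collapses to panmixia). Genotypes are Hardy-Weinberg within population.
Disease status follows a logistic model combining planted per-allele
effects, a female log-odds of 0.25 (a mild positive effect consistent with
the female predominance among cases), and a baseline prevalence of 0.35;
individuals are accumulated by retrospective sampling until the case and
control quotas are met, which preserves odds ratios. The default common
panel is 120 variants spread over the seven gene regions proportional to
region length — a desk-scale stand-in for the few-thousand-SNV density of
a real targeted panel; tests that need more resolution (e.g. the ancestry
property) raise it explicitly.

Rare variation uses two mechanisms: background rare variants
(MAF 0.002) that carry benign annotations, and three reserved
frequency-zero slots per gene on which inheritance events are planted —
so the ground-truth ledger is exhaustive by construction and detection can
be scored for exact recovery. Planted carriers' symptom ratings are
shifted up by 2 points (clamped at 4) before rescaling, reproducing the
qualitative observation that carriers report moderate-to-severe symptoms
in a testable form. Read depths are Poisson (mean 450) with binomial
allele draws (het fraction 0.5 by default, configurable to exercise the
70:30 rule); one duplicated variant pair (r² = 1) is planted to exercise
LD pruning. Annotation scores are drawn above all thresholds for
deleterious-labelled variants and below for benign ones, with configurable
per-field missingness.

What the generator does **not** emulate: realistic LD haplotype structure
(only the duplicated pair), sequencing error and genotype miscalls beyond
allele-balance noise, age structure in disease risk, site-specific batch
effects, relatedness, or annotation scores correlated with true functional
impact in any graded way. Passing tests on synthetic data therefore
demonstrate the correctness and calibration of the statistical machinery
under the stated model, not robustness to every artefact of real
sequencing data.

## Numerical choices and problem sizes

All randomness descends from a single seed through per-stage derived
sub-seeds (CRC-based, process-independent), so identical configurations
produce byte-identical outputs and stages can be rerun in isolation.
Property tests run at sizes chosen to make their statistical tolerances
sharp while keeping the suite quick: the HWE implementation is compared
with an independent enumeration for every configuration up to 200 alleles
(≈ 90k configurations, agreement to 1e-12); odds-ratio recovery uses 200
cohorts of n = 4,000 (mean within 5%, CI coverage ≥ 93%); the null scan
uses 1,000 variants at n = 1,000; ancestry accuracy uses five populations
of 50 cohort samples each at F = 0.1 with a 40-per-population reference;
kernel-test calibration uses 2,000 null replicates at n = 400 with 15
markers (rejection rate within the 95% binomial interval around 0.05).

## Known limitations

- Wald intervals undercover slightly for very sparse variants; separation
  is flagged rather than penalized (no Firth correction).
- The Liu moment-matching p-value is approximate in the far tail; the
  Imhof or permutation options are preferable below ~1e-4.
- The oligogenic screen does not weight by gene dosage sensitivity or
  attempt phase; it enumerates co-occurrence only.
- No sample-level QC (relatedness, sex checks) is implemented; inputs are
  assumed to be from unrelated individuals.
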