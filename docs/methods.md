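# Methods

## The design being analyzed

A randomized trial with a training arm (EG) and a non-exercising control arm
(CG).  Cardiorespiratory fitness is measured as Cooper 12-minute run
distance (km) at weeks 0, 4 and 8; the response phenotype is the percent
change from week 0 to week 8 computed **per participant**.  Group summaries
are means of individual percent changes, not the percent change of group
means — with heterogeneous baselines the two differ, and all downstream
statistics use the former.  Training exposure is quantified by the
session-RPE method: sTL (A.U.) = running duration (min) × session intensity
(%V̇O₂max), where intensity is mapped from the Borg CR-10 session RPE.  The
default mapping is linear (sRPE × 10), so the prescribed sRPE 6–7 band
corresponds to 60–70 %V̇O₂max; the mapping is pluggable.  When sessions
within a week differ, the weekly load is mean sTL × session count, and the
program total sums weekly loads (these reduce to the plain products for a
uniform program, and remain defined for taper weeks around test sessions).

## Genotype quality control

Chip calls carry up to six replicate probe readings in forward and reverse
orientations.  Reverse readings are base-complemented onto the forward
strand; a call whose normalized readings disagree is set to missing (never
imputed), and a participant whose missingness exceeds a configurable ceiling
(default 20% of the panel) is removed before any statistics.  Palindromic
A/T and C/G SNPs cannot be strand-resolved from sequence alone; they are
trusted as reported, with a warning — chip pipelines resolve these upstream,
and the simulated panels avoid palindromic pairs entirely.  Monomorphic
SNPs (a single genotype across all non-missing calls) are uninformative and
removed; the removal is idempotent, and a SNP whose only variation is
missingness still counts as monomorphic.

## Population-frequency exclusion

For each SNP with a published alternate-allele proportion, Hardy-Weinberg
expected genotype counts (p², 2pq, q² at the cohort's non-missing n, rounded
to integers because exact tests need integer tables) are compared with
observed counts by an exact conditional test: the two-sided p is the sum of
probabilities of all tables with the observed margins no more probable than
the observed table (Fisher's exact test for 2×2; the Freeman–Halton
extension, computed by full enumeration in exact integer arithmetic, for the
2×3 genotype table).  When any expected genotype class rounds to zero the
comparison falls back to the 2×2 allele-count table.  SNPs with p ≤ 0.05
are excluded from scoring as likely genotyping or sampling artifacts.  Two
numerical notes: conditioning on a near-deterministic "expected" row makes
this test conservative (the null exclusion rate is well below the nominal
alpha — measured ≈0.3% at alpha = 5%), and exclusion is monotone in alpha by
construction.  scipy's `fisher_exact` covers only the 2×2 case, which is
why the enumeration is implemented here; it is cross-checked in the tests
against independent rational-arithmetic enumeration and against R's
`fisher.test`.

## Discovery: screen, confirm, assign

Training-arm participants are dichotomized at the arm mean percent
improvement (strictly greater ⇒ responder; ties non-responder; the control
arm is never classified).  Each polymorphic SNP is screened with Pearson's
χ² (no continuity correction) on a responder × allele-count 2×2 table by
default (each participant contributes two allele copies); a genotype-model
2×3 table is available by flag.  SNPs fall into a primary band (p ≤ 0.05)
or secondary band (0.05 < p ≤ 0.075).  **No multiple-testing correction is
applied by default**: the screen is deliberately permissive and its
false-positive count grows linearly with panel size; Bonferroni and
Benjamini-Hochberg switches exist for sensitivity analysis and can only
shrink the banded set.  Banded SNPs are confirmed by one-way ANOVA of
percent improvement across genotype groups (groups with fewer than two
members dropped by default, mergeable into the heterozygote group), gated on
Levene's homogeneity test; a SNP is retained when its band is primary or
secondary, ANOVA p ≤ 0.05, variances are homogeneous, and it is not
population-excluded.  The retention rule admits secondary-band SNPs because
the confirmation, not the screen, carries the magnitude information.  The
favorable allele of a retained SNP is the allele with the higher relative
frequency among responders; an exact tie drops the SNP with a warning.
Screen output order is deterministic: χ² p ascending, rsid lexicographic
tie-break.

## Scoring and regression

Each retained SNP contributes 2 (homozygous favorable), 1 (heterozygous) or
0 to a participant's total genotype score — deliberately unweighted, since
the additive equal-effect model is the hypothesis under test.  A missing
genotype at a retained SNP contributes 0 and is counted in `n_missing`
(policy switchable to participant exclusion, mirroring wholesale removal of
probe-inconsistent participants).  The score is regressed by OLS against
percent improvement; slope, intercept, Pearson r, R² and the two-sided
t-test p on the slope are reported.  A companion regression of percent
improvement on baseline distance quantifies the training-status effect
(negative slope = larger relative gains in less-fit starters).

### The selection-circularity caveat

Selecting SNPs by association with the response and then regressing the
summed score on that same response inflates R² by construction.  The χ²
screen and the ANOVA confirmation reuse the same phenotype, so their joint
null pass rate is far above alpha² (measured ≈2–3% of a null panel), and on
a 715-SNP null panel with 21 training participants the pipeline typically
retains 7–20 SNPs whose in-sample score regression is "significant" at
p ≈ 1e-7 despite zero planted effects.  At the default study scale the
per-SNP screen also has little power against the calibrated ~3-point
per-allele effect, so the retained set is dominated by chance associations
even when real effects exist.  The honest checks are therefore
out-of-sample: scores built from SNPs selected on one cohort show no
association with an independent null cohort's responses, and scoring with
the *true* planted alleles recovers the planted R².  Both are exercised in
the test suite; any in-sample R² from `run_discovery` should be read with
this caveat.

## Group statistics and effect sizes

Every comparison is gated on Shapiro-Wilk normality (worst group) and
Levene homogeneity at alpha 0.05; failing the gate switches to the
rank-based equivalent (Mann-Whitney U with exact small-sample p-values for
groups of n ≤ 20 without ties, Wilcoxon signed-rank, Friedman).  The
repeated-measures ANOVA across the three test weeks is computed from the
subject × week sum-of-squares decomposition and is verified against
statsmodels' `AnovaRM`.  Cohen's d for a within-group change is the mean
change divided by the group's **baseline** SD — the standardizer that
reproduces the tabulated week-8 effect sizes (0.48 training, 0.08 control)
exactly from group summaries; change-score or pooled SD variants can be
computed by passing those SDs instead.  Labels: trivial < 0.20, small
0.20–0.49, medium 0.50–0.79, large ≥ 0.80.  The "repeat-hit" helper gives
the chance of one gene clearing an alpha-level screen k times independently
(alpha^k; e.g. 0.05³ = 1.25×10⁻⁴) and its expectation over a panel.

## The synthetic-cohort generator

Defaults are the study conditions the analysis targets: 21 training and 24
control participants; a 1,000-SNP panel with 28.5% of sites fixed
monomorphic; polymorphic alternate-allele frequencies uniform on
[0.05, 0.95] (European-like common-variant spectrum; the chip's true
frequency spectrum is unknown); 18 causal SNPs with equal additive effects
at favorable-allele frequency 0.30; training-arm baselines
N(2.22, 0.48²) km and control N(2.06, 0.37²) km; control-arm percent change
N(1.55, 6.98²).  The per-allele effect β, intercept and residual SD are
calibrated in closed form so the planted score-response R² is 0.85 at a
response mean/SD of 11.51/9.09%: with score variance Var(S) = 2m f(1−f)
for m causal SNPs at frequency f, β² Var(S) = R²·σ², residual² = (1−R²)·σ².
The causal-allele frequency 0.30 keeps total scores in a realistic 5–15
range; because the score is a sum of 18 binomials, any frequency choice
trades intercept against slope without changing the planted R².  Week-4
distance interpolates 0.6 of the week-8 change (the observed mid-study
fraction 0.14/0.23 ≈ 0.61); a negative baseline coefficient can plant the
baseline-dependence effect (off by default).  Genotypes are drawn from HWE
at each SNP's frequency, and metadata records the true sampling frequency,
so population-outlier exclusions are calibrated at their nominal level.
Probe artifacts fabricate three forward + three reverse replicate readings
per call and corrupt a configurable fraction; named participants can be
corrupted wholesale to exercise whole-participant removal.  All randomness
flows from the single config seed.

What the generator does **not** emulate: linkage disequilibrium (SNPs are
drawn marginally), population structure, genotyping-error correlation
across SNPs, unequal causal effect sizes, and diary non-compliance.
Passing recovery tests therefore demonstrate correctness of the pipeline
under the additive independent-SNP model, not robustness of the scientific
conclusion to correlated real panels.

## Problem sizes and numerical choices

The test suite and acceptance script run desk-scale versions of every
experiment: R² recovery uses 100–200 replicates of an 18-SNP, 17-participant
cohort; slope recovery 100–150 replicates at n = 100/arm; favorable-allele
accuracy ≈25 replicates at n = 100/arm with per-allele effect = residual SD
(accuracy is measured among *retained* causal SNPs — assignment's
precondition — where it is ≈100%; unconditionally over all causal SNPs at
that signal level it is ≈96%); null calibration on 715-SNP, 45-participant
cohorts.  Exact-test enumeration is O(product of column totals) and is used
for the cohort sizes here (total ≤ ~100); p-value comparisons in tests use
exact rational arithmetic.  Degenerate inputs are defined rather than
crashed: zero-margin contingency tables give χ² = 0, p = 1; all-identical
ANOVA groups give F = 0, p = 1; all-zero count rows give an exact p = 1
with a warning; zero-variance predictors raise.

## Known limitations

- The select-then-regress R² is anti-conservative (above); the pipeline
  reports it because it is the procedure under study, not because it is a
  valid estimate of genetic signal.
- The exact population-frequency comparison treats rounded expected counts
  as a second sample; it is conservative and its power at n = 45 is limited
  to large frequency shifts.
- Exact Mann-Whitney p-values switch to the normal approximation above
  n = 20 per group or in the presence of ties.
- X-chromosome SNPs are scored like autosomal ones (male hemizygosity is
  not modeled), matching the unweighted-count convention of the score.
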