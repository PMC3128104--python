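# Methods

## The model being tested

Two case-control (or quantitative-trait) GWAS of the same phenotype share a
set of SNPs. If the discovery study's per-SNP effect estimates reflect real
effects, then the probability that a SNP reaches P < α in the independent
test study is, to first order, its statistical power computed from the
discovery effect size, the discovery allele frequency, and the test sample
size. `powerrep` operationalizes this as a logistic regression of the
per-SNP replication indicator on per-SNP power. The framework's identifying
assumptions: the two studies measure the same underlying effects (no
population-specific effects or phenotype heterogeneity), have similar LD
structure, and are sample-disjoint (so discovery noise and test noise are
independent). One headline P-value is produced per model, never per SNP.

## Power calculations

**Binary traits** use the 1-df allelic (allele-count) chi-square test. The
discovery OR and MAF are rounded to 2 decimal places before the calculation
(the rounding mirrors how such discovery statistics are consumed and makes
an OR of 1.004 an exact null); the case allele frequency implied by the OR
is p₁ = OR·p₀/(1 + p₀(OR − 1)); the noncentrality parameter is the squared
standardized two-proportion contrast at the test study's allele counts; and
power is the noncentral-χ²(1, λ) mass beyond the central critical value.
Whether the original construct used allele counts or a genotype-trend
parameterization is not determinable from the construct's description alone;
at Hardy–Weinberg equilibrium the two agree closely, and the forward
simulation (logistic regression on genotype, i.e. the trend parameterization)
is the arbiter: the analytic calculator must match its rejection rate within
Monte-Carlo error, and does. The calculator accepts any effect-allele
frequency in (0, 1) and is exactly invariant to allele relabelling
(p → 1 − p, OR → 1/OR) when rounding is off.

**Quantitative traits** follow the `pwr.f2.test` convention: SNP variance
2p(1 − p) under HWE, R² = β²·2p(1 − p)/s², f² = R²/(1 − R²), numerator df 1,
denominator df N − 2, noncentrality f²·(u + v + 1). The trait SD default for
height-like runs is 9.2 cm; β and s must share units. The formula's R² uses
the residual trait variance as s², which overstates the noncentrality by a
factor 1 + R² relative to total-variance R²; at the per-SNP effect sizes this
framework addresses (R² ≪ 0.01) the difference is far below Monte-Carlo
resolution.

Null effects return power = α *exactly* in both calculators (the power of a
size-α test under the null is its size), which keeps the degenerate case
noise-free in downstream regressions.

A low-sample-size filter (`filter_low_n`, default: drop the lowest-n 20%,
keeping ties at the cut) exists for meta-analysis inputs where per-SNP N
varies; the single-N simulated studies make it a no-op.

## Enrichment models

Models are maximum-likelihood logistic fits (statsmodels `Logit`) of
`replicated` on: power (I); power + near_exon + power×near_exon (II); the
same two forms on the subset of SNPs with effects in the same direction in
both studies (III, IV); same_direction alone (M1); and
power + same_direction + power×same_direction (M2). SNPs with an exactly
null effect in either study carry an undefined direction and are excluded
from III/IV/M1/M2. Wald P-values are the default (matching `glm` output); a
likelihood-ratio switch refits without each term. Non-convergence or
(quasi-)separation is flagged and the P-values withheld rather than
reported. Power enters untransformed as a proportion in [0, 1].

Excess replication above a power threshold t is
n_rep(power ≥ t) − n(power ≥ t)·r̄, with r̄ the replication rate over *all*
records; the counts are kept as exact floats and rounded only for display.
Power deciles are [0, 0.1), …, [0.9, 1.0] with power 1.0 in the top bin.

The permutation negative control shuffles the replication labels across SNPs
and refits: this preserves the marginal replication rate while severing the
SNP-to-power link, giving a finite-sample null for the observed fit. (With
individual-level data one would permute case/control status instead; at
summary scale, label permutation is the faithful surrogate, and the
individual-level variant is available through the simulator's cohorts.)

The smoothing-spline summary (`UnivariateSpline`, cubic, inverse-variance
weights from per-power-value counts) is descriptive only: it renders the
replication-proportion curve that the model fits quantify, clipped to [0, 1]
and constant-extrapolated outside the observed power range.

LD pruning is the standard greedy sliding window (50 SNPs, step 5,
r² < 0.5): within each window the later SNP of any pair at r² ≥ the cutoff
is removed, deterministically keeping the earlier SNP, before the window
advances. Constant (zero-variance) columns have undefined r² and are never
removed on that account.

## Synthetic data

**Summary-statistic study pairs** (`generate_study_pair`) emulate a shared
SNP panel with known truth. Defaults are the study conditions the framework
targets: 50,000 SNPs (scaled to 20,000 in the recovery tests), MAF uniform
on (0.05, 0.5), 30% causal with true ln OR ~ N(0, 0.08), discovery
1,868/2,938 and test 2,191/1,434 cases/controls. Observed effects in each
study are independent draws from the asymptotic normal sampling distribution
of the single-SNP ln OR (or β), with standard errors evaluated at the true
allele frequencies — the standard large-sample approximation, cross-checked
against full individual-level simulation. P-values are two-sided Wald.
Observed allele frequencies are reported noise-free; their sampling noise is
second-order for power. Half the test-study records have their allele labels
swapped so harmonization is genuinely exercised. Palindromic (A/T, C/G)
pairs occur naturally and are kept by default, aligned by allele label.

When a near-gene signal is planted, causal SNPs are placed within 10 kb of
synthetic exons (1,500 exons of 150 bp on a 200 Mb chromosome; ~15% of
uniform positions fall within 10 kb of one). Planting is *complete*
(`exon_frac_near = 1.0`) in the recovery scenario: the power × near-exon
interaction is driven by far-from-exon high-power SNPs being winner's-curse
nulls, and even 20% of causal SNPs leaking into the far stratum dilutes the
interaction to near-null. This is a property of the interaction test, not of
the implementation, and is worth remembering when interpreting weak
interaction terms on real data.

**Forward simulations** are the independent oracles. Binary: one population
(default 10⁵ individuals; the full-scale 10⁶ is a parameter away and needed
when the requested case count exceeds the smaller population's affected
pool) with HWE genotypes; disease risk is prevalence × OR^(risk alleles)
(prevalence 1%), affection by comparison with a uniform draw; each of 100
replicates samples cases and controls afresh from the fixed population and
fits a single-SNP logistic regression. Because the population's affected
pool is itself a random draw, replicates within one population are
correlated; oracle comparisons therefore average over several populations
and use the across-population spread as the Monte-Carlo SE. Quantitative:
each replicate draws a fresh cohort with trait = s·N(0, 1) + β·(allele
count) and fits a simple linear regression (equivalent to resampling from an
effectively infinite population; the case-enrichment issue that motivates a
fixed population in the binary design does not arise). A balanced-power
sampling helper (19 SNPs per 5% power bracket) is available; the default
calibration grids are uniform in power.

**Calibration** (`power_calibration_curve`): 40 SNPs with MAF uniform in
(0.05, 0.5) and β solved by root-finding so analytic power spans 0.05–0.95
at n = 2,000 and α = 0.05; 100 simulated replicate analyses per SNP; OLS
slope of empirical rate on analytic power. The slope is ~1.0 and the
acceptance band ±0.1; n = 2,000 with 100 replicates keeps the run under a
minute while the binomial noise per point (≤ 0.05) averages out over 40
points.

**Individual-level cohorts** for polygenic scoring are sampled
retrospectively: under the multiplicative per-allele risk model with
independent SNPs and a rare disease, a case's alleles at a SNP with true OR
and population frequency p are Bernoulli with the tilted frequency
p·OR/(1 + p(OR − 1)), and controls carry the population frequency. This is
exact per SNP under the generating risk model and avoids simulating the
million-individual prospective population that direct ascertainment of
thousands of cases at 1% prevalence would require. LD-structured genotypes
(Gaussian-copula haplotype blocks) exist solely to exercise the pruner; the
default generators keep SNPs independent, so passing tests say nothing about
LD-induced miscalibration on real data.

What the synthetic data do *not* model: LD between SNPs (except the
dedicated block mode), population stratification, genotyping error,
imputation uncertainty, sample overlap between studies, and data-quality
artifacts in the extreme discovery tail. Recovery on these generators
demonstrates the statistical machinery, not robustness to those real-data
failure modes.

## Polygenic scoring

Scores are the mean over included SNPs of discovery ln(OR) × effect-allele
dosage (the PLINK `--score` averaging convention; a sum variant is a flag).
SNP subsets at progressive discovery-P thresholds are nested by
construction. Score–status association is a logistic regression reported
with a Wald P and Nagelkerke's pseudo-R² (the statistic `rms::lrm` reports;
Cox–Snell is available). The score is standardized internally before the
fit — the association is invariant to affine rescaling, and a unit-scale
predictor makes separation detectable by coefficient magnitude. Perfect or
quasi-separation raises a dedicated error rather than returning meaningless
estimates. The default threshold ladder (10⁻⁴, 10⁻³, 10⁻², 0.1, 0.5, 1) is
this package's choice of a conventional ladder.

## Harmonization and annotation conventions

SNPs are matched across studies by identifier, not position. Swapped allele
labels invert the OR (negate β) and complement the frequency; allele pairs
that are neither identical nor swapped are excluded. Strand-ambiguous A/T
and C/G SNPs are kept by default and aligned by label (a `drop` policy
exists; without strand information neither choice is verifiable, so the
switch is exposed rather than a guess hard-coded). Effects are stored on
their natural scale (OR, not ln OR); the MAF filter (> 1% by default)
applies to the discovery study's minor allele.

SNP positions are 1-based; BED and refGene exon intervals are converted from
UCSC 0-based half-open on read. Overlapping exons are merged before the
nearest-exon search (binary search over merged interval edges, verified
against an all-pairs scan). Distance is the basepair gap — 0 inside an exon,
start − pos or pos − end outside — and SNPs with no exon within the search
window (1 Mb default) carry a missing distance that maps to "not near" at
every threshold. Near-exon indicators at an ascending threshold grid are
monotone by construction.

## Numerical choices

- Wald P-values from the asymptotic normal; simulated P-values clipped to
  ≥ 10⁻³⁰⁰ to stay in (0, 1].
- Noncentral distributions via scipy (`ncx2`, `ncf`); λ floored at 10⁻³⁰⁰
  before the tail call and the exact-null branch returned as α.
- `beta_for_power` brackets the root in [0, 0.999·s/√(2p(1−p))] (the R² → 1
  bound) and solves to 10⁻¹⁰.
- All generators take a single integer seed through
  `numpy.random.default_rng`; identical seeds give byte-identical output
  files. Derived seeds stay below 2³¹.
- Ties in `filter_low_n` are kept; ties between equidistant exons are
  irrelevant because only the distance is retained.

## Known limitations

- The binary power calculator and the logistic-regression forward simulation
  agree to Monte-Carlo precision at HWE, but the allelic NCP is an
  asymptotic approximation: at MAF near the 1% filter boundary and extreme
  ORs its error is a few parts per thousand.
- The interaction test's sensitivity collapses under partial planting (see
  above); real near-gene enrichment that is partial will need far more SNPs
  than the complete-planting recovery scenario suggests.
- Replication is a hard P < α indicator; no use is made of the test study's
  effect magnitudes beyond their sign.
- The pipeline assumes both studies report the same genome build; there is
  no liftover, imputation, or genotype-level QC.
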