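# powerrep

Power-based replication enrichment for GWAS summary statistics.

## The problem

A genome-wide association study of modest size often ends with no
genome-wide-significant hits, yet its sub-significant results may still carry
real signal. `powerrep` tests for that signal without ever calling
individual SNPs significant: for every SNP shared between a *discovery* and a
*test* study it computes the power to detect the discovery effect in the test
sample, then asks — with a single logistic regression across all SNPs —
whether replication in the test study (P < 0.05) is a function of that power.
If the discovery effects are real and well estimated, replication approaches
a *linear* function of power with slope 1; if they are noise, the relationship
is flat. Because one hypothesis is tested over all SNPs jointly, the headline
P-value needs no multiple-testing correction.

The same machinery stratifies the test by genomic context (is the
power–replication slope steeper for SNPs near exons?) and by direction of
effect, counts the excess of replicating SNPs in high-power strata, and
validates the whole chain by forward simulation.

## The statistics

**Case-control power.** From the discovery odds ratio OR and control
minor-allele frequency p₀ (both rounded to 2 decimals), the implied case
allele frequency is p₁ = OR·p₀ / (1 + p₀(OR − 1)). With 2N₁ case and 2N₀
control alleles in the test sample, the 1-df allelic chi-square test has
noncentrality

&nbsp;&nbsp;λ = (p₁ − p₀)² / [ p̄(1 − p̄)(1/2N₁ + 1/2N₀) ],&nbsp;&nbsp;
p̄ = (2N₁p₁ + 2N₀p₀)/(2N₁ + 2N₀),

and power is P[χ²₁(λ) > χ²₁,₁₋α]. A null effect gives power = α exactly.

**Quantitative-trait power.** With SNP variance 2p(1 − p) under
Hardy–Weinberg equilibrium, R² = β²·2p(1 − p)/s², Cohen's f² = R²/(1 − R²),
and power is the noncentral-F tail P[F(1, N − 2; λ) > F₁,N₋₂,₁₋α] with
λ = f²(u + v + 1), u = 1, v = N − 2 (the `pwr.f2.test` convention).

**Enrichment models.** Logistic regressions of the per-SNP replication
indicator: replication ~ power (Model I); adding a near-exon indicator and
its interaction with power (Model II); the same pair of models on the subset
of SNPs whose effects agree in sign across studies (Models III/IV); and
direction-of-effect models replication ~ same-direction (M1) and
replication ~ power × same-direction (M2). Excess replication above a power
threshold t is n_rep(power ≥ t) − n(power ≥ t) × overall replication rate.

## Worked example

The numbered scripts under `analysis/` run the whole framework on a
synthetic study pair with known truth (20,000 SNPs, 30% causal with
ln OR ~ N(0, 0.08), causal SNPs planted within 10 kb of synthetic exons,
discovery 1,868/2,938 and test 2,191/1,434 cases/controls):

```
python analysis/01_simulate_study_pair.py
python analysis/02_replication_vs_power.py
python analysis/03_exon_enrichment.py
python analysis/04_power_calibration.py
python analysis/05_polygenic_scoring.py
```

Step 02 prints:

```
20000 harmonized SNPs; 11.1% replicate at P<0.05; 5.9% have power >= 0.6
power term: P = 0.00e+00 (all SNPs), 0.00e+00 (same-direction subset)
power >= 0.6: 618/1187 replicate; expected 132 at the overall rate 11.12% -> excess 486
permutation control: observed P 0.00e+00 vs permuted 1st percentile 0.008
```

Replication is strongly predicted by power (the Wald P underflows), the
high-power stratum replicates far beyond the genome-wide average (618
observed vs 132 expected), and shuffling the replication labels across SNPs
destroys the association. Step 03 recovers the planted near-gene signal:

```
model II @ 2 kb: interaction -0.29, P = 2.44e-01
model II @ 25 kb: interaction +3.88, P = 8.38e-20
sweep: interaction strongest at 10 kb (-log10 P = 23.0)
```

— the power × near-exon interaction peaks at the 10 kb planting scale and is
absent at 2 kb, the planted analogue of enrichment near genes but not inside
exons. Step 04 prints the calibration result the framework rests on:

```
OLS slope of empirical rate on analytic power: 0.983 (max |rate - power| = 0.098 over 40 SNPs)
```

The same stages are available as a CLI (`powerrep simulate | harmonize |
annotate | power | enrich | score | run`); `powerrep run --preset
synthetic-bd --seed 7 -o rundir` executes the chain end to end and writes a
manifest of SHA-256 hashes so reruns are verifiably identical.

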