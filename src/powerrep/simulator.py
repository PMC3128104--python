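"""Synthetic data with known truth: forward simulations and study pairs.

Two tiers of generator live here.

*Individual-level forward simulations* draw genotypes under Hardy-Weinberg
equilibrium and phenotypes from an explicit risk model, then measure the
empirical replication rate of a single SNP over repeated sampled analyses:

- binary: a population is simulated once per SNP; an individual's disease
  risk is ``prevalence * OR**(risk-allele count)`` and they are affected when
  that risk exceeds a uniform draw.  Each replicate samples fresh cases and
  controls from this population and fits a single-SNP logistic regression.
- quantitative: each replicate draws a fresh cohort whose trait is a
  standard-normal baseline (times ``sd_trait``) plus ``beta`` per allele,
  then fits a simple linear regression.

These simulations are the independent arbiter for the analytic power
calculators, and a designed grid of them gives the slope-1 power-calibration
curve.

*Summary-statistic study pairs* emulate a discovery + test pair of GWAS with
a configurable fraction of shared true effects: per SNP the true ln(OR) (or
beta) is drawn, and each study's observed effect is sampled independently
from the asymptotic normal distribution of the single-SNP estimator at that
study's sample size, with Wald P-values.  Causal SNPs can be concentrated
near synthetic exons to plant a near-gene enrichment signal.  The truth
(causal flags, true effects, planting flags) is retained for recovery tests,
and the emitted tables round-trip through :mod:`powerrep.io_harmonize`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats, optimize

from .exon_annotation import ExonInterval, merge_exons
from .io_harmonize import SnpSummary, write_summary
from .power import power_quantitative

_ALLELE_PAIRS = [(a, b) for a, b in itertools.product("ACGT", repeat=2) if a != b]


@dataclass
class SimStudyPair:
    """Discovery + test summary tables with ground truth and synthetic exons."""

    discovery: list[SnpSummary]
    test: list[SnpSummary]
    truth: pd.DataFrame
    exons: list[ExonInterval]
    seed: int
    trait_kind: str

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit discovery/test/truth tables and an exon BED under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "discovery": outdir / "discovery.tsv",
            "test": outdir / "test.tsv",
            "truth": outdir / "truth.tsv",
            "exons": outdir / "exons.bed",
        }
        write_summary(self.discovery, paths["discovery"])
        write_summary(self.test, paths["test"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["exons"], "w") as fh:
            for ex in self.exons:
                # back to BED's 0-based half-open on write
                fh.write(f"{ex.chrom}\t{ex.start - 1}\t{ex.end}\n")
        return paths


def _hwe_genotypes(rng: np.random.Generator, maf: float, size) -> np.ndarray:
    return rng.binomial(2, maf, size=size)


def simulate_binary_replication_rate(
    or_: float,
    maf: float,
    n_cases: int,
    n_controls: int,
    prevalence: float = 0.01,
    pop_size: int = 100_000,
    n_reps: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical single-SNP replication rate from a forward case-control sim.

    One population of ``pop_size`` individuals is simulated (genotypes under
    HWE, affection via the multiplicative risk rule); each replicate samples
    ``n_cases`` affected and ``n_controls`` unaffected individuals and fits a
    logistic regression of status on allele count.  Returns the fraction of
    replicates with P < alpha.
    """
    if prevalence * or_**2 >= 1.0:
        raise ValueError("prevalence * OR^2 must stay below 1 (risk is a probability)")
    rng = np.random.default_rng(seed)
    g = _hwe_genotypes(rng, maf, pop_size)
    risk = prevalence * or_**g
    affected = rng.uniform(size=pop_size) < risk
    case_pool = np.flatnonzero(affected)
    control_pool = np.flatnonzero(~affected)
    if len(case_pool) < n_cases or len(control_pool) < n_controls:
        raise ValueError(
            f"population of {pop_size} yielded {len(case_pool)} affected / "
            f"{len(control_pool)} unaffected; increase pop_size"
        )
    hits = 0
    for _ in range(n_reps):
        ci = rng.choice(case_pool, size=n_cases, replace=False)
        ki = rng.choice(control_pool, size=n_controls, replace=False)
        gg = np.concatenate([g[ci], g[ki]]).astype(float)
        y = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
        X = np.column_stack([np.ones_like(gg), gg])
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
            pv = res.pvalues[1]
        except Exception:  # degenerate draw (e.g. monomorphic sample)
            continue
        if np.isfinite(pv) and pv < alpha:
            hits += 1
    return hits / n_reps


def simulate_quantitative_replication_rate(
    beta: float,
    maf: float,
    n_test: int,
    n_reps: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    sd_trait: float = 1.0,
) -> float:
    """Empirical replication rate for a quantitative-trait SNP.

    Per replicate: genotypes under HWE, trait = sd_trait * N(0,1) baseline +
    beta * allele count, simple linear regression, reject at P < alpha.
    ``beta`` and ``sd_trait`` share units (defaults put beta in SD units).
    Fully vectorized across replicates via the t statistic of the sample
    correlation.
    """
    if n_test <= 10:
        raise ValueError("n_test must exceed 10")
    rng = np.random.default_rng(seed)
    G = _hwe_genotypes(rng, maf, (n_reps, n_test)).astype(float)
    Y = sd_trait * rng.standard_normal((n_reps, n_test)) + beta * G
    Gc = G - G.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((Gc**2).sum(axis=1) * (Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Gc * Yc).sum(axis=1) / denom
        t = r * np.sqrt((n_test - 2) / np.maximum(1.0 - r**2, 1e-300))
    pv = 2.0 * stats.t.sf(np.abs(t), df=n_test - 2)
    pv = np.where(np.isfinite(pv), pv, 1.0)  # monomorphic draws never reject
    return float((pv < alpha).mean())


def beta_for_power(
    target_power: float,
    maf: float,
    n_test: int,
    alpha: float = 0.05,
    sd_trait: float = 1.0,
) -> float:
    """Invert the quantitative power curve: beta achieving ``target_power``.

    A target equal to alpha is the null (beta 0); power below alpha is
    unattainable, since alpha is the floor of the power curve.
    """
    if not 0.0 < alpha <= target_power < 1.0:
        raise ValueError("need alpha <= target_power < 1")
    if target_power == alpha:
        return 0.0

    def f(b: float) -> float:
        return power_quantitative(b, maf, sd_trait, n_test, alpha) - target_power

    hi = sd_trait / np.sqrt(2 * maf * (1 - maf))  # R^2 -> 1 bound
    return float(optimize.brentq(f, 0.0, 0.999 * hi, xtol=1e-10))


def power_calibration_curve(
    n_snps: int = 40,
    n_test: int = 2000,
    n_reps: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    power_range: tuple[float, float] = (0.05, 0.95),
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[pd.DataFrame, float]:
    """Slope-1 calibration: empirical replication rate vs analytic power.

    Designs ``n_snps`` quantitative-trait SNPs whose analytic power spans
    ``power_range`` (MAF uniform in ``maf_range``, beta solved per SNP), runs
    the forward simulation for each, and regresses empirical rate on analytic
    power by ordinary least squares.  Returns the per-SNP table and the
    fitted slope — near 1.0 when the analytic calculator is calibrated.
    """
    rng = np.random.default_rng(seed)
    targets = np.linspace(power_range[0], power_range[1], n_snps)
    mafs = rng.uniform(maf_range[0], maf_range[1], size=n_snps)
    rows = []
    for i, (tp, maf) in enumerate(zip(targets, mafs)):
        beta = beta_for_power(tp, maf, n_test, alpha)
        analytic = power_quantitative(beta, maf, 1.0, n_test, alpha)
        empirical = simulate_quantitative_replication_rate(
            beta, maf, n_test, n_reps=n_reps, alpha=alpha,
            seed=int(rng.integers(2**31 - 1)),
        )
        rows.append(
            {"snp": i, "maf": maf, "beta": beta,
             "analytic_power": analytic, "empirical_rate": empirical}
        )
    table = pd.DataFrame(rows)
    slope = float(
        np.polyfit(table["analytic_power"], table["empirical_rate"], 1)[0]
    )
    return table, slope


def sample_balanced_power_bins(
    powers: np.ndarray,
    per_bin: int = 19,
    bin_width: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Indices sampling up to ``per_bin`` SNPs from each power bracket."""
    rng = np.random.default_rng(seed)
    powers = np.asarray(powers, dtype=float)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    picks: list[np.ndarray] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        idx = np.flatnonzero((powers >= lo) & (powers < hi))
        if len(idx):
            picks.append(rng.choice(idx, size=min(per_bin, len(idx)), replace=False))
    return np.sort(np.concatenate(picks)) if picks else np.array([], dtype=int)


def _synthetic_exons(
    rng: np.random.Generator,
    genome_length: int,
    n_exons: int,
    exon_width: int,
) -> list[ExonInterval]:
    starts = np.sort(rng.integers(1, genome_length - exon_width, size=n_exons))
    return [ExonInterval("1", int(s), int(s + exon_width - 1)) for s in starts]


def _case_freq(p0: np.ndarray, or_: np.ndarray) -> np.ndarray:
    return or_ * p0 / (1.0 + p0 * (or_ - 1.0))


def generate_study_pair(
    n_snps: int = 50_000,
    frac_causal: float = 0.3,
    effect_scale: float = 0.08,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_disc: tuple[int, int] | int = (1868, 2938),
    n_test: tuple[int, int] | int = (2191, 1434),
    exon_frac_near: Optional[float] = None,
    near_bp: int = 10_000,
    trait_kind: str = "binary",
    sd_trait: float = 9.2,
    seed: int = 0,
    genome_length: int = 200_000_000,
    n_exons: int = 1500,
    exon_width: int = 150,
) -> SimStudyPair:
    """Synthetic discovery + test summary-statistic pair with known truth.

    Per SNP: MAF uniform in ``maf_range``; with probability ``frac_causal``
    the SNP is causal with true ln(OR) ~ Normal(0, effect_scale) (beta in
    trait units for quantitative traits), else null.  Observed effects in the
    two studies are independent asymptotic-normal draws around the truth with
    the standard error implied by each study's sample size; P-values are
    two-sided Wald.  With ``exon_frac_near`` set, each causal SNP is placed
    within ``near_bp`` of a synthetic exon with that probability (other SNPs
    uniform on the genome).  The default sample sizes mirror a modest
    case-control discovery (1,868/2,938) and test (2,191/1,434) design.

    The test study's allele labels are randomly swapped on half the SNPs so
    harmonization is actually exercised downstream.
    """
    if not 0.0 <= frac_causal <= 1.0:
        raise ValueError("frac_causal must lie in [0,1]")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_range[0], maf_range[1], size=n_snps)
    causal = rng.uniform(size=n_snps) < frac_causal

    if trait_kind == "binary":
        true_lnor = np.where(causal, rng.normal(0.0, effect_scale, size=n_snps), 0.0)
        true_effect = np.exp(true_lnor)
    elif trait_kind == "quantitative":
        true_beta = np.where(causal, rng.normal(0.0, effect_scale, size=n_snps), 0.0)
        true_effect = true_beta
    else:
        raise ValueError(f"unknown trait_kind {trait_kind!r}")

    exons = _synthetic_exons(rng, genome_length, n_exons, exon_width)
    pos = rng.integers(1, genome_length, size=n_snps)
    planted = np.zeros(n_snps, dtype=bool)
    if exon_frac_near is not None:
        starts, ends = merge_exons(exons)["1"]
        planted = causal & (rng.uniform(size=n_snps) < exon_frac_near)
        which = rng.integers(0, len(starts), size=n_snps)
        offset = rng.integers(-near_bp, near_bp + 1, size=n_snps)
        anchor = np.where(offset < 0, starts[which], ends[which])
        pos = np.where(planted, np.clip(anchor + offset, 1, genome_length), pos)

    order = np.argsort(pos, kind="stable")
    maf, causal, true_effect, pos, planted = (
        maf[order], causal[order], true_effect[order], pos[order], planted[order]
    )
    snp_ids = np.array([f"rs{i + 1:07d}" for i in range(n_snps)])

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    swap_test = rng.uniform(size=n_snps) < 0.5

    def _study(n, effect_true):
        if trait_kind == "binary":
            n_ca, n_co = n
            lnor = np.log(effect_true)
            p1 = _case_freq(maf, effect_true)
            se = np.sqrt(
                1.0 / (2 * n_ca * p1 * (1 - p1)) + 1.0 / (2 * n_co * maf * (1 - maf))
            )
            obs = lnor + rng.normal(size=n_snps) * se
            pv = 2.0 * stats.norm.sf(np.abs(obs / se))
            return np.exp(obs), pv, n_ca, n_co, n_ca + n_co
        n_tot = int(n)
        se = sd_trait / np.sqrt(n_tot * 2.0 * maf * (1.0 - maf))
        obs = effect_true + rng.normal(size=n_snps) * se
        pv = 2.0 * stats.norm.sf(np.abs(obs / se))
        return obs, pv, 0, 0, n_tot

    eff_d, pv_d, ca_d, co_d, tot_d = _study(n_disc, true_effect)
    eff_t, pv_t, ca_t, co_t, tot_t = _study(n_test, true_effect)
    pv_d = np.clip(pv_d, 1e-300, 1.0)
    pv_t = np.clip(pv_t, 1e-300, 1.0)

    discovery: list[SnpSummary] = []
    test: list[SnpSummary] = []
    for i in range(n_snps):
        ea, oa = _ALLELE_PAIRS[pair_idx[i]]
        discovery.append(
            SnpSummary(
                snp_id=snp_ids[i], chrom="1", pos=int(pos[i]),
                effect_allele=ea, other_allele=oa,
                effect=float(eff_d[i]), eaf=float(maf[i]), pvalue=float(pv_d[i]),
                n_cases=ca_d, n_controls=co_d, n_total=tot_d,
            )
        )
        if swap_test[i]:
            t_eff = 1.0 / eff_t[i] if trait_kind == "binary" else -eff_t[i]
            t_ea, t_oa, t_eaf = oa, ea, 1.0 - maf[i]
        else:
            t_eff, t_ea, t_oa, t_eaf = eff_t[i], ea, oa, maf[i]
        test.append(
            SnpSummary(
                snp_id=snp_ids[i], chrom="1", pos=int(pos[i]),
                effect_allele=t_ea, other_allele=t_oa,
                effect=float(t_eff), eaf=float(t_eaf), pvalue=float(pv_t[i]),
                n_cases=ca_t, n_controls=co_t, n_total=tot_t,
            )
        )

    truth = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": pos,
            "maf": maf,
            "causal": causal,
            "true_effect": true_effect,
            "near_exon_planted": planted,
        }
    )
    return SimStudyPair(
        discovery=discovery, test=test, truth=truth, exons=exons,
        seed=seed, trait_kind=trait_kind,
    )


def simulate_case_control_cohort(
    truth: pd.DataFrame,
    n_cases: int,
    n_controls: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Individual-level case/control dosages consistent with a truth table.

    Uses retrospective sampling: under the multiplicative per-allele risk
    model with independent SNPs and a rare disease, a case's alleles at a SNP
    with true odds ratio OR and population frequency p are Bernoulli with the
    tilted frequency p*OR / (1 + p*(OR-1)); controls carry the population
    frequency.  Returns (dosage DataFrame individuals x SNPs, status vector).
    """
    rng = np.random.default_rng(seed)
    maf = truth["maf"].to_numpy(dtype=float)
    orr = truth["true_effect"].to_numpy(dtype=float)
    p_case = _case_freq(maf, orr)
    g_cases = rng.binomial(2, p_case, size=(n_cases, len(maf)))
    g_controls = rng.binomial(2, maf, size=(n_controls, len(maf)))
    dosages = pd.DataFrame(
        np.vstack([g_cases, g_controls]).astype(float),
        columns=truth["snp_id"].tolist(),
        index=[f"ind{i + 1}" for i in range(n_cases + n_controls)],
    )
    status = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)])
    return dosages, status


def simulate_ld_block_genotypes(
    n_ind: int,
    n_snps: int,
    block_size: int = 10,
    rho: float = 0.9,
    maf: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Block-correlated HWE genotypes (Gaussian-copula haplotypes).

    SNPs within a block share a latent equicorrelated Gaussian (correlation
    ``rho``); blocks are independent.  Exists solely to exercise the LD
    pruner — the default study-pair generator keeps SNPs independent.
    """
    rng = np.random.default_rng(seed)
    thr = stats.norm.ppf(maf)
    G = np.zeros((n_ind, n_snps))
    for _ in range(2):  # two haplotypes per individual
        Z = np.empty((n_ind, n_snps))
        for b0 in range(0, n_snps, block_size):
            b1 = min(b0 + block_size, n_snps)
            shared = rng.standard_normal((n_ind, 1))
            own = rng.standard_normal((n_ind, b1 - b0))
            Z[:, b0:b1] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
        G += Z < thr
    return pd.DataFrame(
        G, columns=[f"rs{i + 1:05d}" for i in range(n_snps)],
        index=[f"ind{i + 1}" for i in range(n_ind)],
    )
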