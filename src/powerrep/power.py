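"""Per-SNP power to replicate a discovery effect in a test sample.

Case-control power uses the 1-df allelic (2x2 allele-count) chi-square test.
Given the discovery odds ratio OR and control minor-allele frequency p0, the
implied case allele frequency is

    p1 = OR * p0 / (1 + p0 * (OR - 1)),

and with 2*n_cases and 2*n_controls alleles in the test sample the
noncentrality parameter is

    lambda = (p1 - p0)^2 / [ pbar (1 - pbar) (1/(2 n_cases) + 1/(2 n_controls)) ],

with pbar the allele-count-weighted mean frequency.  Power is the mass of the
noncentral chi-square(1, lambda) beyond the central chi-square critical value
at alpha.  OR and MAF are rounded to 2 decimal places first (matching how the
discovery statistics are consumed); an OR that rounds to 1.00 is a null
effect and yields power exactly alpha.

Quantitative-trait power follows the noncentral-F convention of R's
``pwr.f2.test``: with SNP variance 2p(1-p) under Hardy-Weinberg equilibrium,
R^2 = beta^2 * 2p(1-p) / s^2, Cohen's f^2 = R^2/(1-R^2), numerator df u = 1,
denominator df v = N - 2 and noncentrality lambda = f^2 * (u + v + 1).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "power_binary",
    "power_quantitative",
    "filter_low_n",
    "power_decile",
    "build_power_records",
]


def _maybe_scalar(x: np.ndarray, scalar: bool):
    return float(x[0]) if scalar else x


def power_binary(
    or_disc,
    maf_disc,
    n_cases_test,
    n_controls_test,
    alpha: float = 0.05,
    round_inputs: bool = True,
):
    """Power of the allelic test in the test sample; accepts arrays.

    ``maf_disc`` is conventionally the discovery *minor*-allele frequency in
    (0, 0.5], with ``or_disc`` the odds ratio for that allele; any control
    frequency in (0, 1) is accepted, and the result is invariant to
    relabelling the alleles (p -> 1-p with OR -> 1/OR describes the same 2x2
    table).  ``round_inputs`` applies the 2-decimal rounding of OR and MAF; a
    frequency that rounds to 0 or 1 violates the MAF > 1% input filter and
    raises.
    """
    orr = np.asarray(or_disc, dtype=float)
    p0 = np.asarray(maf_disc, dtype=float)
    scalar = orr.ndim == 0 and p0.ndim == 0
    orr = np.atleast_1d(orr).copy()
    p0 = np.atleast_1d(p0).copy()
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0,1)")
    if np.any(orr <= 0):
        raise ValueError("odds ratios must be positive")
    if np.any((p0 <= 0) | (p0 >= 1)):
        raise ValueError("allele frequencies must lie in (0, 1)")
    if round_inputs:
        orr = np.round(orr, 2)
        p0 = np.round(p0, 2)
        if np.any((p0 <= 0) | (p0 >= 1)):
            raise ValueError("MAF rounds to 0.00; apply the MAF filter first")
    na = 2.0 * np.asarray(n_cases_test, dtype=float)
    nb = 2.0 * np.asarray(n_controls_test, dtype=float)
    if np.any(na <= 0) or np.any(nb <= 0):
        raise ValueError("case and control counts must be positive")
    p1 = orr * p0 / (1.0 + p0 * (orr - 1.0))
    pbar = (na * p1 + nb * p0) / (na + nb)
    lam = (p1 - p0) ** 2 / (pbar * (1.0 - pbar) * (1.0 / na + 1.0 / nb))
    crit = stats.chi2.isf(alpha, df=1)
    power = stats.ncx2.sf(crit, df=1, nc=np.maximum(lam, 1e-300))
    power = np.where(lam == 0.0, alpha, power)
    return _maybe_scalar(power, scalar)


def power_quantitative(
    beta_disc,
    eaf_disc,
    sd_trait: float,
    n_test,
    alpha: float = 0.05,
):
    """Noncentral-F power of a 1-df regression predictor; accepts arrays.

    ``beta_disc`` is in trait units per effect allele, ``sd_trait`` the trait
    standard deviation in the same units (9.2 cm for the height runs).
    """
    beta = np.asarray(beta_disc, dtype=float)
    p = np.asarray(eaf_disc, dtype=float)
    n = np.asarray(n_test, dtype=float)
    scalar = beta.ndim == 0 and p.ndim == 0 and n.ndim == 0
    beta, p, n = np.atleast_1d(beta), np.atleast_1d(p), np.atleast_1d(n)
    beta, p, n = np.broadcast_arrays(beta, p, n)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0,1)")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must lie in (0,1)")
    if sd_trait <= 0:
        raise ValueError("sd_trait must be positive")
    if np.any(n <= 2):
        raise ValueError("n_test must exceed 2")
    var_snp = 2.0 * p * (1.0 - p)
    r2 = beta**2 * var_snp / sd_trait**2
    if np.any(r2 >= 1.0):
        raise ValueError("implied R^2 >= 1; beta inconsistent with sd_trait")
    f2 = r2 / (1.0 - r2)
    u = 1.0
    v = n - 2.0
    lam = f2 * (u + v + 1.0)
    crit = stats.f.isf(alpha, dfn=u, dfd=v)
    power = stats.ncf.sf(crit, dfn=u, dfd=v, nc=np.maximum(lam, 1e-300))
    power = np.where(lam == 0.0, alpha, power)
    return _maybe_scalar(power, scalar)


def filter_low_n(
    frame: pd.DataFrame, fraction: float = 0.20, n_col: str = "n_total_test"
) -> pd.DataFrame:
    """Drop the lowest-sample-size fraction of SNPs, keeping ties at the cut.

    The cut value is the n of the first retained rank, so SNPs tied with it
    survive; with all n equal nothing is dropped.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    if fraction == 0.0 or frame.empty:
        return frame.copy()
    n = frame[n_col].to_numpy()
    k = int(math.floor(fraction * len(n)))
    if k == 0:
        return frame.copy()
    cut = np.sort(n, kind="stable")[k]
    return frame[frame[n_col] >= cut].copy()


def power_decile(power) -> np.ndarray:
    """Decile index 0-9 for power in [0,1]; power 1.0 falls in the top bin."""
    p = np.atleast_1d(np.asarray(power, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("power outside [0,1]")
    return np.minimum((p * 10).astype(int), 9)


def build_power_records(
    pairs: pd.DataFrame,
    trait_kind: str = "binary",
    alpha_power: float = 0.05,
    alpha_replication: float = 0.05,
    sd_trait: float | None = None,
    round_inputs: bool = True,
) -> pd.DataFrame:
    """Attach per-SNP power, replication flag and power decile to a pair table.

    Binary traits: the discovery effect is re-expressed on the minor allele
    (eaf > 0.5 inverts the OR) before the rounding rule, and the test-study
    case/control counts set the sample size.  ``replicated`` is simply
    ``pvalue_test < alpha_replication``.
    """
    out = pairs.copy()
    if trait_kind == "binary":
        eaf = out["eaf_disc"].to_numpy(dtype=float)
        orr = out["effect_disc"].to_numpy(dtype=float)
        flip = eaf > 0.5
        maf = np.where(flip, 1.0 - eaf, eaf)
        orr = np.where(flip, 1.0 / orr, orr)
        out["power"] = power_binary(
            orr,
            maf,
            out["n_cases_test"].to_numpy(),
            out["n_controls_test"].to_numpy(),
            alpha=alpha_power,
            round_inputs=round_inputs,
        )
    elif trait_kind == "quantitative":
        if sd_trait is None:
            raise ValueError("sd_trait is required for quantitative traits")
        out["power"] = power_quantitative(
            out["effect_disc"].to_numpy(dtype=float),
            out["eaf_disc"].to_numpy(dtype=float),
            sd_trait,
            out["n_total_test"].to_numpy(dtype=float),
            alpha=alpha_power,
        )
    else:
        raise ValueError(f"unknown trait_kind {trait_kind!r}")
    out["replicated"] = out["pvalue_test"] < alpha_replication
    out["power_decile"] = power_decile(out["power"].to_numpy())
    return out
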