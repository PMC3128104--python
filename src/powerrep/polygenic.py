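"""Polygenic scoring from discovery log-odds-ratios.

An individual's score at a discovery P-value threshold is the mean, over the
SNPs passing that threshold with a non-missing dosage, of ln(OR_discovery)
times the effect-allele dosage (the PLINK ``--score`` averaging convention;
a sum variant is available).  Score-phenotype association is a logistic
regression of case/control status on the score, reported with a Wald P-value
and Nagelkerke's pseudo-R^2.  Progressive thresholds give nested SNP subsets,
tracing out the variance-explained curve as weakly associated SNPs are added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError


@dataclass(frozen=True)
class ScoreProfile:
    individual_id: str
    score: float  # NaN when no usable SNPs
    n_snps_used: int
    threshold: float


class SeparationError(RuntimeError):
    """The score perfectly separates cases from controls."""


def compute_scores(
    dosages: pd.DataFrame,
    effects: Mapping[str, float],
    pvalues: Mapping[str, float],
    threshold: float,
    mode: str = "mean",
) -> list[ScoreProfile]:
    """Per-individual score over SNPs with discovery P <= threshold.

    ``dosages`` is individuals x SNPs in [0, 2] (NaN = missing); ``effects``
    maps snp_id -> ln(OR); ``pvalues`` maps snp_id -> discovery P.  An empty
    SNP subset at the threshold is an error naming it; an individual with no
    non-missing included dosage gets a NaN score.
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    included = [
        s for s in dosages.columns if s in effects and pvalues.get(s, 1.0) <= threshold
    ]
    if not included:
        raise ValueError(f"no SNPs pass discovery P <= {threshold}")
    D = dosages[included].to_numpy(dtype=float)
    w = np.array([effects[s] for s in included])
    contrib = D * w
    n_used = np.isfinite(D).sum(axis=1)
    total = np.nansum(contrib, axis=1)
    with np.errstate(invalid="ignore"):
        score = total / n_used if mode == "mean" else total
    score = np.where(n_used == 0, np.nan, score)
    return [
        ScoreProfile(str(ind), float(s), int(k), threshold)
        for ind, s, k in zip(dosages.index, score, n_used)
    ]


def score_association(
    scores: Sequence[ScoreProfile], phenotype: Sequence[int]
) -> tuple[float, float]:
    """(Wald P, Nagelkerke pseudo-R^2) of status regressed on the score."""
    s = np.array([p.score for p in scores], dtype=float)
    y = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least two individuals of each phenotype class")
    if np.ptp(s) == 0:
        raise ValueError("score is constant across individuals")
    # Standardize internally: the Wald P and pseudo-R^2 are invariant to
    # affine rescaling, and a unit-scale predictor makes the separation
    # heuristic below meaningful regardless of the score's numeric range.
    s = (s - s.mean()) / s.std()
    X = np.column_stack([np.ones_like(s), s])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError("score perfectly separates the phenotype classes") from exc
    if (
        not res.mle_retvals.get("converged", False)
        or not np.all(np.isfinite(res.bse))
        or abs(res.params[1]) > 50
    ):
        raise SeparationError("logistic fit did not converge (quasi-separation)")
    pvalue = float(res.pvalues[1])
    r2 = nagelkerke_r2(res.llf, res.llnull, len(y))
    return pvalue, r2


def nagelkerke_r2(llf: float, llnull: float, n: int) -> float:
    """Nagelkerke's rescaled Cox-Snell pseudo-R^2 (what rms::lrm reports)."""
    cox_snell = 1.0 - np.exp(2.0 * (llnull - llf) / n)
    max_cs = 1.0 - np.exp(2.0 * llnull / n)
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


def cox_snell_r2(llf: float, llnull: float, n: int) -> float:
    return float(1.0 - np.exp(2.0 * (llnull - llf) / n))


def progressive_thresholds(
    dosages: pd.DataFrame,
    effects: Mapping[str, float],
    pvalues: Mapping[str, float],
    phenotype: Sequence[int],
    thresholds: Sequence[float] = (1e-4, 1e-3, 1e-2, 0.1, 0.5, 1.0),
    mode: str = "mean",
) -> pd.DataFrame:
    """Score-association curve across a ladder of discovery P cutoffs.

    Thresholds whose SNP subset is empty are skipped (recorded with NaN).
    """
    rows = []
    for thr in thresholds:
        try:
            profiles = compute_scores(dosages, effects, pvalues, thr, mode=mode)
            pv, r2 = score_association(profiles, phenotype)
            n_snps = profiles[0].n_snps_used if profiles else 0
        except ValueError:
            pv, r2, n_snps = np.nan, np.nan, 0
        rows.append(
            {"threshold": thr, "n_snps": n_snps, "pvalue": pv, "pseudo_r2": r2}
        )
    return pd.DataFrame(rows)
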