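"""Replication-versus-power models and excess-replication accounting.

The central hypothesis test of the framework is a logistic regression of a
per-SNP replication indicator (test-study P below alpha) on the power to
detect that SNP computed from the discovery study.  The model ladder:

=====  =======================================================  =============
tag    terms (besides the intercept)                            SNP subset
=====  =======================================================  =============
I      power                                                    all
II     power, near_exon, power x near_exon                      all
III    power                                                    same-direction
IV     power, near_exon, power x near_exon                      same-direction
M1     same_direction                                           direction defined
M2     power, same_direction, power x same_direction            direction defined
=====  =======================================================  =============

Each fitted model yields ONE headline P-value per term; SNPs are never tested
individually, so no multiple-testing correction across SNPs applies.

The module also counts excess replication in high-power strata (observed
replicated count minus the count expected under the genome-wide average
replication rate), provides a permutation negative control that shuffles the
replication labels across SNPs, a greedy sliding-window LD pruner, and a
smoothing-spline summary used for replication-proportion plots.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import UnivariateSpline
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exon_annotation import near_exon_col

MODEL_TAGS = ("I", "II", "III", "IV", "M1", "M2")

_SUBSET = {
    "I": "all",
    "II": "all",
    "III": "same_direction",
    "IV": "same_direction",
    "M1": "direction_defined",
    "M2": "direction_defined",
}


@dataclass
class EnrichmentFit:
    """A fitted replication model: per-term (estimate, SE, P) plus metadata.

    ``pvalues`` are withheld (None) when the optimizer failed to converge or
    the fit was perfectly separated.
    """

    model_tag: str
    coefficients: dict[str, tuple[float, float, Optional[float]]]
    n_snps: int
    snp_subset: str
    near_exon_threshold_bp: Optional[int] = None
    converged: bool = True
    pvalue_kind: str = "wald"

    def term(self, name: str) -> tuple[float, float, Optional[float]]:
        return self.coefficients[name]

    def to_dict(self) -> dict:
        return {
            "model_tag": self.model_tag,
            "coefficients": {
                k: {"estimate": v[0], "se": v[1], "pvalue": v[2]}
                for k, v in self.coefficients.items()
            },
            "n_snps": self.n_snps,
            "snp_subset": self.snp_subset,
            "near_exon_threshold_bp": self.near_exon_threshold_bp,
            "converged": self.converged,
            "pvalue_kind": self.pvalue_kind,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _model_frame(
    records: pd.DataFrame, model_tag: str, near_exon_threshold_bp: Optional[int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = records
    if model_tag in ("III", "IV"):
        df = df[df["same_direction"].notna() & (df["same_direction"] == True)]  # noqa: E712
    elif model_tag in ("M1", "M2"):
        df = df[df["same_direction"].notna()]
    if df.empty:
        raise ValueError(f"no usable records for model {model_tag}")
    X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    if model_tag in ("I", "II", "III", "IV", "M2"):
        X["power"] = df["power"].to_numpy(dtype=float)
    if model_tag in ("II", "IV"):
        if near_exon_threshold_bp is None:
            raise ValueError(f"model {model_tag} needs a near-exon threshold")
        col = near_exon_col(near_exon_threshold_bp)
        if col not in df.columns:
            raise ValueError(f"missing column {col}; annotate SNPs first")
        near = df[col].to_numpy(dtype=float)
        X["near_exon"] = near
        X["power_x_near_exon"] = X["power"].to_numpy() * near
    if model_tag in ("M1", "M2"):
        sd = df["same_direction"].astype(bool).to_numpy(dtype=float)
        X["same_direction"] = sd
        if model_tag == "M2":
            X["power_x_same_direction"] = X["power"].to_numpy() * sd
    return df, X


def fit_model(
    records: pd.DataFrame,
    model_tag: str,
    near_exon_threshold_bp: Optional[int] = None,
    use_lrt: bool = False,
) -> EnrichmentFit:
    """Maximum-likelihood logistic fit of ``replicated`` on the model's terms.

    P-values are Wald by default; ``use_lrt`` switches every non-intercept
    term to a likelihood-ratio test against the model without it.
    """
    if model_tag not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {model_tag!r}")
    if records.empty:
        raise ValueError("no records to fit")
    df, X = _model_frame(records, model_tag, near_exon_threshold_bp)
    y = df["replicated"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("replication indicator is constant; nothing to fit")
    res, ok = _fit_logit(y, X)
    coeffs: dict[str, tuple[float, float, Optional[float]]] = {}
    for term in X.columns:
        est = float(res.params[term]) if res is not None else float("nan")
        se = float(res.bse[term]) if res is not None else float("nan")
        pv: Optional[float] = float(res.pvalues[term]) if ok else None
        coeffs[term] = (est, se, pv)
    if ok and use_lrt:
        for term in X.columns:
            if term == "intercept":
                continue
            res0, ok0 = _fit_logit(y, X.drop(columns=[term]))
            if not ok0:
                coeffs[term] = (coeffs[term][0], coeffs[term][1], None)
                continue
            lr = 2.0 * (res.llf - res0.llf)
            coeffs[term] = (
                coeffs[term][0],
                coeffs[term][1],
                float(stats.chi2.sf(max(lr, 0.0), df=1)),
            )
    return EnrichmentFit(
        model_tag=model_tag,
        coefficients=coeffs,
        n_snps=len(df),
        snp_subset=_SUBSET[model_tag],
        near_exon_threshold_bp=near_exon_threshold_bp,
        converged=ok,
        pvalue_kind="lrt" if use_lrt else "wald",
    )


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Logit fit returning (results, converged-and-identified flag)."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return None, False
    ok = bool(res.mle_retvals.get("converged", False))
    # Runaway coefficients signal quasi-separation even when the optimizer
    # reports convergence.
    if ok and (np.abs(res.params).max() > 50 or not np.all(np.isfinite(res.bse))):
        ok = False
    return res, ok


@dataclass
class ExcessReport:
    """Observed-minus-expected replication in a high-power stratum."""

    power_threshold: float
    n_total: int
    n_high: int
    n_replicated_high: int
    overall_rate: float
    expected: float
    excess: float
    per_decile_counts: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def high_rate(self) -> float:
        return self.n_replicated_high / self.n_high if self.n_high else 0.0

    @property
    def high_fraction(self) -> float:
        return self.n_high / self.n_total if self.n_total else 0.0

    @property
    def false_fraction(self) -> float:
        """Share of high-power replications expected under the average rate."""
        return self.expected / self.n_replicated_high if self.n_replicated_high else 0.0

    @property
    def excess_rounded(self) -> int:
        return int(round(self.excess))

    def to_dict(self) -> dict:
        return {
            "power_threshold": self.power_threshold,
            "n_total": self.n_total,
            "n_high": self.n_high,
            "n_replicated_high": self.n_replicated_high,
            "overall_rate": self.overall_rate,
            "expected": self.expected,
            "excess": self.excess,
            "excess_rounded": self.excess_rounded,
            "high_rate": self.high_rate,
            "high_fraction": self.high_fraction,
            "false_fraction": self.false_fraction,
            "per_decile_counts": [list(t) for t in self.per_decile_counts],
        }


def excess_from_counts(
    n_total: int,
    n_high: int,
    n_replicated_high: int,
    overall_rate: float,
    power_threshold: float = 0.6,
    per_decile_counts: Optional[list[tuple[int, int, int]]] = None,
) -> ExcessReport:
    """Excess arithmetic from marginal counts (expected = n_high * rate)."""
    expected = n_high * overall_rate
    return ExcessReport(
        power_threshold=power_threshold,
        n_total=n_total,
        n_high=n_high,
        n_replicated_high=n_replicated_high,
        overall_rate=overall_rate,
        expected=expected,
        excess=n_replicated_high - expected,
        per_decile_counts=per_decile_counts or [],
    )


def excess_by_power(records: pd.DataFrame, power_threshold: float = 0.6) -> ExcessReport:
    """Count excess replicated SNPs above a power threshold.

    The expected count applies the replication rate over ALL records to the
    high-power stratum; per-decile counts cover the full power range.
    """
    if not 0.0 < power_threshold < 1.0:
        raise ValueError("power_threshold must lie in (0,1)")
    power = records["power"].to_numpy(dtype=float)
    rep = records["replicated"].to_numpy(dtype=bool)
    n_total = len(records)
    overall = rep.mean() if n_total else 0.0
    high = power >= power_threshold
    n_high = int(high.sum())
    n_rep_high = int(rep[high].sum())
    from .power import power_decile  # local import avoids a cycle

    dec = power_decile(power)
    per_decile = [
        (d, int((dec == d).sum()), int(rep[dec == d].sum())) for d in range(10)
    ]
    return ExcessReport(
        power_threshold=power_threshold,
        n_total=n_total,
        n_high=n_high,
        n_replicated_high=n_rep_high,
        overall_rate=float(overall),
        expected=float(n_high * overall),
        excess=float(n_rep_high - n_high * overall),
        per_decile_counts=per_decile,
    )


def permutation_control(
    records: pd.DataFrame,
    n_perm: int,
    seed: int,
    model_tag: str = "I",
    near_exon_threshold_bp: Optional[int] = None,
    term: str = "power",
) -> np.ndarray:
    """Model refits with the replication labels randomly permuted across SNPs.

    Breaking the SNP-to-label link preserves the marginal replication rate
    while destroying any power-replication association, so the returned
    P-values for ``term`` are a finite-sample null reference for the observed
    fit.  (With individual-level data the analogous control permutes
    case/control status; at summary scale label permutation is the available
    surrogate.)
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    shuffled = records.copy()
    labels = records["replicated"].to_numpy()
    out = np.empty(n_perm)
    for i in range(n_perm):
        shuffled["replicated"] = rng.permutation(labels)
        fit = fit_model(shuffled, model_tag, near_exon_threshold_bp)
        pv = fit.term(term)[2]
        out[i] = np.nan if pv is None else pv
    return out


def ld_prune(
    genotypes,
    snp_ids: Optional[Sequence[str]] = None,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.5,
) -> list[str]:
    """Greedy sliding-window LD pruning on an individuals-by-SNPs dosage matrix.

    Within each window every pair with r^2 >= ``r2_max`` loses its later SNP
    (input order is kept deterministic: the earlier SNP survives); the window
    then advances by ``step`` SNPs.  SNPs must already be ordered by
    chromosome and position.
    """
    if window < 2:
        raise ValueError("window must be at least 2 SNPs")
    if step < 1:
        raise ValueError("step must be >= 1")
    if isinstance(genotypes, pd.DataFrame):
        ids = list(genotypes.columns)
        G = genotypes.to_numpy(dtype=float)
    else:
        G = np.asarray(genotypes, dtype=float)
        ids = list(snp_ids) if snp_ids is not None else [str(i) for i in range(G.shape[1])]
    n_snps = G.shape[1]
    kept = np.ones(n_snps, dtype=bool)
    for start in range(0, max(n_snps - 1, 1), step):
        idx = [j for j in range(start, min(start + window, n_snps)) if kept[j]]
        if len(idx) < 2:
            continue
        sub = G[:, idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(sub, rowvar=False)
        r2 = r**2
        for a in range(len(idx)):
            if not kept[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if kept[idx[b]] and np.isfinite(r2[a, b]) and r2[a, b] >= r2_max:
                    kept[idx[b]] = False
    return [ids[j] for j in range(n_snps) if kept[j]]


def spline_summary(
    records: pd.DataFrame,
    n_grid: int = 101,
    smoothing: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic smoothing spline of the replication indicator on power.

    Returns an ascending grid covering [0, 1] and the smoothed replication
    proportion on it (clipped to [0, 1], constant-extrapolated beyond the
    observed power range).  Descriptive only — no inference is attached.
    """
    if len(records) < 50:
        raise ValueError("spline summary needs at least 50 records")
    power = records["power"].to_numpy(dtype=float)
    rep = records["replicated"].to_numpy(dtype=float)
    agg = (
        pd.DataFrame({"power": np.round(power, 4), "rep": rep})
        .groupby("power")["rep"]
        .agg(["mean", "size"])
        .reset_index()
    )
    x = agg["power"].to_numpy()
    y = agg["mean"].to_numpy()
    w = np.sqrt(agg["size"].to_numpy(dtype=float))
    grid = np.linspace(0.0, 1.0, n_grid)
    if len(x) == 1:
        return grid, np.full(n_grid, y[0])
    k = min(3, len(x) - 1)
    spl = UnivariateSpline(x, y, w=w, k=k, s=smoothing, ext=3)
    return grid, np.clip(spl(grid), 0.0, 1.0)
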