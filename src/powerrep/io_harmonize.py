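"""Summary-statistic IO and two-study harmonization.

A replication-enrichment analysis starts from two association-summary tables
(a *discovery* and a *test* study) that must be aligned onto a shared SNP set
with a common effect allele before power can be computed from one and
replication assessed in the other.  This module owns that plumbing: reading
and writing tab-delimited summary tables, aligning effect alleles (inverting
the odds ratio / negating beta when the two studies report opposite alleles),
and the discovery-side minor-allele-frequency filter.

SNPs are matched on identifier (rsID), not position.  Strand-ambiguous A/T and
C/G ("palindromic") SNPs are kept by default and aligned purely by allele
label; a ``palindromic="drop"`` switch removes them instead, since without
strand information their alignment cannot be verified.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Column names used in powerrep's native tab-delimited dialect.
DEFAULT_COLUMNS: dict[str, str] = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "effect": "effect",
    "eaf": "eaf",
    "pvalue": "pvalue",
    "n_cases": "n_cases",
    "n_controls": "n_controls",
    "n_total": "n_total",
}

#: PLINK ``.assoc.logistic``-style dialect (joined with allele-2/frequency
#: columns as emitted by ``--assoc`` + ``--freq`` merges).
PLINK_ASSOC_COLUMNS: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "effect": "OR",
    "eaf": "MAF",
    "pvalue": "P",
    "n_total": "NMISS",
}

_MANDATORY = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "effect",
    "eaf",
    "pvalue",
    "n_total",
)


@dataclass(frozen=True)
class SnpSummary:
    """One SNP's association record in one study.

    ``effect`` is on its natural scale: an odds ratio for binary traits, a
    beta in trait units for quantitative traits.  ``eaf`` is the frequency of
    ``effect_allele``.  ``n_cases``/``n_controls`` are zero for quantitative
    studies.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    effect: float
    eaf: float
    pvalue: float
    n_cases: int = 0
    n_controls: int = 0
    n_total: int = 0

    def validate(self, trait_kind: str = "binary") -> None:
        """Raise ``ValueError`` on the first violated invariant."""
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: bad effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: bad other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: identical alleles")
        if self.pos <= 0:
            raise ValueError(f"{self.snp_id}: nonpositive position")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.snp_id}: eaf {self.eaf} outside (0,1)")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"{self.snp_id}: pvalue {self.pvalue} outside (0,1]")
        if not math.isfinite(self.effect):
            raise ValueError(f"{self.snp_id}: non-finite effect")
        if trait_kind == "binary":
            if self.effect <= 0:
                raise ValueError(f"{self.snp_id}: odds ratio must be positive")
            if self.n_total < self.n_cases + self.n_controls:
                raise ValueError(f"{self.snp_id}: n_total < n_cases + n_controls")
        if self.n_cases < 0 or self.n_controls < 0 or self.n_total <= 0:
            raise ValueError(f"{self.snp_id}: bad sample sizes")

    @property
    def maf(self) -> float:
        """Minor-allele frequency, min(eaf, 1 - eaf)."""
        return min(self.eaf, 1.0 - self.eaf)

    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class HarmonizedPair:
    """Discovery/test records aligned to a common effect allele.

    ``same_direction`` is ``None`` for null-effect SNPs (OR exactly 1 or beta
    exactly 0 in either study), whose direction is undefined; such SNPs are
    excluded from direction-of-effect models downstream.
    """

    snp_id: str
    chrom: str
    pos: int
    discovery: SnpSummary
    test: SnpSummary
    same_direction: Optional[bool]


def _effect_sign(effect: float, trait_kind: str) -> int:
    if trait_kind == "binary":
        if effect == 1.0:
            return 0
        return 1 if effect > 1.0 else -1
    if effect == 0.0:
        return 0
    return 1 if effect > 0 else -1


def direction_agreement(
    disc: SnpSummary, test: SnpSummary, trait_kind: str
) -> Optional[bool]:
    """Sign agreement of the aligned effects; ``None`` if either is null."""
    s1 = _effect_sign(disc.effect, trait_kind)
    s2 = _effect_sign(test.effect, trait_kind)
    if s1 == 0 or s2 == 0:
        return None
    return s1 == s2


def read_summary(
    path: str | Path,
    trait_kind: str = "binary",
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> list[SnpSummary]:
    """Read a tab-delimited summary-statistic table.

    Rows that fail parsing or the :class:`SnpSummary` invariants are dropped
    and counted in a log message; a missing mandatory column is a hard error
    naming the column.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    for field in _MANDATORY:
        if cols[field] not in raw.columns:
            raise ValueError(
                f"{path}: missing mandatory column {cols[field]!r} (field {field})"
            )
    have_case_cols = cols["n_cases"] in raw.columns and cols["n_controls"] in raw.columns

    records: list[SnpSummary] = []
    n_dropped = 0
    for row in raw.itertuples(index=False):
        row = dict(zip(raw.columns, row))
        try:
            rec = SnpSummary(
                snp_id=str(row[cols["snp_id"]]),
                chrom=str(row[cols["chrom"]]),
                pos=int(row[cols["pos"]]),
                effect_allele=str(row[cols["effect_allele"]]).upper(),
                other_allele=str(row[cols["other_allele"]]).upper(),
                effect=float(row[cols["effect"]]),
                eaf=float(row[cols["eaf"]]),
                pvalue=float(row[cols["pvalue"]]),
                n_cases=int(row[cols["n_cases"]]) if have_case_cols else 0,
                n_controls=int(row[cols["n_controls"]]) if have_case_cols else 0,
                n_total=int(row[cols["n_total"]]),
            )
            rec.validate(trait_kind)
        except (ValueError, TypeError) as exc:
            n_dropped += 1
            logger.debug("dropped row: %s", exc)
            continue
        records.append(rec)
    if n_dropped:
        logger.warning("%s: dropped %d of %d rows failing invariants",
                       path, n_dropped, len(raw))
    return records


def write_summary(records: Sequence[SnpSummary], path: str | Path) -> None:
    """Write records in the native dialect; floats use shortest round-trip repr."""
    fields = list(DEFAULT_COLUMNS)
    with open(path, "w") as fh:
        fh.write("\t".join(fields) + "\n")
        for r in records:
            fh.write("\t".join(str(getattr(r, f)) for f in fields) + "\n")


def _flip_to(disc: SnpSummary, test: SnpSummary, trait_kind: str) -> SnpSummary:
    """Re-express ``test`` on ``disc``'s effect allele (alleles are swapped)."""
    effect = 1.0 / test.effect if trait_kind == "binary" else -test.effect
    return replace(
        test,
        effect_allele=test.other_allele,
        other_allele=test.effect_allele,
        effect=effect,
        eaf=1.0 - test.eaf,
    )


def harmonize(
    disc: Sequence[SnpSummary],
    test: Sequence[SnpSummary],
    trait_kind: str = "binary",
    palindromic: str = "keep",
) -> list[HarmonizedPair]:
    """Intersect two studies on snp_id and align effect alleles.

    When the two studies report swapped alleles the test effect is inverted
    (OR -> 1/OR, beta -> -beta) and its allele frequency complemented.  Allele
    pairs that are neither identical nor swapped are excluded and logged.
    """
    if not disc or not test:
        raise ValueError("harmonize requires non-empty discovery and test lists")
    if palindromic not in ("keep", "drop"):
        raise ValueError(f"unknown palindromic policy {palindromic!r}")
    test_by_id = {t.snp_id: t for t in test}
    pairs: list[HarmonizedPair] = []
    n_mismatch = 0
    n_palindromic = 0
    for d in disc:
        t = test_by_id.get(d.snp_id)
        if t is None:
            continue
        if palindromic == "drop" and d.is_palindromic():
            n_palindromic += 1
            continue
        if (t.effect_allele, t.other_allele) == (d.effect_allele, d.other_allele):
            aligned = t
        elif (t.other_allele, t.effect_allele) == (d.effect_allele, d.other_allele):
            aligned = _flip_to(d, t, trait_kind)
        else:
            n_mismatch += 1
            logger.debug(
                "%s: allele mismatch %s/%s vs %s/%s",
                d.snp_id, d.effect_allele, d.other_allele,
                t.effect_allele, t.other_allele,
            )
            continue
        pairs.append(
            HarmonizedPair(
                snp_id=d.snp_id,
                chrom=d.chrom,
                pos=d.pos,
                discovery=d,
                test=aligned,
                same_direction=direction_agreement(d, aligned, trait_kind),
            )
        )
    if n_mismatch:
        logger.warning("excluded %d SNPs with incompatible allele pairs", n_mismatch)
    if n_palindromic:
        logger.info("dropped %d palindromic SNPs", n_palindromic)
    if not pairs:
        logger.warning("no SNPs shared between discovery and test studies")
    return pairs


def apply_maf_filter(
    pairs: Sequence[HarmonizedPair], min_maf: float
) -> list[HarmonizedPair]:
    """Retain pairs whose *discovery* minor-allele frequency exceeds ``min_maf``."""
    if not 0.0 <= min_maf < 0.5:
        raise ValueError("min_maf must lie in [0, 0.5)")
    return [p for p in pairs if p.discovery.maf > min_maf]


def pairs_to_frame(pairs: Sequence[HarmonizedPair]) -> pd.DataFrame:
    """Flatten harmonized pairs into the tabular form downstream modules use."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "snp_id": p.snp_id,
                "chrom": p.chrom,
                "pos": p.pos,
                "effect_disc": p.discovery.effect,
                "eaf_disc": p.discovery.eaf,
                "pvalue_disc": p.discovery.pvalue,
                "n_cases_disc": p.discovery.n_cases,
                "n_controls_disc": p.discovery.n_controls,
                "n_total_disc": p.discovery.n_total,
                "effect_test": p.test.effect,
                "eaf_test": p.test.eaf,
                "pvalue_test": p.test.pvalue,
                "n_cases_test": p.test.n_cases,
                "n_controls_test": p.test.n_controls,
                "n_total_test": p.test.n_total,
                "same_direction": p.same_direction,
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["same_direction"] = frame["same_direction"].astype("boolean")
    return frame


def write_pairs(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if "same_direction" in frame.columns:
        frame["same_direction"] = frame["same_direction"].astype("boolean")
    return frame
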