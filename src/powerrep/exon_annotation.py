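"""Distance-to-nearest-exon annotation.

Each SNP is annotated with the gap, in basepairs, to the closest exon on its
chromosome within a search window (default 1 Mb); a SNP inside an exon gets
distance 0, and a SNP with no exon in the window gets a missing-value
sentinel (NaN).  Boolean near-exon indicator columns at configurable
thresholds (the headline strata are 2 kb and 25 kb) feed the interaction
models in :mod:`powerrep.enrichment`.

Coordinate conventions: SNP positions are 1-based; BED and refGene exon
intervals arrive 0-based half-open (UCSC convention) and are converted to
1-based inclusive on read.  Overlapping exons are merged before search, so
only the distance — never the identity — of the nearest exon is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExonInterval:
    """One exon, 1-based inclusive coordinates on the SNP convention."""

    chrom: str
    start: int
    end: int
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")


def read_bed(path: str | Path) -> list[ExonInterval]:
    """Read a BED3+ file (0-based half-open) into 1-based intervals."""
    exons = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else None
            exons.append(ExonInterval(chrom, start + 1, end, name))
    return exons


def read_refgene(path: str | Path) -> list[ExonInterval]:
    """Read a UCSC refGene table, exploding exonStarts/exonEnds comma lists.

    Accepts both the 16-column dump with a leading ``bin`` integer and the
    15-column variant without it; no header expected.
    """
    exons = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            # A leading bin column is an integer where `name` would be text.
            offset = 1 if parts[0].lstrip("-").isdigit() else 0
            name = parts[offset + 0]
            chrom = parts[offset + 2]
            starts = [int(s) for s in parts[offset + 8].rstrip(",").split(",") if s]
            ends = [int(s) for s in parts[offset + 9].rstrip(",").split(",") if s]
            for s, e in zip(starts, ends):
                exons.append(ExonInterval(chrom, s + 1, e, name))
    return exons


def merge_exons(exons: Iterable[ExonInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge overlapping/adjacent intervals per chromosome.

    Returns ``{chrom: (starts, ends)}`` with both arrays sorted ascending.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for ex in exons:
        by_chrom.setdefault(ex.chrom, []).append((ex.start, ex.end))
    merged = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        out: list[list[int]] = []
        for s, e in ivals:
            if out and s <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        arr = np.asarray(out, dtype=np.int64)
        merged[chrom] = (arr[:, 0], arr[:, 1])
    return merged


def _normalize_snps(snps) -> pd.DataFrame:
    if isinstance(snps, pd.DataFrame):
        return snps[["snp_id", "chrom", "pos"]].reset_index(drop=True)
    return pd.DataFrame(list(snps), columns=["snp_id", "chrom", "pos"])


def nearest_exon_distance(
    snps,
    exons: Iterable[ExonInterval],
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Gap to the closest exon within ``window_bp``, per SNP.

    ``snps`` is a DataFrame with ``snp_id``/``chrom``/``pos`` columns or an
    iterable of ``(snp_id, chrom, pos)`` tuples.  Returns the input columns
    plus ``distance_bp`` (float; 0 inside an exon, NaN when no exon lies
    within the window).  Chromosomes absent from the exon table yield NaN for
    all their SNPs, with a warning.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    frame = _normalize_snps(snps)
    merged = merge_exons(exons)
    dist = np.full(len(frame), np.nan)
    missing_chroms = []
    for chrom, idx in frame.groupby("chrom", sort=False).groups.items():
        pos = frame.loc[idx, "pos"].to_numpy(dtype=np.int64)
        if chrom not in merged:
            missing_chroms.append(chrom)
            continue
        starts, ends = merged[chrom]
        # Interval i is "before or at" pos when starts[i] <= pos.
        k = np.searchsorted(starts, pos, side="right")
        left_gap = np.full(len(pos), np.inf)
        has_left = k > 0
        left_end = ends[np.maximum(k - 1, 0)]
        inside = has_left & (pos <= left_end)
        left_gap[has_left] = pos[has_left] - left_end[has_left]
        left_gap[inside] = 0.0
        right_gap = np.full(len(pos), np.inf)
        has_right = k < len(starts)
        right_gap[has_right] = starts[np.minimum(k, len(starts) - 1)][has_right] - pos[has_right]
        d = np.minimum(left_gap, right_gap)
        d[d > window_bp] = np.nan
        dist[np.asarray(idx)] = d
    if missing_chroms:
        logger.warning(
            "no exons on chromosome(s) %s; SNPs there get no distance",
            ", ".join(map(str, missing_chroms)),
        )
    out = frame.reset_index(drop=True)
    out["distance_bp"] = dist
    return out


def near_exon_col(threshold_bp: int) -> str:
    """Column name carrying the <=threshold indicator."""
    return f"near_exon_{threshold_bp}"


def add_near_exon_columns(
    frame: pd.DataFrame,
    thresholds: Sequence[int],
    distance_col: str = "distance_bp",
) -> pd.DataFrame:
    """Add one boolean ``near_exon_<d>`` column per threshold.

    A missing distance (no exon within the search window) maps to False at
    every threshold.  Thresholds must be positive and ascending, which makes
    the columns monotone: near at d1 implies near at d2 >= d1.
    """
    grid = list(thresholds)
    if any(d <= 0 for d in grid):
        raise ValueError("thresholds must be positive")
    if grid != sorted(grid):
        raise ValueError("thresholds must be sorted ascending")
    out = frame.copy()
    d = out[distance_col].to_numpy(dtype=float)
    for thr in grid:
        out[near_exon_col(thr)] = (d <= thr) & np.isfinite(d)
    return out


# Alias matching the sweep terminology used for the distance-threshold scan.
distance_sweep_thresholds = add_near_exon_columns


def annotate_snps(
    frame: pd.DataFrame,
    exons: Iterable[ExonInterval],
    thresholds: Sequence[int] = (2000, 25000),
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Convenience: distance + indicator columns merged back onto ``frame``."""
    ann = nearest_exon_distance(frame[["snp_id", "chrom", "pos"]], exons, window_bp)
    ann = add_near_exon_columns(ann, thresholds)
    keep = ["snp_id", "distance_bp"] + [near_exon_col(t) for t in thresholds]
    return frame.merge(ann[keep], on="snp_id", how="left")
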