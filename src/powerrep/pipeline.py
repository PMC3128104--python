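"""End-to-end orchestration: simulate/ingest -> harmonize -> annotate ->
power -> enrichment, with a manifest for reproducibility.

``run_pipeline`` drives the whole chain from a :class:`RunConfig` and writes
every fitted model, the excess-replication report, decile counts and a spline
table under a run directory, together with a manifest recording the config,
package version and SHA-256 of each output, so a rerun with the same seed is
verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .enrichment import excess_by_power, fit_model, permutation_control, spline_summary
from .exon_annotation import annotate_snps, read_bed
from .io_harmonize import (
    apply_maf_filter,
    harmonize,
    pairs_to_frame,
    read_summary,
    write_pairs,
)
from .power import build_power_records, filter_low_n
from .simulator import SimStudyPair, generate_study_pair, power_calibration_curve

logger = logging.getLogger(__name__)

PRESETS = {
    # Modest case-control discovery/test pair with a polygenic signal.
    "synthetic-bd": dict(
        trait_kind="binary", n_snps=50_000, frac_causal=0.3, effect_scale=0.08,
        n_disc=(1868, 2938), n_test=(2191, 1434), exon_frac_near=1.0,
    ),
    # Large-discovery quantitative pair (height-like, sd 9.2 cm).
    "synthetic-height": dict(
        trait_kind="quantitative", n_snps=40_000, frac_causal=0.3,
        effect_scale=0.15, n_disc=53_394, n_test=37_052, sd_trait=9.2,
    ),
}


@dataclass
class RunConfig:
    """Validated knobs for a pipeline run."""

    trait_kind: str = "binary"
    alpha_power: float = 0.05
    alpha_replication: float = 0.05
    maf_min: float = 0.01
    exon_thresholds: tuple[int, ...] = (2000, 10000, 25000)
    models: tuple[str, ...] = ("I", "II", "III", "IV", "M1", "M2")
    power_threshold: float = 0.6
    sd_trait: float = 9.2
    seed: int = 17
    preset: Optional[str] = "synthetic-bd"
    sim_overrides: dict = field(default_factory=dict)
    n_perm: int = 0
    outdir: str = "powerrep_run"

    def validate(self) -> None:
        for name in ("alpha_power", "alpha_replication"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0,1)")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if not 0.0 < self.power_threshold < 1.0:
            raise ValueError("power_threshold must lie in (0,1)")
        if self.trait_kind not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")
        if self.preset is not None and self.preset not in PRESETS and self.preset != "calibration":
            raise ValueError(f"unknown preset {self.preset!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("exon_thresholds", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exon_thresholds"] = list(self.exon_thresholds)
        d["models"] = list(self.models)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def powered_records_from_pair(
    pair: SimStudyPair,
    config: RunConfig,
) -> pd.DataFrame:
    """Harmonize + annotate + power a simulated pair into a record table."""
    pairs = harmonize(pair.discovery, pair.test, trait_kind=pair.trait_kind)
    pairs = apply_maf_filter(pairs, config.maf_min)
    frame = pairs_to_frame(pairs)
    frame = annotate_snps(frame, pair.exons, thresholds=config.exon_thresholds)
    return build_power_records(
        frame,
        trait_kind=pair.trait_kind,
        alpha_power=config.alpha_power,
        alpha_replication=config.alpha_replication,
        sd_trait=config.sd_trait,
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Stage order: simulate (or load), read back through the IO layer,
    harmonize, MAF-filter, annotate, power, fit the requested models, excess
    report, optional permutation control, spline table, manifest.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.preset == "calibration":
        return _run_calibration(config, outdir)

    sim_kwargs = dict(PRESETS[config.preset or "synthetic-bd"])
    sim_kwargs.update(config.sim_overrides)
    trait_kind = sim_kwargs.pop("trait_kind", config.trait_kind)
    sd_trait = sim_kwargs.pop("sd_trait", config.sd_trait)
    pair = generate_study_pair(
        trait_kind=trait_kind, sd_trait=sd_trait, seed=config.seed, **sim_kwargs
    )
    simdir = outdir / "sim"
    paths = pair.write(simdir)
    logger.info("simulated %d SNPs (%s)", len(pair.discovery), trait_kind)

    # Round-trip through the readers so the run exercises the IO contracts.
    disc = read_summary(paths["discovery"], trait_kind)
    test = read_summary(paths["test"], trait_kind)
    exons = read_bed(paths["exons"])
    pairs = harmonize(disc, test, trait_kind=trait_kind)
    logger.info("harmonized %d shared SNPs", len(pairs))
    pairs = apply_maf_filter(pairs, config.maf_min)
    frame = pairs_to_frame(pairs)
    frame = annotate_snps(frame, exons, thresholds=config.exon_thresholds)
    records = build_power_records(
        frame,
        trait_kind=trait_kind,
        alpha_power=config.alpha_power,
        alpha_replication=config.alpha_replication,
        sd_trait=sd_trait,
    )
    if trait_kind == "quantitative":
        records = filter_low_n(records, fraction=0.0)  # single-N sim: no-op
    write_pairs(records, outdir / "records.tsv")

    fits = {}
    primary_thr = config.exon_thresholds[0]
    for tag in config.models:
        thr = primary_thr if tag in ("II", "IV") else None
        try:
            fits[tag] = fit_model(records, tag, near_exon_threshold_bp=thr).to_dict()
        except ValueError as exc:
            logger.warning("model %s skipped: %s", tag, exc)
    with open(outdir / "fits.json", "w") as fh:
        json.dump(fits, fh, indent=2)

    report = excess_by_power(records, config.power_threshold)
    with open(outdir / "excess.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    pd.DataFrame(
        report.per_decile_counts, columns=["decile", "n", "n_replicated"]
    ).to_csv(outdir / "decile_counts.tsv", sep="\t", index=False)

    grid, prop = spline_summary(records)
    pd.DataFrame({"power": grid, "replication_proportion": prop}).to_csv(
        outdir / "spline.tsv", sep="\t", index=False
    )

    if config.n_perm > 0:
        perms = permutation_control(records, config.n_perm, seed=config.seed)
        pd.DataFrame({"pvalue": perms}).to_csv(
            outdir / "permutation_pvalues.tsv", sep="\t", index=False
        )

    _write_manifest(config, outdir)
    return outdir


def _run_calibration(config: RunConfig, outdir: Path) -> Path:
    table, slope = power_calibration_curve(seed=config.seed, alpha=config.alpha_power)
    table.to_csv(outdir / "calibration.tsv", sep="\t", index=False)
    with open(outdir / "slope.json", "w") as fh:
        json.dump({"slope": slope, "n_snps": len(table)}, fh, indent=2)
    _write_manifest(config, outdir)
    return outdir


def _write_manifest(config: RunConfig, outdir: Path) -> None:
    files = {
        p.relative_to(outdir).as_posix(): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    hashed = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    manifest = {
        "powerrep_version": __version__,
        "config": config.to_dict(),
        # outdir is where the run lands, not what it computes
        "config_hash": hashlib.sha256(
            json.dumps(hashed, sort_keys=True).encode()
        ).hexdigest(),
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
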