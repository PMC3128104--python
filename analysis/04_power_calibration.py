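#!/usr/bin/env python
"""Show that empirical replication tracks analytic power with slope 1.

Designs 40 quantitative-trait SNPs whose analytic power spans 0.05-0.95 at
n = 2,000, forward-simulates 100 replicate cohort analyses per SNP, and
regresses the empirical replication rate on analytic power.  A slope near 1
means the power calculation is a calibrated predictor of replication — the
property the whole enrichment framework rests on.

Outputs under results/analysis/: calibration.tsv, calibration_slope.json.
"""

import argparse
import json
from pathlib import Path

from powerrep.simulator import power_calibration_curve

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=17)
parser.add_argument("--outdir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

table, slope = power_calibration_curve(
    n_snps=40, n_test=2000, n_reps=100, alpha=0.05, seed=args.seed
)
table.to_csv(args.outdir / "calibration.tsv", sep="\t", index=False)
(args.outdir / "calibration_slope.json").write_text(
    json.dumps({"slope": slope, "n_snps": len(table), "n_reps": 100}, indent=2)
)
resid = (table["empirical_rate"] - table["analytic_power"]).abs().max()
print(f"OLS slope of empirical rate on analytic power: {slope:.3f} "
      f"(max |rate - power| = {resid:.3f} over {len(table)} SNPs)")
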