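import numpy as np
import pandas as pd
import pytest

import powerrep as pr
from powerrep.pipeline import RunConfig, powered_records_from_pair


def make_summary_file(path, rows, header=None):
    """Write a native-dialect summary table from row dicts."""
    cols = header or [
        "snp_id", "chrom", "pos", "effect_allele", "other_allele",
        "effect", "eaf", "pvalue", "n_cases", "n_controls", "n_total",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    return path


def snp_row(snp_id="rs1", chrom="1", pos=1000, effect_allele="A", other_allele="G",
            effect=1.2, eaf=0.3, pvalue=0.05, n_cases=100, n_controls=100,
            n_total=200):
    return dict(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=effect_allele,
        other_allele=other_allele, effect=effect, eaf=eaf, pvalue=pvalue,
        n_cases=n_cases, n_controls=n_controls, n_total=n_total,
    )


def make_records(n, power, replicated, same_direction=None, near=None, seed=0):
    """Assemble a minimal power-record table for model-fitting tests."""
    rng = np.random.default_rng(seed)
    power = np.broadcast_to(np.asarray(power, dtype=float), (n,)).copy()
    replicated = np.broadcast_to(np.asarray(replicated, dtype=bool), (n,)).copy()
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "power": power,
            "replicated": replicated,
        }
    )
    df["same_direction"] = pd.array(
        same_direction if same_direction is not None else [True] * n,
        dtype="boolean",
    )
    if near is not None:
        df["near_exon_2000"] = np.asarray(near, dtype=bool)
    df["power_decile"] = np.minimum((df["power"] * 10).astype(int), 9)
    return df


@pytest.fixture(scope="session")
def enriched_records():
    """Powered record table from an enriched synthetic study pair (30% causal)."""
    pair = pr.generate_study_pair(n_snps=20_000, frac_causal=0.3,
                                  effect_scale=0.08, seed=11)
    return powered_records_from_pair(pair, RunConfig())


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()
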