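"""Shared fixtures: small synthetic tables generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lipidmr import SynthConfig, generate_mother_data
from lipidmr.gwas_io import EXPOSURES, TRAITS, merged_columns

settings.register_profile(
    "lipidmr",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("lipidmr")


def make_merged(
    n: int = 12,
    seed: int = 0,
    chrom: str | None = "1",
    same_pair: bool = True,
) -> pd.DataFrame:
    """Small hand-rolled merged table with consistent allele pairs."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"snp_id": [f"rs{i:04d}" for i in range(n)]})
    df["chrom"] = chrom if chrom is not None else rng.integers(1, 5, n).astype(str)
    df["pos"] = np.sort(rng.choice(np.arange(1, 10_000_000), size=n, replace=False)).astype(
        float
    )
    pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
    pick = rng.integers(0, len(pairs), n)
    a1 = np.array([pairs[i][0] for i in pick])
    a2 = np.array([pairs[i][1] for i in pick])
    for trait in TRAITS:
        beta = rng.normal(0, 0.1, n)
        se = rng.uniform(0.01, 0.05, n)
        df[f"beta_{trait}"] = beta
        df[f"se_{trait}"] = se
        df[f"p_{trait}"] = np.clip(rng.uniform(1e-12, 1, n), 1e-12, 1.0)
        df[f"n_{trait}"] = rng.integers(50_000, 100_000, n).astype(float)
        if same_pair:
            df[f"a1_{trait}"] = a1
            df[f"a2_{trait}"] = a2
        else:
            flip = rng.random(n) < 0.5
            df[f"a1_{trait}"] = np.where(flip, a2, a1)
            df[f"a2_{trait}"] = np.where(flip, a1, a2)
    return df[merged_columns()]


@pytest.fixture
def merged_small() -> pd.DataFrame:
    return make_merged(n=12, seed=1)


@pytest.fixture(scope="session")
def synth_small():
    """A fast synthetic mother table with its truth (M = 4,000)."""
    config = SynthConfig(m=4_000)
    table, truth = generate_mother_data(config, seed=7)
    return table, truth


@pytest.fixture(scope="session")
def synth_selected(synth_small):
    """Stage-1 selection of the small synthetic table, harmonized."""
    from lipidmr import Thresholds, apply_thresholds, build_beta_table

    table, truth = synth_small
    selected = apply_thresholds(table, Thresholds(p_v=5e-08), reference=table)
    return build_beta_table(selected), truth
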