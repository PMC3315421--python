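import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from regenkit import ArraySimParams, QpcrSimParams, gen_microarray_dataset, gen_qpcr_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)


@pytest.fixture
def noise_free_qpcr():
    """Paired Ct table with known ratios and unequal efficiencies, no noise."""
    params = QpcrSimParams(
        R_by_condition={"sham": 1.0, "crush": 2.35},
        E_target=1.9,
        E_control=2.0,
        ct_noise_sd=0.0,
        sample_spread_sd=0.5,
        n_samples_per_condition=6,
        seed=7,
    )
    table, truth = gen_qpcr_dataset(params)
    return params, table, truth


@pytest.fixture
def small_array():
    """Probe-level matrix: 60 genes, two spiked, one 9-replicate group."""
    params = ArraySimParams(
        n_unique_probes=60,
        replicate_groups={"gene_00000": 9, "gene_00003": 2},
        true_log2_fc={"gene_00001": 2.0, "gene_00002": -2.0},
        biological_sd=0.25,
        seed=42,
    )
    matrix, truth = gen_microarray_dataset(params)
    return params, matrix, truth


@pytest.fixture
def ct_pairs(noise_free_qpcr):
    _, table, _ = noise_free_qpcr
    sub = table[(table["condition"] == "crush")]
    wide = sub.pivot(index="sample_id", columns="gene_name", values="ct")
    return wide[["GAPDH", "CEBP"]].to_numpy()
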