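import numpy as np
import pandas as pd
import pytest

from duogrs.io_formats import WeightTable
from duogrs.synthetic_cohort import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """300 trios over 200 variants, perfect phase, fixed seed."""
    return simulate_cohort(SimParams(n_trios=300, n_variants=200, seed=11))


@pytest.fixture(scope="session")
def small_calls(small_cohort):
    from duogrs.duo_phasing import infer_duo_transmission

    return infer_duo_transmission(
        small_cohort.observed, block_length=small_cohort.params.block_length)


@pytest.fixture
def two_site_panel():
    return WeightTable(pd.DataFrame({
        "variant_id": ["rs1", "rs2"],
        "chrom": ["1", "1"],
        "pos": [100, 200],
        "effect_allele": ["A", "C"],
        "other_allele": ["G", "T"],
        "weight": [0.03, 0.02],
    }))


def make_panel(n: int, seed: int = 0) -> WeightTable:
    rng = np.random.default_rng(seed)
    return WeightTable(pd.DataFrame({
        "variant_id": [f"rs{j}" for j in range(n)],
        "chrom": "1",
        "pos": np.arange(1, n + 1) * 500,
        "effect_allele": "A",
        "other_allele": "G",
        "weight": rng.uniform(0.005, 0.05, size=n),
    }))
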