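import numpy as np
import pandas as pd
import pytest

from phenoload import SimulationConfig


def make_variants(rows: list[dict]) -> pd.DataFrame:
    """Build a variant table from partial row dicts, filling schema defaults."""
    defaults = {
        "AF_nfe": 0.01,
        "AF_afr": 0.01,
        "cadd": 30.0,
        "spliceai": 0.0,
        "utr5_flag": False,
        "carriers_normal": 0,
        "carriers_impaired": 0,
    }
    filled = []
    for i, row in enumerate(rows):
        rec = {"variant_id": f"chr1:{i + 1}:A:G", "gene": "GENE1", **defaults, **row}
        filled.append(rec)
    columns = ["variant_id", "gene", *defaults]
    return pd.DataFrame(filled, columns=columns if not filled else None)


@pytest.fixture
def variants_factory():
    return make_variants


@pytest.fixture
def small_config() -> SimulationConfig:
    """A fast configuration for unit tests of the generator and pipeline."""
    return SimulationConfig(
        seed=7,
        n_genes=300,
        n_controls=100,
        n_cases=100,
        n_signal_genes=8,
        n_variable_genes=20,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
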