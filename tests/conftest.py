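import numpy as np
import pandas as pd
import pytest

from orthoflora.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_sim_config():
    """Scaled-down simulation settings for fast end-to-end fixtures."""
    return SimulationConfig(
        seed=11,
        n_ogs=80,
        n_background_genes=200,
        n_snps_cds=20,
        n_snps_genic_noncoding=15,
        n_snps_promoter=12,
        n_snps_intergenic=8,
        n_svs=12,
    )


@pytest.fixture
def toy_count_table():
    return pd.DataFrame(
        {
            "og_id": ["OG5_A", "OG5_B", "OG5_C", "OG5_D"],
            "n_reference": [2, 5, 6, 1],
            "n_target": [16, 5, 1, 0],
        }
    )
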