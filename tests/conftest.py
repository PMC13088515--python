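import numpy as np
import pandas as pd
import pytest

from hapdeficit.simulate import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def population():
    """Mid-sized population with the default planted lethal (embryonic)."""
    cfg = SimulationConfig(rng_seed=11, n_founders=600, n_generations=4,
                           n_offspring_per_generation=600)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def scan_population():
    """Population sized so the planted region is comfortably detectable."""
    cfg = SimulationConfig(rng_seed=2, n_founders=900, n_generations=3,
                           n_offspring_per_generation=900, q_lethal=0.10)
    return simulate_population(cfg)


@pytest.fixture()
def toy_markers():
    return pd.DataFrame({
        "chrom": "1",
        "marker_id": [f"m{i}" for i in range(7)],
        "pos_bp": [1, 400_000, 900_000, 1_400_000, 1_900_000, 2_400_000, 2_900_000],
        "allele1": "A",
        "allele2": "B",
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
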