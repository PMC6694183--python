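import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rumiprox.synthetic import SimulationConfig, simulate_study

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study (42 animals, 120 genes) for fast tests."""
    cfg = SimulationConfig(seed=11, n_genes=120, n_gene_blocks=6,
                           n_signal_genes_per_trait=8, n_shared_fcr_adg=3,
                           n_shared_rfi_dfi=2, rare_gene_frac=0.1)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """One full-size study under default conditions."""
    return simulate_study(SimulationConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_phenotypes(rng):
    n = 24
    breed = np.repeat(["A", "B"], 12)
    diet = np.tile(np.repeat(["x", "y"], 6), 2)
    adg = rng.uniform(0.9, 1.9, n)
    mbw = rng.uniform(90, 130, n)
    fat = rng.uniform(4, 12, n)
    dfi = 0.2 + 4.0 * adg + 0.03 * mbw + 0.1 * fat + rng.normal(0, 0.4, n)
    table = pd.DataFrame({
        "animal_id": [f"A{i:02d}" for i in range(n)],
        "breed": breed, "diet": diet, "year": "2013", "additive": "control",
        "DFI": dfi, "ADG": adg, "MBW": mbw, "fat_depth": fat,
    })
    table["FCR"] = table["DFI"] / table["ADG"]
    from rumiprox.phenotypes import derive_rfi
    table["RFI"] = derive_rfi(table)
    return table
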