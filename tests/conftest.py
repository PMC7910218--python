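import numpy as np
import pytest

from phenoscreen import qc, synthetic

SMALL_GENES = (
    "Adnp", "Ank2", "Drd2", "Mecp2", "Tcf4", "Tbr1", "Csmd1", "Kynu",
)


@pytest.fixture(scope="session")
def small_design():
    return synthetic.ScreenDesign(genes=SMALL_GENES, n_replicates=2)


@pytest.fixture(scope="session")
def small_config(small_design):
    return synthetic.SimulationConfig(
        design=small_design,
        efficacy_range=(0.8, 1.0),
        dud_fraction=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    return synthetic.generate_screen(small_config)


@pytest.fixture(scope="session")
def small_normalized(small_screen):
    return qc.normalize_log2(small_screen)


@pytest.fixture(scope="session")
def proteomics_tables():
    cfg = synthetic.SyntheticProteomicsConfig(
        n_proteins=120,
        genes={"Tcf4": ["Tcf4_sh1", "Tcf4_sh2", "Tcf4_sh3", "Tcf4_sh4"]},
        planted_regulated={
            "Tcf4": {f"REG_{i:02d}": (1.0 if i % 2 else -1.0) for i in range(10)}
        },
        noise_sd=0.1,
        contaminant_fraction=0.05,
        seed=21,
    )
    return cfg, synthetic.generate_proteomics(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
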