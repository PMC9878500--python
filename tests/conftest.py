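import numpy as np
import pandas as pd
import pytest

from ileox.metabolome import RawMetaboliteTable
from ileox.simulate import StudyConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study at the default configuration."""
    return generate_study(StudyConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_study():
    """Synthetic study with a deterministic index -> NT relation."""
    return generate_study(StudyConfig(seed=12, nt_noise_sd=0.0))


@pytest.fixture()
def separable_typing_config():
    """Factory for well-separated community-typing configurations
    (~30 samples per type: 75 animals x 2 sample fractions, 5 types)."""

    def make(seed: int) -> StudyConfig:
        return StudyConfig(
            seed=seed,
            n_animals_per_diet={"CON": 25, "NFDM": 25, "BC": 25},
            fractions=("digesta",),
            dirichlet_concentration=2000.0,
            sequencing_depth=20_000,
        )

    return make


@pytest.fixture()
def toy_raw_table():
    """Four animals x three metabolites with one missing cell."""
    values = pd.DataFrame(
        {
            "m1": [2.0, 4.0, 8.0, 4.0],
            "m2": [5.0, 5.0, 5.0, 5.0],
            "m3": [np.nan, 3.0, 6.0, 12.0],
        },
        index=["a1", "a2", "a3", "a4"],
    )
    meta = pd.DataFrame(
        {"diet": ["CON", "CON", "BC", "BC"], "replicate": [1, 2, 1, 2]},
        index=values.index,
    )
    return RawMetaboliteTable(values=values, animal_meta=meta)
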