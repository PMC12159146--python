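import numpy as np
import pandas as pd
import pytest

from diastab import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across tests."""
    config = CohortConfig(
        n_proteins=200,
        samples_per_tissue=(5, 8),
        frac_stable_discriminative=0.3,
        dsi_module_size=30,
        seed=42,
    )
    peptides, ff, ffpe, metadata, truth = simulate_cohort(config)
    return {
        "config": config,
        "peptides": peptides,
        "ff": ff,
        "ffpe": ffpe,
        "metadata": metadata,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
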