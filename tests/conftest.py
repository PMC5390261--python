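import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from spcdelta import CountMatrix, SimulationConfig, simulate_dataset
from spcdelta.quantitation import make_sample_id


@pytest.fixture
def small_matrix():
    """3 proteins x 2 conditions x 1 compartment x 2 bio x 2 tech."""
    cols = [
        make_sample_id(cond, "cell", b, t)
        for cond in ("control", "kd")
        for b in (1, 2)
        for t in (1, 2)
    ]
    rng = np.random.default_rng(11)
    counts = pd.DataFrame(
        rng.integers(1, 30, size=(3, len(cols))),
        index=["P1", "P2", "P3"],
        columns=cols,
    )
    return CountMatrix(counts)


@pytest.fixture(scope="session")
def default_sim():
    """One seeded dataset with differential and nuisance proteins, reused
    across read-only tests."""
    config = SimulationConfig(
        n_proteins=500,
        de_fraction=0.1,
        fold_change_range=(8.0, 8.0),
        nuisance_fractions={
            "keratin": 0.02,
            "no_accession": 0.01,
            "fragment": 0.01,
            "uncharacterized": 0.01,
            "cdna_like": 0.01,
            "skeletal_muscle": 0.02,
        },
        seed=42,
    )
    matrix, proteins, truth = simulate_dataset(config)
    return config, matrix, proteins, truth
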