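import numpy as np
import pandas as pd
import pytest

from vaporqsip import ExperimentDesign, filter_fractions, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A modest noisy experiment shared by tests that only need plausible data."""
    design = ExperimentDesign(n_taxa=60, n_replicates=3, reads_per_tube=30_000, seed=11)
    return simulate_experiment(design)


@pytest.fixture(scope="session")
def small_filtered(small_experiment):
    sim = small_experiment
    return sim, filter_fractions(sim.fractions)


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Noise-free experiment on a wide, non-truncating grid (identity checks)."""
    design = ExperimentDesign(
        n_taxa=40, n_replicates=2, seed=5,
        density_min=1.56, density_max=1.82, n_fractions=40,
    ).noiseless
    return simulate_experiment(design)


@pytest.fixture()
def toy_tube():
    """One hand-built tube: 3 taxa, 4 fractions, easy numbers."""
    frac_ids = [f"T1:{i}" for i in range(1, 5)]
    features = pd.DataFrame(
        [[10, 80, 10, 0], [0, 0, 50, 50], [5, 5, 5, 5]],
        index=["t1", "t2", "t3"], columns=frac_ids, dtype=float,
    )
    fractions = pd.DataFrame(
        {
            "tube_id": "T1",
            "fraction_index": [1, 2, 3, 4],
            "density": [1.70, 1.71, 1.72, 1.73],
            "total_copies": [1e6, 4e6, 2e6, 1e6],
            "total_read_pairs": [5000, 5000, 5000, 5000],
        },
        index=pd.Index(frac_ids, name="fraction_id"),
    )
    return features, fractions


def brute_force_wad(densities, copies):
    """Independent weighted-mean oracle."""
    num = sum(d * y for d, y in zip(densities, copies))
    den = sum(copies)
    return num / den
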