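import numpy as np
import pytest

from msxfgp.data import GenoPhenoDataset, SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """60 samples x 30 markers, strong signal; fast enough for model fits."""
    dataset, causal, effects = simulate_dataset(
        SimulationSpec(
            n_samples=60, n_markers=30, n_causal=3, heritability=0.9, seed=11
        )
    )
    return dataset, causal, effects


@pytest.fixture
def deterministic_dataset():
    """Tiny dataset with a phenotype exactly linear in one marker (no noise)."""
    rng = np.random.default_rng(5)
    genotypes = rng.integers(0, 3, size=(60, 10)).astype(float)
    phenotypes = 2.0 * genotypes[:, 3] + 1.0
    return GenoPhenoDataset(
        sample_ids=[f"S{i}" for i in range(60)],
        marker_ids=[f"M{j}" for j in range(10)],
        genotypes=genotypes,
        phenotypes=phenotypes,
    )
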