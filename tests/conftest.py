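import numpy as np
import pytest

import sweetgate as sg


@pytest.fixture(scope="session")
def default_dataset():
    """Two planted sweet clusters + 300 background molecules, 100 descriptors."""
    return sg.generate_synthetic_dataset(seed=11)


@pytest.fixture(scope="session")
def fitted_system(default_dataset):
    """Expert system fitted on a stratified 70% of the default dataset.

    Returns (system, split indices, fps, table, labels, metadata).
    """
    fps, table, y, meta = default_dataset
    refs = sg.planted_cluster_references(fps, meta)
    train, test = sg.stratified_split(y, int(round(0.3 * len(y))), seed=11)
    system = sg.SweetTasteExpertSystem()
    system.fit(fps.subset(train), table.subset_rows(train), y[train],
               cluster_references=refs)
    return system, (train, test), fps, table, y, meta


@pytest.fixture(scope="session")
def planted_descriptor_dataset():
    """Descriptor-only fixture: 6 informative of 100, effect 1.5 SD, n = 300."""
    config = sg.SyntheticConfig(cluster_sizes=(), n_background_sweet=150,
                                n_background_nonsweet=150)
    return sg.generate_synthetic_dataset(config, seed=7)


@pytest.fixture(scope="session")
def ga_run(planted_descriptor_dataset):
    """One deterministic GA subset-selection run on the planted fixture."""
    _, table, y, meta = planted_descriptor_dataset
    cfg = sg.GaConfig(population_size=30, n_generations=30, seed=7)
    return sg.ga_vss(table, y, cfg), meta


@pytest.fixture(scope="session")
def monte_carlo_report(fitted_system):
    """100-iteration Monte Carlo validation of the fitted expert system."""
    system, (train, _), fps, table, y, _ = fitted_system
    return sg.monte_carlo_expert(fps.subset(train), table.subset_rows(train),
                                 y[train], system, n_iter=100, seed=11)


def random_binary_matrix(rng: np.random.Generator, n: int, n_bits: int,
                         density: float = 0.2) -> np.ndarray:
    return (rng.random((n, n_bits)) < density).astype(np.uint8)
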