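import logging

import pytest

from tcrpair import SimulationParams, simulate_dataset

logging.getLogger("tcrpair").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_sim():
    """The default-condition simulation shared across expensive tests."""
    return simulate_dataset(SimulationParams(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast simulation for structural checks."""
    params = SimulationParams(seed=7, n_clonotypes=40, n_samples=3)
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free conditions: no ambient contamination, dropout or doublets."""
    params = SimulationParams(
        seed=3,
        n_clonotypes=60,
        ambient_rate=0.0,
        dropout_alpha=0.0,
        dropout_beta=0.0,
        doublet_rate=0.0,
        vendor_unassigned_rate=0.0,
    )
    return simulate_dataset(params)


def annotate(dataset):
    """Run contig QC, clonotype collapse and dominant-chain selection.

    Operates on a deep copy so session-scoped simulations stay pristine.
    """
    from tcrpair import Dataset
    from tcrpair.clonotyping import (
        collapse_and_impute_clonotypes,
        filter_dataset_contigs,
        select_dominant_chains_dataset,
    )

    ds = Dataset.from_parts(
        [g.copy() for g in dataset.iter_gems()],
        dataset.panel.values(),
        dataset.samples.values(),
    )
    ds, _ = filter_dataset_contigs(ds)
    ds = collapse_and_impute_clonotypes(ds)
    return select_dominant_chains_dataset(ds)
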