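import numpy as np
import pandas as pd
import pytest

from ullmannkit import SimConfig, simulate
from ullmannkit.classifier import assemble_features
from ullmannkit.io_cli import product_coords


@pytest.fixture(scope="session")
def default_dataset():
    """One default staged simulation shared across tests."""
    return simulate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def noise_free_dataset():
    return simulate(SimConfig(seed=7, label_noise=0.0))


@pytest.fixture(scope="session")
def uniform_panel_dataset():
    """Every product screened against the full 36-ligand panel."""
    return simulate(SimConfig(seed=7, n_products_initial=28, n_products_extension=0))


def feature_table(dataset):
    """Per-reaction (d, n_charge, vbur, yield) table for a SimDataset."""
    return assemble_features(
        dataset.reactions,
        dataset.products_frame,
        dataset.ligands_frame,
        dataset.bromides_frame,
        dataset.amines_frame,
    )


def passing_coords(dataset):
    """(product_id, n_charge, vbur) for the control-passing products."""
    coords = product_coords(
        dataset.products_frame, dataset.bromides_frame, dataset.amines_frame
    )
    keep = {p.product_id for p in dataset.passing_products}
    return coords[coords["product_id"].isin(keep)].reset_index(drop=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
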