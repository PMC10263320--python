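"""Shared fixtures and simulation helpers for the test suite.

The canonical population condition used across ordering tests mirrors the
package's study design: 200 samples, 60 rhythmic seed genes (17 clock +
43 background) with relative amplitudes 0.15-1.0, multiplicative noise
CV 0.2.
"""

import dataclasses
import warnings

import numpy as np
import pytest

from clockscope import SeedGeneList, SimConfig, simulate_population

# silence the small-cohort advisory warnings during tests
warnings.filterwarnings("ignore", message=".*samples.*")


def population_config(seed, delta=0.0, n_samples=200, noise_cv=0.2, batches=None,
                      n_genes=300):
    kwargs = dict(
        n_samples=n_samples,
        n_genes=n_genes,
        n_background_rhythmic=43,
        background_ramp_range=(0.15, 1.0),
        noise_cv=noise_cv,
        disruption=delta,
        seed=seed,
    )
    if batches is not None:
        kwargs["batches"] = batches
    return SimConfig(**kwargs)


def rhythmic_seed_list(dataset) -> SeedGeneList:
    genes = list(dataset.truth_gene_params.index[dataset.truth_gene_params["is_rhythmic"]])
    return SeedGeneList(genes, source="user_file")


@pytest.fixture(scope="session")
def intact_dataset():
    return simulate_population(population_config(seed=1))


@pytest.fixture(scope="session")
def disrupted_dataset():
    return simulate_population(population_config(seed=1, delta=1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
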