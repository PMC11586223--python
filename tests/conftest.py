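"""Shared fixtures: small synthetic datasets and parameter sets."""

from __future__ import annotations

import numpy as np
import pytest

from ramanbarrier.prep import preprocess_dataset
from ramanbarrier.synth import GeneratorParams, StudyDesign, generate_dataset


@pytest.fixture(scope="session")
def clean_params() -> GeneratorParams:
    """Generator defaults with noise, background and batch effects off."""
    return GeneratorParams().clean()


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    """Reduced acquisition plan (coarser grid, fewer spots) for fast tests."""
    return StudyDesign(
        n_membranes=3, n_spots_per_timepoint=10, n_blank_spectra=20,
        grid=(500.0, 2000.0, 2.0),
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One full-noise default-design dataset (220 spectra), seed 1."""
    return generate_dataset(StudyDesign(), GeneratorParams(), seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return generate_dataset(small_design, GeneratorParams(), seed=1)


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    return preprocess_dataset(small_dataset)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
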