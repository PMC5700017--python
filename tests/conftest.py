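"""Shared fixtures: synthetic training sets and libraries built once per session."""

import numpy as np
import pytest

import pepforge as pf


@pytest.fixture(scope="session")
def training_set():
    rng = np.random.default_rng(202)
    return pf.make_training_set(6, 18, (5, 12), rng)


@pytest.fixture(scope="session")
def library(training_set):
    return pf.build_library(pf.dataset_filter(training_set))


@pytest.fixture(scope="session")
def native_peptide():
    """A coil 'native' given the best resolution in its training set, so its
    own conformers found every cluster they join."""
    rng = np.random.default_rng(7)
    return pf.sample_coil("MKWVTF", rng=rng, resolution=0.8, source_id="native_x")


@pytest.fixture(scope="session")
def recovery_library(native_peptide):
    rng = np.random.default_rng(11)
    train = pf.make_training_set(6, 20, (5, 12), rng, extra_chains=[native_peptide])
    return pf.build_library(pf.dataset_filter(train))


@pytest.fixture(scope="session")
def ideal_helix12():
    return pf.make_ideal_helix("AEKLLSQFAKLW")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
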