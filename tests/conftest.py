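"""Shared fixtures: one photon bank and one study per session.

The Monte Carlo bank and the leave-one-out study dominate the suite's
runtime, so they are built once at session scope and shared by the unit,
property and acceptance tests.
"""

import numpy as np
import pytest

import hemospec as hs


@pytest.fixture(scope="session")
def geom():
    return hs.ProbeGeometry()


@pytest.fixture(scope="session")
def bank100():
    """Baseline bank: mu_s_ref = 100 cm^-1, Mie anisotropy, matched boundary."""
    return hs.simulate_bank(100.0, hs.mie_g(), n_photons=100_000, seed=42)


@pytest.fixture(scope="session")
def bank50():
    """Companion bank at half the scattering, for similarity checks."""
    return hs.simulate_bank(50.0, hs.mie_g(), n_photons=100_000, seed=43)


@pytest.fixture(scope="session")
def model(bank100, geom):
    return hs.ReflectanceModel(bank100, geom)


@pytest.fixture(scope="session")
def grid51():
    return np.linspace(430.0, 630.0, 51)


@pytest.fixture(scope="session")
def ext():
    return hs.default_extinction_model()


@pytest.fixture(scope="session")
def eps51(ext, grid51):
    return hs.synth_extinction(ext, grid51)


@pytest.fixture(scope="session")
def phantoms():
    return hs.make_table1_series()


@pytest.fixture(scope="session")
def noiseless_inputs(phantoms, ext, model, grid51):
    inst = hs.default_instrument(grid51, noise_cv=0.0, seed=3)
    return hs.make_study_inputs(phantoms, ext, model.predict, inst)


@pytest.fixture(scope="session")
def noisy_study(phantoms, ext, model, eps51, grid51):
    """Full 16-phantom leave-one-out study at the 2% noise study condition."""
    inst = hs.default_instrument(grid51, noise_cv=0.02, seed=1)
    inputs = hs.make_study_inputs(phantoms, ext, model.predict, inst)
    return hs.leave_one_out_study(inputs, model, eps51)
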