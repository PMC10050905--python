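"""Shared fixtures: library entries, synthetic spectra, analysis config."""

import numpy as np
import pytest
from hypothesis import settings

import hsqcmultiplet as hm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from hsqcmultiplet.library import Coupling, ResonanceEntry


@pytest.fixture(scope="session")
def library():
    return hm.default_library()


@pytest.fixture()
def config():
    return hm.AnalysisConfig()


@pytest.fixture(scope="session")
def dd_entry():
    """A doublet-of-doublets CH entry (two one-bond couplings)."""
    return ResonanceEntry("meta", "C2", 4.11, 69.3,
                          (Coupling("C1", 54.9), Coupling("C3", 37.1)))


@pytest.fixture(scope="session")
def doublet_entry():
    """A doublet CH entry (one one-bond coupling)."""
    return ResonanceEntry("metb", "C5", 4.06, 69.8, (Coupling("C4", 41.0),))


@pytest.fixture()
def simple_grid():
    """A small uniform grid with known descending axes for IO tests."""
    axis_h = np.linspace(4.5, 3.5, 41)
    axis_c = np.linspace(75.0, 65.0, 101)
    rng = np.random.default_rng(0)
    return hm.SpectrumGrid(
        intensities=rng.normal(size=(101, 41)),
        axis_h=axis_h,
        axis_c=axis_c,
        freq_h=800.13,
        freq_c=201.20,
        j_scaling=1,
        provenance="fixture",
    )
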