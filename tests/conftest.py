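"""Shared fixtures: synthetic libraries and the trained adduct corrector.

Everything is generated programmatically with fixed seeds; nothing is
downloaded or stored on disk.
"""

import numpy as np
import pytest

from speclib_repair.corrector import build_corpus, train_corrector
from speclib_repair.libops import merge_libraries
from speclib_repair.spectral_io import SpectralLibrary, Spectrum
from speclib_repair.synth import make_benchmark_suite, make_reliability_pair


@pytest.fixture(scope="session")
def benchmark_suite():
    return make_benchmark_suite(seed=1)


@pytest.fixture(scope="session")
def integrated_subject(benchmark_suite):
    return merge_libraries(benchmark_suite.libraries, "integrated")


@pytest.fixture(scope="session")
def adduct_corpus():
    return build_corpus()


@pytest.fixture(scope="session")
def trained_corrector(adduct_corpus):
    """(model, report) trained at seed 7 with the 80/20 stratified split."""
    return train_corrector(adduct_corpus, seed=7, holdout=0.2)


@pytest.fixture(scope="session")
def reliability_pair():
    lib_a, lib_b, truth = make_reliability_pair(seed=1)
    return lib_a, lib_b, truth


@pytest.fixture
def tiny_library():
    """Two fully-annotated spectra, one per ion mode, with a unicode name."""
    return SpectralLibrary(name="tiny", spectra=[
        Spectrum(metadata={
            "name": "α-D-glucose", "inchikey": "WQZGKKKJIJFFOK-GASJEMHNSA-N",
            "smiles": "OC1OC(CO)C(O)C(O)C1O", "formula": "C6H12O6",
            "exact_mass": "180.063388", "adduct": "[M+H]+",
            "precursor_mz": "181.070664", "ionmode": "positive",
            "source_library": "tiny",
        }, peaks=[(85.029, 0.4), (127.039, 1.0), (163.060, 0.2)]),
        Spectrum(metadata={
            "name": "citrate", "inchikey": "KRKNYBCHXYNGOX-UHFFFAOYSA-N",
            "smiles": "OC(=O)CC(O)(CC(O)=O)C(O)=O", "formula": "C6H8O7",
            "exact_mass": "192.027003", "adduct": "[M-H]-",
            "precursor_mz": "191.019728", "ionmode": "negative",
            "source_library": "tiny",
        }, peaks=[(87.008, 0.7), (111.008, 1.0), (173.009, 0.3)]),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20250928)
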