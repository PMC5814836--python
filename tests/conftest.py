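import numpy as np
import pytest

from diazosip.raman import preprocess
from diazosip.sip import DensityWindows
from diazosip.synthetic import (
    GradientSimParams,
    SpectraSimParams,
    simulate_gradient_experiment,
    simulate_spectra,
)


@pytest.fixture
def rna_windows():
    return DensityWindows.rna_default()


@pytest.fixture(scope="session")
def small_experiment():
    """One labelled + one control RNA gradient, 60 OTUs, one fully labelled OTU."""
    params = GradientSimParams(
        n_otus=60,
        labelled_otu_ids=frozenset({"OTU_0001"}),
        fixed_abundances={"OTU_0001": 0.02},
        seed=42,
    )
    tables, truth, qpcr = simulate_gradient_experiment(params)
    return params, tables, truth, qpcr


@pytest.fixture(scope="session")
def preprocessed_spectra():
    """Small preprocessed spectra panel: 8 strains x 6 levels x 8 cells."""
    params = SpectraSimParams(cells_per_level=8, seed=5)
    return preprocess(simulate_spectra(params))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
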