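import numpy as np
import pandas as pd
import pytest

from nadscope.metabolomics import IntensityMatrix
from nadscope.peaks import nad_region_library
from nadscope.simulate import default_spectrum_truth, simulate_spectrum


@pytest.fixture(scope="session")
def nad_lib():
    return nad_region_library()


@pytest.fixture(scope="session")
def noiseless_seven(nad_lib):
    """Noiseless spectrum generated from the 7-peak fitting model itself."""
    truth = default_spectrum_truth(snr=np.inf, names=nad_lib.names)
    spec, truth = simulate_spectrum(truth)
    return spec, truth


@pytest.fixture(scope="session")
def full_noiseless():
    """Noiseless nine-resonance spectrum (PCr + gamma-ATP + NAD region)."""
    truth = default_spectrum_truth(snr=np.inf)
    spec, truth = simulate_spectrum(truth)
    return spec, truth


def make_matrix(values: np.ndarray, groups, batches=None, protein=None, log_scale=True):
    """Small IntensityMatrix builder for metabolomics tests."""
    n_met, n_samp = values.shape
    cols = [f"s{j}" for j in range(n_samp)]
    vals = pd.DataFrame(values, index=[f"m{i}" for i in range(n_met)], columns=cols)
    meta = pd.DataFrame(
        {
            "group": list(groups),
            "prep_batch": list(batches) if batches is not None else ["b1"] * n_samp,
            "protein_conc": list(protein) if protein is not None else [0.0] * n_samp,
        },
        index=cols,
    )
    return IntensityMatrix(vals, meta, log_scale=log_scale)


@pytest.fixture
def matrix_builder():
    return make_matrix
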