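import warnings

import numpy as np
import pytest

from srvs import SRVSConfig, build_design, gen_planted, srvs_select


@pytest.fixture(autouse=True)
def _silence_nonconvergence():
    """The accumulation loop warns when it hits the step cap; that is
    expected behaviour in many deliberately tiny test runs."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="SRVS did not converge", category=RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def tiny_planted():
    """30 samples, 100 columns, 5 strong signal columns."""
    return gen_planted(15, 15, 100, 5, 8.0, seed=700)


@pytest.fixture(scope="session")
def tiny_selection(tiny_planted):
    design = build_design(tiny_planted.modality1)
    result = srvs_select(
        design, tiny_planted.phenotype, SRVSConfig(window_size=25, seed=41)
    )
    return design, result


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
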