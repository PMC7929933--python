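import warnings

import numpy as np
import pytest

from grnprecision.config import build_parameters, build_signal_profile, default_config
from grnprecision.synth import generate_benchmark


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def wt_model():
    cfg = default_config()
    return build_parameters(cfg), build_signal_profile(cfg), cfg


@pytest.fixture(scope="session")
def double_well():
    return generate_benchmark("double_well_1d")


@pytest.fixture(scope="session")
def wt_bistable_signal(wt_model):
    """A signal level inside the wild-type bistable interval."""
    from grnprecision import neuraltube as nt

    params, profile, _ = wt_model
    r_fold, r_end = nt.fold_position(params, profile)
    return profile(r_fold + 0.08)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
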