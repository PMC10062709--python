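import numpy as np
import pytest

from anisokin.model_core import BindingParameters


@pytest.fixture(scope="session")
def probe_params() -> BindingParameters:
    """The probe's kinetic parameter set used throughout the recovery studies:
    slow association, sub-nanomolar affinity, mild non-specific binding."""
    return BindingParameters(
        kon_L=4.2e-4, Kd_L=2.8e-4 / 4.2e-4,
        kon_C=1e-5, Ki_C=0.1,
        kon_NS=1e-5, koff_NS=4e-4,
        R_stock=20.0, NBV_stock=100.0,
        FA_free=0.081, FA_bound=0.35, FA_ns=0.15,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
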