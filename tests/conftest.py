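import numpy as np
import pytest

from rpvolt import (
    ElectrodeParams,
    NoiseParams,
    PreprocessSpec,
    build_fscv,
    build_rpv,
    sample,
)
from rpvolt.simulate import simulate_calibration, table1_combined_design


@pytest.fixture(scope="session")
def rpv_full():
    """The four-step pulse digitized at 125 kHz (1000 features)."""
    return sample(build_rpv())


@pytest.fixture(scope="session")
def rpv_small():
    """Same pulse at 12.5 kHz (100 features) for cheap simulations."""
    return sample(build_rpv(), sample_rate=12_500)


@pytest.fixture(scope="session")
def fscv_full():
    return sample(build_fscv())


@pytest.fixture
def quiet_electrode():
    """No drift, no capacitance coupling — removes every confound."""
    return ElectrodeParams(c_dl_conc_coupling=0.0, drift_rate=0.0, drift_walk_sd=0.0)


@pytest.fixture
def no_noise():
    return NoiseParams(white_sd=0.0, seed=0)


@pytest.fixture
def l2_spec():
    return PreprocessSpec(center=True, scale_mode="normalize", norm="l2")


@pytest.fixture(scope="session")
def default_calibration(rpv_full):
    """An 18-standard calibration under the default study conditions."""
    return simulate_calibration(
        table1_combined_design(seed=0), rpv_full, noise=NoiseParams(seed=0)
    )
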