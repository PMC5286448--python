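import numpy as np
import pytest

from smipp import TruthParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def quiet_params():
    """A deterministic site: no trends, no IAV, no couplings, no noise."""
    return TruthParams(
        trend_gs_start=0.0, trend_gs_end=0.0, trend_gpp_max=0.0,
        iav_sd_gs_start=0.0, iav_sd_gs_end=0.0, iav_sd_gpp_max=0.0,
        temp_sens_gs_start=0.0, temp_sens_gs_end=0.0, temp_sens_gpp_max=0.0,
        obs_noise_sd=0.0, n_years=6, seed=42,
    )
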