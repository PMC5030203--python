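import numpy as np
import pytest

from mbfpet.synthetic import make_input_function
from mbfpet.timing_io import RB82, default_schedule


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def aif():
    # 1 s sampling keeps fits fast; the convolution is exact on any grid
    return make_input_function(tracer=RB82, dt_s=1.0)


@pytest.fixture(scope="session")
def rvif():
    return make_input_function(
        peak_time_s=21.0, peak_amp=55_000.0, t0_s=6.0, tracer=RB82, dt_s=1.0
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
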