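import numpy as np
import pytest
from hypothesis import settings

import sdhscreen as s

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def quiet_cfg():
    """Noise-free simulation config on 1:1 mixed media."""
    return s.SimConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def wt_curve_clean(quiet_cfg):
    """Noise-free diauxic wild-type curve with ground truth attached."""
    return s.gen_growth_curve(s.wild_type(), cfg=quiet_cfg)


@pytest.fixture(scope="session")
def sdh2_curve_clean(quiet_cfg):
    """Noise-free single-phase curve of the respiration-deficient mutant."""
    return s.gen_growth_curve(s.sdh2_null(), cfg=quiet_cfg)
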