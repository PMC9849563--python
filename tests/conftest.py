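import numpy as np
import pytest

import gaitphase as gp


@pytest.fixture(scope="session")
def clean_lgw_session():
    """Noise-free level-walking session: 10 strides at exactly 1.10 s each."""
    return gp.generate_session("LGW", 10, gp.NoiseSpec.zero(), seed=7)


@pytest.fixture(scope="session")
def noisy_lgw_session():
    """Level-walking session with default stride and sensor variability."""
    return gp.generate_session("LGW", 30, seed=21)


@pytest.fixture(scope="session")
def labelled_lgw(noisy_lgw_session):
    """Session with pipeline-derived continuous phase labels."""
    series, _, _ = noisy_lgw_session
    binary = gp.extract_phases(series.f_z)
    hs = gp.find_heel_strikes(binary)
    labels = gp.label_continuous_phase(hs, len(series))
    return series, labels
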