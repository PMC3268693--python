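import numpy as np
import pytest

import betaburn as bb


@pytest.fixture
def wilson_default() -> bb.WilsonModel:
    """Strong diffractor: B0 = 15 A^2, 10 shells to the 2.0 A floor."""
    return bb.WilsonModel.from_resolution(B0=15.0, scale0=1.0, d_min=2.0, n_shells=10)


@pytest.fixture
def char_default(wilson_default) -> bb.CharacterizationInput:
    """Default characterization: dose rate 0.15 MGy/s, strong crystal."""
    return bb.CharacterizationInput(dose_rate=0.15, wilson=wilson_default)


@pytest.fixture
def protocol_default(char_default) -> bb.Protocol:
    return bb.generate_protocol(char_default)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
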