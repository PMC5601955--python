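import numpy as np
import pytest

from emgpr.preprocess import SegmentationSpec
from emgpr.sessions import ProtocolSpec
from emgpr.synth import FrontEndSpec, generate_session, make_activation_matrix


@pytest.fixture(scope="session")
def small_protocol() -> ProtocolSpec:
    """Scaled-down protocol for fast tests: 4 movements, 4 channels, 500 Hz."""
    return ProtocolSpec(
        sampling_rate=500.0,
        n_channels=4,
        movements=("m1", "m2", "m3", "m4"),
        n_repetitions=2,
        contraction_s=2.0,
        rest_s=1.0,
    )


@pytest.fixture(scope="session")
def small_frontend() -> FrontEndSpec:
    # low-pass must sit below the 250 Hz Nyquist of the small protocol
    return FrontEndSpec(lowpass_cutoff_hz=200.0)


@pytest.fixture(scope="session")
def small_session(small_protocol, small_frontend):
    model = make_activation_matrix(
        len(small_protocol.movements), small_protocol.n_channels,
        overlap=0.0, rng_seed=11,
    )
    return generate_session(small_protocol, model, small_frontend)


@pytest.fixture(scope="session")
def default_protocol() -> ProtocolSpec:
    return ProtocolSpec()


@pytest.fixture(scope="session")
def default_session(default_protocol):
    """One full-scale session (16 ch, 2 kHz, 192 s); reused across tests."""
    model = make_activation_matrix(8, 16, overlap=0.0, rng_seed=1)
    return generate_session(default_protocol, model, FrontEndSpec())


@pytest.fixture(scope="session")
def small_segmentation() -> SegmentationSpec:
    return SegmentationSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
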