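import numpy as np
import pytest

from restcompare import (
    HeadModel,
    build_lead_field,
    equivalent_source_layer,
    standard_montage,
)


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def montage64(head):
    return standard_montage(64, scalp_radius_m=head.scalp_radius)


@pytest.fixture(scope="session")
def rest_lead_field(head, montage64):
    """Equivalent-source lead field used by the infinity standardization."""
    pos, ori = equivalent_source_layer(head, 300)
    return build_lead_field(head, montage64, pos, ori)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def sinusoid_recording(freqs, sfreq=1000.0, duration=10.0, phases=None, amplitudes=None):
    """Helper: multichannel pure-sinusoid EEGRecording."""
    from restcompare import EEGRecording

    t = np.arange(int(round(sfreq * duration))) / sfreq
    phases = phases or [0.0] * len(freqs)
    amplitudes = amplitudes or [1.0] * len(freqs)
    data = np.vstack(
        [a * np.cos(2 * np.pi * f * t + p) for f, p, a in zip(freqs, phases, amplitudes)]
    )
    labels = [f"ch{i}" for i in range(len(freqs))]
    return EEGRecording(data, sfreq, labels, reference="infinity")
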