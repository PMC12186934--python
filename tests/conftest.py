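import numpy as np
import pytest
from hypothesis import settings

import magdensity as md

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def presets():
    return md.scanner_presets()


@pytest.fixture(scope="session")
def phantom():
    """Small bilateral phantom shared by reconstruction-level tests."""
    return md.make_phantom((32, 32, 12), 0.6, seed=7)


@pytest.fixture(scope="session")
def noiseless_series(phantom, presets):
    """Noiseless echo series of the shared phantom, one per scanner."""
    return {
        name: md.simulate_echoes(phantom, prof, seed=0)
        for name, prof in presets.items()
    }


def forward_voxel(profile, a_w, a_f, psi_hz, phase0=0.0, phase1=0.0, r2star=0.0):
    """Independent forward-model oracle for a single voxel's echo signal."""
    te = np.asarray(profile.echo_times) * 1e-3
    n = np.arange(te.size)
    s = (
        (a_w + a_f * np.exp(2j * np.pi * profile.fat_offset_hz * te))
        * np.exp(2j * np.pi * psi_hz * te)
        * np.exp(-te * r2star)
        * np.exp(1j * (phase0 + phase1 * n))
    )
    return s


def voxel_series(profile, a_w, a_f, psi_hz, **kw):
    s = forward_voxel(profile, a_w, a_f, psi_hz, **kw)
    return md.EchoSeries(data=s.reshape(1, 1, 1, -1), echo_times=profile.echo_times)
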