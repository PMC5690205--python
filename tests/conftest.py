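import numpy as np
import pytest

from resp4d import (
    AcquisitionConfig,
    MotionWaveform,
    WaveformKind,
    simulate_cine_study,
)
from resp4d.geometry import DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def eval_slice_z(geometry):
    """Evaluation plane 200 mm from the central piece (lever ratio ~0.574)."""
    return geometry.z0_mm - 200.0


def make_study(
    amplitude_mm=10.0,
    kind=WaveformKind.SINE,
    noise_sd_hu=20.0,
    seed=7,
    tc_s=0.0,
    n_slabs=1,
    slices_per_slab=1,
    slice_zs=None,
    geometry=DEFAULT_GEOMETRY,
    **acq_kw,
):
    waveform = MotionWaveform(kind, amplitude_mm=amplitude_mm, period_s=6.0, tc_s=tc_s)
    cfg = AcquisitionConfig(
        n_slabs=n_slabs,
        slices_per_slab=slices_per_slab,
        noise_sd_hu=noise_sd_hu,
        **acq_kw,
    )
    if slice_zs is None:
        slice_zs = [geometry.z0_mm - 200.0 + 3.0 * i for i in range(n_slabs * slices_per_slab)]
    return simulate_cine_study(waveform, geometry, cfg, slice_zs, seed=seed)


@pytest.fixture(scope="session")
def sine_study_a10():
    """Single-slice 20-frame cine of a +/-10 mm, 6 s sine at 20 HU noise."""
    return make_study(amplitude_mm=10.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_study_a10():
    return make_study(amplitude_mm=10.0, noise_sd_hu=0.0, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
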