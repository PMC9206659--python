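import numpy as np
import pytest

from pshg.polarimetry import PolState
from pshg.synthetic import FiberField, GroupPreset, NoiseModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_uniform_field(
    shape=(8, 8),
    delta=0.0,
    alpha=0.0,
    r=2.0,
    c=0.0,
    amplitude=1.0,
    chiral_phase=90.0,
):
    """Single-fiber field with constant parameters on every pixel."""
    full = lambda v: np.full(shape, float(v))
    return FiberField(
        fiber_mask=np.ones(shape, dtype=bool),
        delta=full(delta),
        alpha=full(alpha),
        r_true=full(r),
        c_true=full(c),
        amplitude=full(amplitude),
        chiral_phase_deg=chiral_phase,
    )


@pytest.fixture
def uniform_field():
    return make_uniform_field


@pytest.fixture
def fast_presets():
    """Down-scaled group presets for quick end-to-end tests."""
    noise = NoiseModel(background_mean=10.0, background_sd=2.0, shot_noise=True, shot_scale=4.0)
    return {
        "normal": GroupPreset(
            label="normal",
            r_mean=1.7,
            r_sd=0.15,
            fiber_density_target=0.30,
            orientation_dispersion=6.0,
            alpha_sd=30.0,
            amplitude_mean=60.0,
            amplitude_sd=12.0,
            chirality=0.3,
            n_layers=2,
            noise=noise,
        ),
        "tumor": GroupPreset(
            label="tumor",
            r_mean=2.2,
            r_sd=0.15,
            fiber_density_target=0.12,
            orientation_dispersion=1.5,
            alpha_sd=12.0,
            amplitude_mean=25.0,
            amplitude_sd=6.0,
            chirality=0.3,
            n_layers=1,
            noise=noise,
        ),
    }


def one_pixel_stokes(s0r=1.0, s0l=1.0, s3r=0.0, s3l=0.0, s0h=1.0, s0v=1.0):
    """Hand-built single-pixel StokesMaps for forced-arithmetic checks."""
    from pshg.polarimetry import StokesMaps

    arr = lambda v: np.array([[float(v)]])
    s0 = {
        PolState.RCP: arr(s0r),
        PolState.LCP: arr(s0l),
        PolState.HLP: arr(s0h),
        PolState.VLP: arr(s0v),
    }
    zero = {p: arr(0.0) for p in s0}
    s3 = dict(zero)
    s3[PolState.RCP] = arr(s3r)
    s3[PolState.LCP] = arr(s3l)
    return StokesMaps(s0=s0, s1={p: arr(0.0) for p in s0}, s3=s3)
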