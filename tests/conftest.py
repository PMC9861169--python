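"""Shared fixtures: small synthetic phantoms sized for fast pixel fitting."""

from dataclasses import replace

import pytest

from relaxmap.dicom_io import RoiSquare
from relaxmap.phantom import (
    PhantomSpec,
    TubeSpec,
    render_series,
    t1_protocol,
    t2_protocol,
)

# Radius 8 so a 10x10 ROI at (11, 11) sits fully inside the first tube
# (a side-10 square needs an inscribed-circle radius of sqrt(50)).
THREE_TUBES = (
    TubeSpec(center=(16, 16), radius=8, t1=300.0, t2=80.0, amplitude=1200.0),
    TubeSpec(center=(16, 48), radius=8, t1=900.0, t2=200.0, amplitude=1000.0),
    TubeSpec(center=(44, 32), radius=8, t1=2200.0, t2=600.0, amplitude=800.0),
)

# ROIs for the 64x64 three-tube scene. The object ROI sits inside the
# slowest-recovering, dimmest tube (T1 = 2200 ms, amplitude 800): training
# on the weakest-signal sample makes every other tube an interpolation for
# the classifier rather than an extrapolation toward noise. The air ROI is
# the lower-left aerated corner.
OBJECT_ROI = RoiSquare(40, 28, 10)
AIR_ROI = RoiSquare(52, 2, 10)


def small_spec(noise_sigma: float = 0.0, seed: int = 0, **kwargs) -> PhantomSpec:
    return PhantomSpec(
        shape=(64, 64), tubes=THREE_TUBES, noise_sigma=noise_sigma, seed=seed, **kwargs
    )


@pytest.fixture(scope="session")
def clean_t1():
    """Noiseless three-tube T1 series with ground truth."""
    return render_series(small_spec(), t1_protocol())


@pytest.fixture(scope="session")
def clean_t2():
    """Noiseless three-tube T2 series with ground truth."""
    return render_series(small_spec(), t2_protocol())


@pytest.fixture(scope="session")
def noisy_t1():
    """Rician-noise three-tube T1 series at SNR ~50."""
    return render_series(small_spec(noise_sigma=20.0, seed=7), t1_protocol())


@pytest.fixture()
def small_spec_factory():
    return small_spec


@pytest.fixture()
def rois():
    return OBJECT_ROI, AIR_ROI
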