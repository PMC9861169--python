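"""Synthetic relaxometry phantoms with known ground truth.

Emulates the classic bench phantom for T1/T2 mapping: a field of view
containing several disk-shaped test tubes (e.g. a CuSO4 dilution ladder
plus distilled water), each with its own T1, T2 and amplitude, on an
aerated background whose only content is acquisition noise. Rendering a
phantom through an acquisition protocol produces a
:class:`~relaxmap.dicom_io.RelaxationSeries` together with the true
parameter maps and object mask, so every downstream stage — training-set
extraction, classification, pixel-wise fitting — can be tested against a
known answer without scanner data.

Magnitude-image noise is Rician by default: each noiseless signal ``s``
becomes ``sqrt((s + n1)^2 + n2^2)`` with ``n1, n2 ~ N(0, sigma^2)``. In
signal-free (aerated) pixels this reduces to a Rayleigh distribution with
mean ``sigma * sqrt(pi/2)``, which is exactly the structured noise floor
the pixel classifier must learn to reject.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dicom_io import RelaxationSeries, SeriesMode
from .physics import full_signal

__all__ = [
    "DEFAULT_TR_PROTOCOL_MS",
    "DEFAULT_TE_PROTOCOL_MS",
    "NoiseModel",
    "TubeSpec",
    "PhantomSpec",
    "AcquisitionProtocol",
    "PhantomGroundTruth",
    "molar_concentration",
    "default_phantom_spec",
    "t1_protocol",
    "t2_protocol",
    "render_series",
]

#: The 23-point saturation-recovery TR ladder (ms) used for T1 mapping:
#: dense at short TR where the recovery curve bends, sparse out to 15 s
#: so the longest TR exceeds 5x the longest expected T1.
DEFAULT_TR_PROTOCOL_MS: tuple[float, ...] = (
    40, 50, 60, 78, 80, 100, 120, 140, 200, 240, 300, 400,
    500, 600, 700, 800, 1000, 1500, 2000, 3000, 5000, 10000, 15000,
)

#: Default T2-mapping echo ladder: 20 geometrically spaced TEs, 10-500 ms.
DEFAULT_TE_PROTOCOL_MS: tuple[float, ...] = tuple(
    float(x) for x in np.round(np.geomspace(10.0, 500.0, 20), 3)
)

#: Default fixed TE (ms) during T1 mapping.
DEFAULT_FIXED_TE_MS = 20.0

#: Default fixed TR (ms) during T2 mapping (long enough for full recovery).
DEFAULT_FIXED_TR_MS = 15000.0


class NoiseModel(enum.Enum):
    RICIAN = "rician"
    GAUSSIAN = "gaussian"


def molar_concentration(mass_g: float, molar_mass: float, volume_l: float) -> float:
    """Molarity ``m / (M * V)`` in mol/L, for solution bookkeeping."""
    if molar_mass <= 0 or volume_l <= 0:
        raise ValueError("molar mass and volume must be > 0")
    if mass_g < 0:
        raise ValueError("mass must be >= 0")
    return mass_g / (molar_mass * volume_l)


@dataclass(frozen=True)
class TubeSpec:
    """One disk-shaped sample tube in the field of view."""

    center: tuple[float, float]  # (row, col), pixels
    radius: float                # pixels
    t1: float                    # ms
    t2: float                    # ms
    amplitude: float             # arbitrary units

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("tube radius must be >= 1 px")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("relaxation times must be > 0 ms")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom scene consumed by :func:`render_series`."""

    shape: tuple[int, int]
    tubes: tuple[TubeSpec, ...]
    noise_sigma: float = 0.0
    noise_model: NoiseModel = NoiseModel.RICIAN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        tubes = tuple(self.tubes)
        for i, a in enumerate(tubes):
            for b in tubes[i + 1:]:
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.radius + b.radius:
                    raise ValueError(f"tubes overlap: {a} and {b}")
        object.__setattr__(self, "tubes", tubes)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Which time parameter varies, its sample points, and the fixed one."""

    mode: SeriesMode
    times: tuple[float, ...]
    fixed_time: float

    def __post_init__(self) -> None:
        if len(self.times) == 0:
            raise ValueError("protocol needs at least one acquisition time")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("protocol times must be strictly increasing")


def t1_protocol(
    times: Sequence[float] = DEFAULT_TR_PROTOCOL_MS,
    fixed_te: float = DEFAULT_FIXED_TE_MS,
) -> AcquisitionProtocol:
    return AcquisitionProtocol(SeriesMode.T1_SERIES, tuple(times), fixed_te)


def t2_protocol(
    times: Sequence[float] = DEFAULT_TE_PROTOCOL_MS,
    fixed_tr: float = DEFAULT_FIXED_TR_MS,
) -> AcquisitionProtocol:
    return AcquisitionProtocol(SeriesMode.T2_SERIES, tuple(times), fixed_tr)


def default_phantom_spec(seed: int = 0) -> PhantomSpec:
    """Five-tube phantom: a concentration ladder plus a water-like tube.

    T1 spans 150-3000 ms (each step >= 20% apart, and the longest under
    TR_max/5 so the recovery curve is fully sampled); T2 and amplitude
    are likewise pairwise distinct, mimicking tubes of visibly different
    maximum intensity. Noise sigma 20 against amplitudes near 1000 gives
    an SNR of about 50, typical of a well-set-up magnitude acquisition.
    """
    tubes = (
        TubeSpec(center=(32, 32), radius=12, t1=150.0, t2=60.0, amplitude=1300.0),
        TubeSpec(center=(32, 96), radius=12, t1=350.0, t2=110.0, amplitude=1150.0),
        TubeSpec(center=(64, 64), radius=12, t1=800.0, t2=200.0, amplitude=1000.0),
        TubeSpec(center=(96, 32), radius=12, t1=1600.0, t2=400.0, amplitude=850.0),
        TubeSpec(center=(96, 96), radius=12, t1=3000.0, t2=1500.0, amplitude=700.0),
    )
    return PhantomSpec(
        shape=(128, 128),
        tubes=tubes,
        noise_sigma=20.0,
        noise_model=NoiseModel.RICIAN,
        seed=seed,
    )


@dataclass
class PhantomGroundTruth:
    """Per-pixel truth rendered alongside a synthetic series."""

    t1_map: np.ndarray
    t2_map: np.ndarray
    amplitude_map: np.ndarray
    mask: np.ndarray        # 1 inside any tube, 0 in aerated background
    label_map: np.ndarray   # 0 background, 1..n_tubes tube index
    tubes: tuple[TubeSpec, ...] = field(default_factory=tuple)


def _rasterize(spec: PhantomSpec) -> PhantomGroundTruth:
    rows, cols = spec.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    t1 = np.zeros(spec.shape)
    t2 = np.zeros(spec.shape)
    amp = np.zeros(spec.shape)
    label = np.zeros(spec.shape, dtype=int)
    for i, tube in enumerate(spec.tubes, start=1):
        inside = (rr - tube.center[0]) ** 2 + (cc - tube.center[1]) ** 2 <= tube.radius**2
        t1[inside] = tube.t1
        t2[inside] = tube.t2
        amp[inside] = tube.amplitude
        label[inside] = i
    return PhantomGroundTruth(
        t1_map=t1,
        t2_map=t2,
        amplitude_map=amp,
        mask=(label > 0).astype(np.uint8),
        label_map=label,
        tubes=spec.tubes,
    )


def render_series(
    spec: PhantomSpec,
    protocol: AcquisitionProtocol,
) -> tuple[RelaxationSeries, PhantomGroundTruth]:
    """Render a phantom through a protocol into a noisy magnitude series.

    Inside-tube pixels follow the product-form spin-echo signal with the
    tube's T1/T2/amplitude; background signal is exactly zero before
    noise. Rendering is reproducible from ``spec.seed``.
    """
    truth = _rasterize(spec)
    rows, cols = spec.shape
    k = len(protocol.times)
    clean = np.zeros((rows, cols, k))

    for i, tube in enumerate(spec.tubes, start=1):
        inside = truth.label_map == i
        if protocol.mode is SeriesMode.T1_SERIES:
            curve = full_signal(
                tube.amplitude, np.asarray(protocol.times), protocol.fixed_time,
                tube.t1, tube.t2,
            )
        else:
            curve = full_signal(
                tube.amplitude, protocol.fixed_time, np.asarray(protocol.times),
                tube.t1, tube.t2,
            )
        clean[inside, :] = curve

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma == 0:
        noisy = clean
    elif spec.noise_model is NoiseModel.RICIAN:
        n1 = rng.normal(0.0, spec.noise_sigma, clean.shape)
        n2 = rng.normal(0.0, spec.noise_sigma, clean.shape)
        noisy = np.hypot(clean + n1, n2)
    else:
        # Linear-regime additive noise; clipped at zero because stored
        # magnitude intensities cannot be negative.
        noisy = np.clip(clean + rng.normal(0.0, spec.noise_sigma, clean.shape), 0.0, None)

    series = RelaxationSeries(
        pixels=noisy,
        times=np.asarray(protocol.times, dtype=float),
        mode=protocol.mode,
        fixed_time=protocol.fixed_time,
        pixel_spacing=(1.0, 1.0),
    )
    return series, truth
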