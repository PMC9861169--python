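"""Closed-form MR signal physics.

The two workhorse models of saturation-recovery relaxometry are

* longitudinal recovery  (T1 mode):  ``SI(TR) = A * (1 - exp(-TR / T1))``
* transverse decay       (T2 mode):  ``SI(TE) = A * exp(-TE / T2)``

with the amplitude ``A`` absorbing proton density and the exponential
factor of whichever time parameter is held fixed during the acquisition.
All times are in milliseconds throughout the package.

The module also houses the proton gyromagnetic constant and the
63.2% / 36.8% characteristic-point utilities used to initialise the
nonlinear least-squares fits in :mod:`relaxmap.fitting`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "GAMMA_OVER_2PI_MHZ_PER_T",
    "SR_FRACTION",
    "DECAY_FRACTION",
    "RelaxationMode",
    "SignalModelParams",
    "larmor_frequency",
    "relaxation_signal",
    "full_signal",
    "CharacteristicEstimate",
    "characteristic_time_estimate",
]

#: Proton gyromagnetic ratio over 2*pi, in MHz per tesla (CODATA value to
#: the precision relevant for clinical field strengths).
GAMMA_OVER_2PI_MHZ_PER_T = 42.57747892

#: Fraction of the recovery plateau reached at TR == T1: 1 - 1/e.
SR_FRACTION = 1.0 - math.exp(-1.0)

#: Fraction of the initial intensity remaining at TE == T2: 1/e.
DECAY_FRACTION = math.exp(-1.0)


class RelaxationMode(enum.Enum):
    """Which single-exponential model a time series follows."""

    SR_RECOVERY = "sr_recovery"  # saturation recovery, varied TR -> T1
    DECAY = "decay"              # monoexponential decay, varied TE -> T2


@dataclass(frozen=True)
class SignalModelParams:
    """Parameters of the two-parameter relaxation model.

    amplitude
        Effective signal amplitude (arbitrary units); absorbs proton
        density and the fixed-time exponential factor.
    relax_time
        T1 or T2 in milliseconds, depending on ``mode``.
    """

    amplitude: float
    relax_time: float
    mode: RelaxationMode

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.relax_time <= 0:
            raise ValueError(f"relax_time must be > 0, got {self.relax_time}")


def larmor_frequency(b0: float) -> float:
    """Proton precession frequency f0 = gamma*B0/(2*pi) in MHz.

    Parameters
    ----------
    b0
        Magnetic flux density in tesla; must be non-negative.
    """
    if b0 < 0:
        raise ValueError(f"field strength must be >= 0 T, got {b0}")
    return GAMMA_OVER_2PI_MHZ_PER_T * b0


def relaxation_signal(t, params: SignalModelParams):
    """Evaluate the relaxation model at time(s) ``t`` (ms).

    SR_RECOVERY returns ``A*(1 - exp(-t/T))`` (monotone increasing);
    DECAY returns ``A*exp(-t/T)`` (monotone decreasing). Accepts scalars
    or arrays.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0 ms")
    decay = np.exp(-t_arr / params.relax_time)
    if params.mode is RelaxationMode.SR_RECOVERY:
        out = params.amplitude * (1.0 - decay)
    else:
        out = params.amplitude * decay
    return out if out.ndim else float(out)


def full_signal(pd: float, tr, te, t1: float, t2: float):
    """Product-form spin-echo signal ``PD*(1-exp(-TR/T1))*exp(-TE/T2)``.

    Reduces to the SR recovery model as TE -> 0 and to the decay model
    as TR -> infinity. ``tr``/``te`` may be scalars or arrays (ms).
    """
    if t1 <= 0 or t2 <= 0:
        raise ValueError("relaxation times must be > 0 ms")
    tr_arr = np.asarray(tr, dtype=float)
    te_arr = np.asarray(te, dtype=float)
    if np.any(tr_arr < 0) or np.any(te_arr < 0):
        raise ValueError("TR and TE must be >= 0 ms")
    out = pd * (1.0 - np.exp(-tr_arr / t1)) * np.exp(-te_arr / t2)
    return out if np.ndim(out) else float(out)


class CharacteristicEstimate(NamedTuple):
    """Result of the 63%/37% characteristic-point estimate.

    ``crossed`` is False when the sampled curve never reaches the
    characteristic level, in which case ``time_ms`` is a fallback (half
    the largest sampled time) and the caller should fit with bounds.
    """

    time_ms: float
    crossed: bool


def characteristic_time_estimate(
    times: Sequence[float],
    intensities: Sequence[float],
    mode: RelaxationMode,
) -> CharacteristicEstimate:
    """Estimate T1/T2 from the first crossing of the characteristic level.

    For SR recovery the level is 63.212% of the plateau (mean of the two
    largest-time samples, valid when the longest time >> T); for decay it
    is 36.788% of the initial intensity. Linear interpolation between the
    bracketing samples gives the crossing time. In decay mode the level is
    relative to the first *sampled* intensity y(t0), so the crossing sits
    at t0 + T and t0 is subtracted. This is a coarse seed for the
    nonlinear fit, not an estimator in its own right.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size < 2 or t.size != y.size:
        raise ValueError("need >= 2 (time, intensity) samples of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    fallback = CharacteristicEstimate(float(t[-1]) / 2.0, False)

    if mode is RelaxationMode.SR_RECOVERY:
        plateau = float(np.mean(y[-2:]))
        if plateau <= 0:
            return fallback
        level = SR_FRACTION * plateau
        above = y >= level
    else:
        initial = float(y[0])
        if initial <= 0:
            return fallback
        level = DECAY_FRACTION * initial
        above = y <= level

    idx = np.flatnonzero(above)
    if idx.size == 0:
        return fallback
    i = int(idx[0])
    if i == 0:
        crossing = float(t[0])
    else:
        y0, y1 = float(y[i - 1]), float(y[i])
        if y1 == y0:
            crossing = 0.5 * float(t[i - 1] + t[i])
        else:
            crossing = float(t[i - 1] + (level - y0) * (t[i] - t[i - 1]) / (y1 - y0))
    if mode is RelaxationMode.DECAY:
        crossing = max(crossing - float(t[0]), 0.5 * float(t[1] - t[0]))
    return CharacteristicEstimate(crossing, True)
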