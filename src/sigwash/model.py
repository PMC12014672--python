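"""Double-sigmoid response model and its derived temporal metrics.

The normalized analgesic response to a stimulation epoch is modelled as the
product of a rising and a falling logistic,

    f(t) = I * S1(t) * S2(t),    S_k(t) = 1 / (1 + exp(-a_k (t - t_mid_k))),

where ``I`` scales the magnitude of the threshold reversal, ``a1 > 0`` and
``a2 < 0`` set the steepness of the ramp-up (wash-in) and wind-down
(wash-out) phases, and ``t_mid1`` / ``t_mid2`` are the half-rise and
half-decay times in minutes.  Everything here is a pure function of the
parameters; fitting and quality control live in :mod:`sigwash.fitting`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import InvalidInputError

__all__ = [
    "SigmoidParams",
    "TemporalMetrics",
    "double_sigmoid",
    "double_sigmoid_derivative",
    "slopes_at_midpoints",
    "fwhm_normalized",
    "temporal_metrics",
]


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the double-sigmoid response curve.

    Attributes
    ----------
    I : float
        Unitless scaling factor (magnitude of the normalized reversal).
        Negative values describe a response running opposite to the
        expected direction and are flagged downstream, not rejected here.
    a1, a2 : float
        Steepness of the ramp-up and wind-down phases, 1/min.  The
        canonical forward model has ``a1 > 0`` and ``a2 < 0``, but during
        fitting either may take any sign.
    t_mid1, t_mid2 : float
        Half-rise and half-decay times, minutes.
    """

    I: float
    a1: float
    a2: float
    t_mid1: float
    t_mid2: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(f"non-finite sigmoid parameters: {arr}")

    def as_array(self) -> np.ndarray:
        return np.array([self.I, self.a1, self.a2, self.t_mid1, self.t_mid2], float)

    @classmethod
    def from_array(cls, theta) -> "SigmoidParams":
        theta = np.asarray(theta, float)
        if theta.shape != (5,):
            raise InvalidInputError(f"expected 5 parameters, got shape {theta.shape}")
        return cls(*theta)


@dataclass(frozen=True)
class TemporalMetrics:
    """Wash-in/wash-out summary of a fitted curve.

    ``slope1``/``slope2`` are the first derivative of the fitted curve at
    its own midpoints (1/min); ``fwhm_norm`` is ``(t_mid2 - t_mid1)``
    normalized by the stimulation duration (unitless fraction).
    """

    slope1: float
    slope2: float
    fwhm_norm: float


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidInputError("time values must be finite")
    return t


def double_sigmoid(t, p: SigmoidParams):
    """Evaluate ``I * S1(t) * S2(t)`` at time(s) ``t`` (minutes).

    Uses :func:`scipy.special.expit`, which saturates rather than
    overflows for arbitrarily large exponent arguments, so extreme
    steepness explored by the optimizer is safe.
    """
    t = _check_times(t)
    s1 = expit(p.a1 * (t - p.t_mid1))
    s2 = expit(p.a2 * (t - p.t_mid2))
    return p.I * s1 * s2


def double_sigmoid_derivative(t, p: SigmoidParams):
    """Analytic first derivative of the double sigmoid, 1/min.

    f'(t) = I * [a1 S1 (1 - S1) S2 + a2 S2 (1 - S2) S1].
    """
    t = _check_times(t)
    s1 = expit(p.a1 * (t - p.t_mid1))
    s2 = expit(p.a2 * (t - p.t_mid2))
    return p.I * (p.a1 * s1 * (1.0 - s1) * s2 + p.a2 * s2 * (1.0 - s2) * s1)


def slopes_at_midpoints(p: SigmoidParams) -> tuple[float, float]:
    """Wash-in and wash-out rates: f'(t_mid1) and f'(t_mid2), in 1/min.

    When the two phases are well separated these approach ``I*a1/4`` and
    ``I*a2/4``; they are evaluated exactly from the analytic derivative,
    which matters when the phases overlap.
    """
    slope1 = float(double_sigmoid_derivative(p.t_mid1, p))
    slope2 = float(double_sigmoid_derivative(p.t_mid2, p))
    return slope1, slope2


def fwhm_normalized(p: SigmoidParams, t_stim: float) -> float:
    """Full-width-half-maximum of the response as a fraction of ``t_stim``.

    Defined operationally as ``(t_mid2 - t_mid1) / t_stim``.  A negative
    value signals an inverted fit (``t_mid2 < t_mid1``) and is preserved
    so quality control can flag it.
    """
    if not np.isfinite(t_stim) or t_stim <= 0:
        raise InvalidInputError(f"t_stim must be positive, got {t_stim}")
    return (p.t_mid2 - p.t_mid1) / float(t_stim)


def temporal_metrics(p: SigmoidParams, t_stim: float) -> TemporalMetrics:
    """Bundle slopes and normalized FWHM for a parameter set."""
    slope1, slope2 = slopes_at_midpoints(p)
    return TemporalMetrics(slope1=slope1, slope2=slope2,
                           fwhm_norm=fwhm_normalized(p, t_stim))
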