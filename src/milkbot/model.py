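"""Closed-form MilkBot lactation model and derived metrics.

The MilkBot model describes daily milk yield ``Y(t)`` of a dairy cow as a
function of days in milk (DIM, ``t``, with t = 1 at parturition)::

    Y(t) = scale * (1 - exp((offset - t)/ramp) / 2) * exp(-decay * t)

It factors a lactation into a saturating *growth* of productive capacity
(one minus half a decaying exponential — the integral of a right-sided
Laplace growth-rate density) times a first-order exponential *death*
(senescence) process, times a magnitude scalar:

* ``scale`` (kg/day) — theoretical maximum daily yield; pure magnitude.
* ``ramp`` (days) — time constant of the early-lactation rise; when one
  ramp has elapsed past ``offset``, growth is ~82% complete.
* ``offset`` (days) — lag between parturition and the growth midpoint
  (the "start of lactation"); may be negative, and is nearly
  unidentifiable from monthly test data.
* ``decay`` (1/day) — senescence rate; ``0.693/decay`` is the lactation's
  persistency expressed as a production half-life.

Everything downstream (peak day/milk, 305-day cumulative yield M305,
persistency) has a closed form, implemented here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MilkBotParams",
    "DerivedMetrics",
    "growthrate",
    "growth",
    "death",
    "predict",
    "peak_day",
    "peak_milk",
    "persistence",
    "cumulative",
    "m305",
    "peak_to_m305_multiplier",
    "derived_metrics",
    "PERSISTENCE_CONSTANT",
    "EXP_CLAMP",
    "DECAY_LIMIT_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Half-life constant used for persistency, kept at the conventional
#: rounded value 0.693 rather than ln 2 = 0.693147... (difference < 0.03%).
PERSISTENCE_CONSTANT = 0.693

#: Exponent arguments are clamped to +/- this value before exponentiation
#: so extreme ramp -> 0 inputs overflow gracefully instead of raising.
EXP_CLAMP = 700.0

#: Below this decay the closed forms that divide by decay switch to their
#: analytic decay -> 0 limit branch.
DECAY_LIMIT_THRESHOLD = 1e-12


def _safe_exp(x):
    """exp with arguments clamped at +/-EXP_CLAMP; clamping is logged."""
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > EXP_CLAMP):
        logger.debug("exponent argument clamped to +/-%g", EXP_CLAMP)
        x = np.clip(x, -EXP_CLAMP, EXP_CLAMP)
    return np.exp(x)


@dataclass(frozen=True)
class MilkBotParams:
    """The four MilkBot parameters.

    Parameters
    ----------
    scale : float
        Magnitude parameter ``a`` (kg/day). Must be positive.
    ramp : float
        Rise time constant ``b`` (days). Must be positive.
    offset : float
        Parturition-to-lactation-start lag ``c`` (days). Any sign.
    decay : float
        Senescence rate ``d`` (1/day). Must be positive under normal
        fitting; ``decay = 0`` is accepted for analytic limit work
        (the flat-curve limit), but peak and persistency are then
        undefined.
    """

    scale: float
    ramp: float
    offset: float
    decay: float

    def __post_init__(self):
        for name in ("scale", "ramp", "offset", "decay"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.ramp <= 0:
            raise ValueError(f"ramp must be positive, got {self.ramp}")
        if self.decay < 0:
            raise ValueError(f"decay must be nonnegative, got {self.decay}")

    def with_scale(self, scale: float) -> "MilkBotParams":
        """Copy with a different scale (unit conversion touches scale only)."""
        return MilkBotParams(scale, self.ramp, self.offset, self.decay)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.scale, self.ramp, self.offset, self.decay)


@dataclass(frozen=True)
class DerivedMetrics:
    """Whole-lactation metrics computed in closed form from the parameters."""

    t_peak: float  # days
    y_peak: float  # kg/day
    persistence: float  # days
    m305: float  # kg
    peak_to_m305_multiplier: float  # dimensionless (kg M305 per kg scale)


# ---------------------------------------------------------------------------
# Model factors
# ---------------------------------------------------------------------------

def growthrate(params: MilkBotParams, t):
    """Rate of creation of productive capacity at DIM ``t`` (1/day).

    A right-sided Laplace density ``(1/(2 ramp)) exp((offset - t)/ramp)``,
    defined for ``t > offset`` only; its integral over (offset, inf) is 1/2.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= params.offset):
        raise ValueError(
            "growthrate is defined for t > offset only "
            f"(right-sided Laplace restriction); got t={t}, offset={params.offset}"
        )
    out = _safe_exp((params.offset - t) / params.ramp) / (2.0 * params.ramp)
    return out if out.ndim else float(out)


def growth(params: MilkBotParams, t):
    """Cumulative growth fraction of productive capacity at DIM ``t``.

    ``1 - exp((offset - t)/ramp)/2``: equals 1/2 at ``t = offset`` by
    definition of offset and approaches 1 as ``t`` grows. For ``t`` far
    below ``offset`` the value drops below 1/2 and can be negative; this
    is the analytic continuation of the right-sided form and is returned
    unclamped.
    """
    t = np.asarray(t, dtype=float)
    out = 1.0 - _safe_exp((params.offset - t) / params.ramp) / 2.0
    return out if out.ndim else float(out)


def death(params: MilkBotParams, t):
    """Senescence survival fraction ``exp(-decay * t)`` at DIM ``t >= 0``."""
    t = np.asarray(t, dtype=float)
    out = _safe_exp(-params.decay * t)
    return out if out.ndim else float(out)


def predict(params: MilkBotParams, t):
    """Expected daily milk yield (kg/day) at DIM ``t`` (scalar or array).

    ``scale * growth(t) * death(t)``; continuous, with a single interior
    maximum when ``decay > 0``.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    out = params.scale * np.asarray(growth(params, t)) * np.asarray(death(params, t))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Derived metrics
# ---------------------------------------------------------------------------

def peak_day(params: MilkBotParams) -> float:
    """DIM of maximum predicted yield.

    ``offset - ramp * ln(2 ramp decay / (1 + ramp decay))``. For large
    ``ramp * decay`` (> 1) this lies before parturition; the analytic
    value is returned untruncated and callers may flag it.
    """
    b, d = params.ramp, params.decay
    if d <= 0:
        raise ValueError("peak_day requires decay > 0 (no interior peak)")
    return params.offset - b * math.log(2.0 * b * d / (1.0 + b * d))


def peak_milk(params: MilkBotParams) -> float:
    """Maximum predicted daily yield (kg/day), ``Y(t_peak)``; < scale."""
    return float(predict(params, peak_day(params)))


def persistence(params: MilkBotParams) -> float:
    """Lactation persistency as a half-life: ``0.693 / decay`` (days)."""
    if params.decay <= 0:
        raise ValueError("persistence requires decay > 0")
    return PERSISTENCE_CONSTANT / params.decay


def _antiderivative(params: MilkBotParams, t: float) -> float:
    """Closed-form antiderivative of predict at t (decay > threshold)."""
    a, b, c, d = params.as_tuple()
    term1 = -a * float(_safe_exp(-d * t)) / d
    k = a * b / (2.0 * (1.0 + b * d))
    term2 = k * float(_safe_exp(c / b - t * (1.0 / b + d)))
    return term1 + term2


def cumulative(params: MilkBotParams, t_start: float, t_end: float) -> float:
    """Cumulative milk yield (kg) between two DIM values, in closed form.

    Integrates ``predict`` exactly: the antiderivative is
    ``-a e^{-dt}/d + (ab/(2(1+bd))) e^{c/b} e^{-t(1/b + d)}``.
    For ``decay`` below ``DECAY_LIMIT_THRESHOLD`` the analytic
    ``decay -> 0`` limit is used (first term becomes ``a * t``).
    Additive over adjacent intervals.
    """
    if not (0 <= t_start < t_end):
        raise ValueError(
            f"require 0 <= t_start < t_end, got [{t_start}, {t_end}]"
        )
    a, b, c, d = params.as_tuple()
    if d < DECAY_LIMIT_THRESHOLD:
        flat = a * (t_end - t_start)
        k = a * b / 2.0
        tail = k * float(
            _safe_exp(c / b - t_end / b) - _safe_exp(c / b - t_start / b)
        )
        return flat + tail
    return _antiderivative(params, t_end) - _antiderivative(params, t_start)


def m305(params: MilkBotParams) -> float:
    """305-day cumulative yield M305 (kg), closed form.

    ``(a - a e^{-305 d})/d + a b e^{c/b}(e^{-305(1/b + d)} - 1)/(2 + 2 b d)``
    with an analytic ``decay -> 0`` limit branch. Identical to
    ``cumulative(params, 0, 305)``.
    """
    a, b, c, d = params.as_tuple()
    if d < DECAY_LIMIT_THRESHOLD:
        return cumulative(params, 0.0, 305.0)
    term1 = (a - a * float(_safe_exp(-305.0 * d))) / d
    term2 = (
        a * b * float(_safe_exp(c / b))
        * (-1.0 + float(_safe_exp(-305.0 * (1.0 / b + d))))
    ) / (2.0 + 2.0 * b * d)
    return term1 + term2


def peak_to_m305_multiplier(params: MilkBotParams) -> float:
    """Change in M305 (kg) per unit increase of the scale parameter.

    Closed form::

        (2 - 2 e^{-305 d} + 2 d b - 2 d b e^{-305 d}
         + d b e^{-305 d - 305/b + c/b} - d b e^{c/b}) / (2 (d + d^2 b))

    Because both M305 and peak milk are linear in scale, this multiplier
    equals ``m305 / scale`` exactly; the analogous "M305 per unit of peak
    milk" ratio is simply ``m305 / peak_milk``.
    """
    a, b, c, d = params.as_tuple()
    if d < DECAY_LIMIT_THRESHOLD:
        return m305(params) / a
    E = lambda x: float(_safe_exp(x))  # noqa: E731
    num = (
        2.0
        - 2.0 * E(-305.0 * d)
        + 2.0 * d * b
        - 2.0 * d * E(-305.0 * d) * b
        + d * E(-305.0 * d - 305.0 / b + c / b) * b
        - d * E(c / b) * b
    )
    return num / (2.0 * (d + d * d * b))


def derived_metrics(params: MilkBotParams) -> DerivedMetrics:
    """All closed-form whole-lactation metrics for one parameter set."""
    return DerivedMetrics(
        t_peak=peak_day(params),
        y_peak=peak_milk(params),
        persistence=persistence(params),
        m305=m305(params),
        peak_to_m305_multiplier=peak_to_m305_multiplier(params),
    )
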