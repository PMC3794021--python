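"""Time-dependent model drivers: population, consumption and yield.

The land-use model is forced by three slowly saturating quantities — world
population ``p(t)`` (persons), per-capita food consumption ``c(t)``
(kg/person/year) and agricultural yield ``y(t)`` (kg/ha/year) — each
represented as a vertically translated logistic curve

    x(t) = x0 + K / (1 + exp(-r * (t - tI)))

where ``x0`` is the pre-industrial floor, ``K`` the asymptotic gain above the
floor, ``r`` the growth rate (1/yr) and ``tI`` the inflection year (A.D.).
The translation fixes the initial condition: x(t) -> x0 as t -> -inf and
x(t) -> x0 + K as t -> +inf.

Beyond the plain logistic, this module provides two ways of extending a
driver past a chosen year ``t_e`` (typically the end of the observational
record):

* a *smooth logistic continuation* — a new logistic with the same floor and
  a different asymptotic gain whose value and slope match the original curve
  at ``t_e`` (used for the two-parameter phase scan), and
* a *linear extension* — tangent-line growth after ``t_e`` (the "sustained
  linear growth" scenario).

A :class:`ScaledDriver` multiplies a driver by a smooth piecewise-linear
gain, used by the consumption-reduction (land-sparing) scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DriverError",
    "LogisticDriver",
    "ExtendedDriver",
    "ScaledDriver",
    "DriverSet",
    "eval_driver",
    "driver_rate",
    "make_continuation",
    "make_linear_extension",
]

# |r*(t-tI)| beyond which the logistic is numerically at its asymptote;
# exp(+-700) is still finite in double precision so no overflow occurs.
_EXP_CAP = 700.0


class DriverError(ValueError):
    """Invalid driver parameters or an impossible continuation."""


class BaseDriver:
    """Minimal driver interface: a value and an analytic rate, both in time."""

    def value(self, t: float) -> float:
        raise NotImplementedError

    def rate(self, t: float) -> float:
        raise NotImplementedError

    def value_and_rate(self, t: float) -> tuple[float, float]:
        """Value and rate together (one exponential for logistic drivers)."""
        return self.value(t), self.rate(t)


@dataclass(frozen=True)
class LogisticDriver(BaseDriver):
    """A vertically translated logistic curve.

    Parameters
    ----------
    x0 : float
        Pre-industrial floor, in the driver's units (>= 0).
    K : float
        Asymptotic gain above the floor (> 0), same units.
    r : float
        Growth rate, 1/yr (> 0).
    tI : float
        Inflection year, A.D.
    """

    x0: float
    K: float
    r: float
    tI: float

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise DriverError(f"K must be > 0, got {self.K}")
        if not self.r > 0:
            raise DriverError(f"r must be > 0, got {self.r}")
        if self.x0 < 0:
            raise DriverError(f"x0 must be >= 0, got {self.x0}")

    @property
    def asymptote(self) -> float:
        """The t -> +inf value x0 + K."""
        return self.x0 + self.K

    def value(self, t: float) -> float:
        z = self.r * (t - self.tI)
        if z >= _EXP_CAP:
            return self.x0 + self.K
        if z <= -_EXP_CAP:
            return self.x0
        return self.x0 + self.K / (1.0 + math.exp(-z))

    def rate(self, t: float) -> float:
        z = self.r * (t - self.tI)
        if z >= _EXP_CAP or z <= -_EXP_CAP:
            return 0.0
        e = math.exp(-z)
        return self.r * self.K * e / ((1.0 + e) * (1.0 + e))

    def value_and_rate(self, t: float) -> tuple[float, float]:
        z = self.r * (t - self.tI)
        if z >= _EXP_CAP:
            return self.x0 + self.K, 0.0
        if z <= -_EXP_CAP:
            return self.x0, 0.0
        e = math.exp(-z)
        denom = 1.0 + e
        return self.x0 + self.K / denom, self.r * self.K * e / (denom * denom)


@dataclass(frozen=True)
class ExtendedDriver(BaseDriver):
    """A driver equal to ``base`` up to ``t_e`` and extended smoothly beyond.

    ``mode`` is either ``"logistic-continuation"`` (``ext`` holds the
    re-solved logistic) or ``"linear-extension"`` (tangent line from
    ``(t_e, v_e)`` with slope ``m_e``).  Value and first derivative are
    continuous at ``t_e`` by construction.
    """

    base: BaseDriver
    t_e: float
    mode: str
    ext: LogisticDriver | None = None
    v_e: float = 0.0
    m_e: float = 0.0

    @property
    def x0(self) -> float:
        return self.base.x0  # type: ignore[attr-defined]

    @property
    def asymptote(self) -> float:
        if self.mode == "logistic-continuation":
            assert self.ext is not None
            return self.ext.asymptote
        return math.inf

    def value(self, t: float) -> float:
        if t <= self.t_e:
            return self.base.value(t)
        if self.mode == "logistic-continuation":
            assert self.ext is not None
            return self.ext.value(t)
        return self.v_e + self.m_e * (t - self.t_e)

    def rate(self, t: float) -> float:
        if t <= self.t_e:
            return self.base.rate(t)
        if self.mode == "logistic-continuation":
            assert self.ext is not None
            return self.ext.rate(t)
        return self.m_e

    def value_and_rate(self, t: float) -> tuple[float, float]:
        if t <= self.t_e:
            return self.base.value_and_rate(t)
        if self.mode == "logistic-continuation":
            assert self.ext is not None
            return self.ext.value_and_rate(t)
        return self.v_e + self.m_e * (t - self.t_e), self.m_e


@dataclass(frozen=True)
class ScaledDriver(BaseDriver):
    """``base`` multiplied by a gain ramping linearly from 1 to ``factor``.

    The gain is 1 for t <= t_on, ``factor`` for t >= t_on + ramp_years, and
    linear in between, so the product is continuous (its slope has the two
    ramp-corner kinks).  Used for consumption-reduction scenarios; the ramp
    avoids injecting a step into the land-conversion rates.
    """

    base: BaseDriver
    factor: float
    t_on: float
    ramp_years: float = 10.0

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise DriverError(f"factor must be > 0, got {self.factor}")
        if not self.ramp_years > 0:
            raise DriverError(f"ramp_years must be > 0, got {self.ramp_years}")

    def _gain(self, t: float) -> tuple[float, float]:
        """Gain g(t) and its derivative."""
        if t <= self.t_on:
            return 1.0, 0.0
        if t >= self.t_on + self.ramp_years:
            return self.factor, 0.0
        slope = (self.factor - 1.0) / self.ramp_years
        return 1.0 + slope * (t - self.t_on), slope

    def value(self, t: float) -> float:
        g, _ = self._gain(t)
        return g * self.base.value(t)

    def rate(self, t: float) -> float:
        g, gdot = self._gain(t)
        v, m = self.base.value_and_rate(t)
        return g * m + gdot * v

    def value_and_rate(self, t: float) -> tuple[float, float]:
        g, gdot = self._gain(t)
        v, m = self.base.value_and_rate(t)
        return g * v, g * m + gdot * v


@dataclass(frozen=True)
class DriverSet:
    """The three model drivers plus the urban footprint per person.

    Attributes
    ----------
    p, c, y : BaseDriver
        Population (persons), per-capita consumption (kg/person/yr) and
        yield (kg/ha/yr).
    s : float
        Urban area required per person, ha/person (> 0); held constant.
    """

    p: BaseDriver
    c: BaseDriver
    y: BaseDriver
    s: float

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise DriverError(f"s must be > 0, got {self.s}")

    def replace(self, **kwargs) -> "DriverSet":
        fields = {"p": self.p, "c": self.c, "y": self.y, "s": self.s}
        fields.update(kwargs)
        return DriverSet(**fields)


def eval_driver(d: BaseDriver, t):
    """Evaluate a driver at scalar or array times ``t`` (years A.D.)."""
    if np.ndim(t) == 0:
        return d.value(float(t))
    t = np.asarray(t, dtype=float)
    return np.array([d.value(ti) for ti in t])


def driver_rate(d: BaseDriver, t):
    """Analytic time derivative of a driver at scalar or array times."""
    if np.ndim(t) == 0:
        return d.rate(float(t))
    t = np.asarray(t, dtype=float)
    return np.array([d.rate(ti) for ti in t])


def make_continuation(d: LogisticDriver, t_e: float, K_new: float) -> ExtendedDriver:
    """Extend ``d`` past ``t_e`` with a logistic of asymptotic gain ``K_new``.

    The continuation keeps the floor ``x0`` and matches both the value and
    the slope of ``d`` at ``t_e``; closed form with ``v = d(t_e)``,
    ``m = d'(t_e)`` and ``q = (v - x0)/K_new``:

        r' = m / (K_new * q * (1 - q)),   tI' = t_e + ln((1-q)/q) / r'

    Raises
    ------
    DriverError
        If ``K_new`` does not exceed the current value above the floor
        (``q >= 1``): no saturating continuation exists (as q -> 1 the
        required rate r' diverges).
    """
    v, m = d.value_and_rate(t_e)
    q = (v - d.x0) / K_new
    if not 0.0 < q < 1.0:
        raise DriverError(
            f"continuation asymptote K_new={K_new} must exceed the current "
            f"value above the floor ({v - d.x0})"
        )
    r_new = m / (K_new * q * (1.0 - q))
    tI_new = t_e + math.log((1.0 - q) / q) / r_new
    ext = LogisticDriver(x0=d.x0, K=K_new, r=r_new, tI=tI_new)
    return ExtendedDriver(base=d, t_e=t_e, mode="logistic-continuation", ext=ext)


def make_linear_extension(d: BaseDriver, t_e: float) -> ExtendedDriver:
    """Extend ``d`` past ``t_e`` along its tangent line at ``t_e``."""
    v, m = d.value_and_rate(t_e)
    return ExtendedDriver(base=d, t_e=t_e, mode="linear-extension", v_e=v, m_e=m)
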