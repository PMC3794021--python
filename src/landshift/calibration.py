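"""Least-squares calibration of logistic drivers to annual series.

The driver curves are fit to annual observations (e.g. FAO population,
consumption or yield series) by minimising the sum of squared residuals of
the *vertically translated* data: the floor ``x0`` is fixed by the initial
condition and only the gain ``K``, rate ``r`` and inflection year ``tI``
are free.  Logistic fits are multimodal in (r, tI), so a small multistart
grid of initialisations is tried and the best residual kept.

Because the historical series themselves are external data, the module also
provides a seeded synthetic-series generator so that the calibration path
can be exercised (and its parameter-recovery behaviour measured) without
any download.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .drivers import LogisticDriver, eval_driver

__all__ = [
    "CalibrationError",
    "NonIdentifiableError",
    "AnnualSeries",
    "FitResult",
    "interpolate_anomalies",
    "fit_logistic",
    "synth_series",
    "constrain_initial_yield",
    "read_series_csv",
    "write_series_csv",
]


class CalibrationError(ValueError):
    """Fit failure or invalid calibration input."""


class NonIdentifiableError(CalibrationError):
    """The series does not constrain the logistic parameters (e.g. constant)."""


@dataclass(frozen=True)
class AnnualSeries:
    """An annual time series for one driver.

    ``years`` must be strictly increasing; ``label`` identifies the driver
    ("p", "c" or "y") and is carried through I/O round trips.
    """

    years: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.shape != values.shape or years.ndim != 1:
            raise CalibrationError("years and values must be 1-D and equal length")
        if np.any(np.diff(years) <= 0):
            raise CalibrationError("years must be strictly increasing")
        if np.any(~np.isfinite(values)):
            raise CalibrationError("values contain missing/non-finite entries")

    def __len__(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class FitResult:
    """A fitted driver with its residual sum of squares and R^2."""

    driver: LogisticDriver
    rss: float
    r2: float

    def __post_init__(self) -> None:
        if self.rss < 0 or self.r2 > 1.0 + 1e-12:
            raise CalibrationError("invalid fit diagnostics")


def interpolate_anomalies(s: AnnualSeries, flagged_years) -> AnnualSeries:
    """Replace flagged interior points by linear interpolation.

    Flagged values are re-drawn from the straight line between the nearest
    *unflagged* neighbours on each side, so consecutive flags share one
    bridging segment.  Flags at the series endpoints are rejected (there is
    no neighbour to anchor the interpolation).  The operation is idempotent.
    """
    flagged = set(float(y) for y in flagged_years)
    if not flagged:
        return s
    years = s.years
    if years[0] in flagged or years[-1] in flagged:
        raise CalibrationError("cannot interpolate anomalies at series endpoints")
    unknown = flagged - set(years.tolist())
    if unknown:
        raise CalibrationError(f"flagged years not in series: {sorted(unknown)}")
    mask = np.array([y in flagged for y in years])
    values = s.values.copy()
    values[mask] = np.interp(years[mask], years[~mask], values[~mask])
    return AnnualSeries(years=years, values=values, label=s.label)


def _logistic_residuals(theta, years, translated):
    K, r, tI = theta
    z = np.clip(r * (years - tI), -700.0, 700.0)
    return K / (1.0 + np.exp(-z)) - translated


def fit_logistic(s: AnnualSeries, x0: float) -> FitResult:
    """Fit (K, r, tI) of a translated logistic with the floor ``x0`` fixed.

    The residuals are unweighted and on the linear scale.  Initial guesses
    are a 3x3 multistart grid r in {0.01, 0.03, 0.1} x tI in {first, mid,
    last year}; the solution with the lowest residual sum of squares wins.
    R^2 is reported on the untranslated series.

    Raises
    ------
    NonIdentifiableError
        For a (near-)constant series, which leaves r unconstrained.
    CalibrationError
        If the series is too short, has values at or below the floor, or
        no start converges.
    """
    if len(s) < 5:
        raise CalibrationError("need at least 5 points to fit a logistic")
    translated = s.values - x0
    if np.any(translated <= 0):
        raise CalibrationError(
            "all values must lie above the floor x0 after translation"
        )
    scale = float(np.max(translated))
    if np.ptp(s.values) <= 1e-9 * max(1.0, float(np.max(np.abs(s.values)))):
        raise NonIdentifiableError(
            "series is constant: growth rate r is unconstrained"
        )

    years = s.years
    # fit on data normalised by the series scale for optimizer conditioning
    tnorm = translated / scale
    K0 = max(float(np.max(tnorm)), 1e-6)
    best = None
    t_starts = (years[0], 0.5 * (years[0] + years[-1]), years[-1])
    for r0 in (0.01, 0.03, 0.1):
        for tI0 in t_starts:
            try:
                res = least_squares(
                    _logistic_residuals,
                    x0=np.array([K0 * 1.5, r0, tI0]),
                    args=(years, tnorm),
                    bounds=([1e-12, 1e-6, years[0] - 2000.0],
                            [np.inf, 10.0, years[-1] + 2000.0]),
                    method="trf",
                )
            except Exception:  # noqa: BLE001 - a failed start is not fatal
                continue
            if not res.success:
                continue
            rss = float(2.0 * res.cost)
            if best is None or rss < best[0]:
                best = (rss, res.x)
    if best is None:
        raise CalibrationError("no multistart initialisation converged")

    K_hat = float(best[1][0]) * scale
    r_hat = float(best[1][1])
    tI_hat = float(best[1][2])
    driver = LogisticDriver(x0=x0, K=K_hat, r=r_hat, tI=tI_hat)
    fitted = eval_driver(driver, years)
    rss = float(np.sum((s.values - fitted) ** 2))
    tss = float(np.sum((s.values - s.values.mean()) ** 2))
    r2 = 1.0 - rss / tss
    return FitResult(driver=driver, rss=rss, r2=r2)


def synth_series(
    d: LogisticDriver,
    years,
    noise_sd: float,
    seed: int,
    label: str = "",
) -> AnnualSeries:
    """Seeded noisy observations of a driver: value(t) + N(0, noise_sd)."""
    if noise_sd < 0:
        raise CalibrationError("noise_sd must be >= 0")
    years = np.asarray(list(years), dtype=float)
    values = eval_driver(d, years)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=len(years))
    return AnnualSeries(years=years, values=np.asarray(values, dtype=float), label=label)


def constrain_initial_yield(grain_yield_kgha: float, ratio: float) -> float:
    """Upper bound on the pre-industrial yield floor y0.

    The all-product yield tracks cereal yield at a roughly constant ratio,
    so an estimate of historical grain yield times that ratio bounds y0
    (e.g. 700 kg/ha medieval grain x 0.6 -> 420 kg/ha).
    """
    if grain_yield_kgha <= 0 or ratio <= 0:
        raise CalibrationError("inputs must be positive")
    return ratio * grain_yield_kgha


def read_series_csv(path, label: str = "") -> AnnualSeries:
    """Read a two-column (year, value) CSV with a header row."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise CalibrationError(f"{path}: expected columns (year, value)")
    return AnnualSeries(
        years=df.iloc[:, 0].to_numpy(dtype=float),
        values=df.iloc[:, 1].to_numpy(dtype=float),
        label=label or str(df.columns[1]),
    )


def write_series_csv(s: AnnualSeries, path) -> None:
    """Write a series as a (year, value) CSV; the value column is labelled."""
    df = pd.DataFrame({"year": s.years, s.label or "value": s.values})
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
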