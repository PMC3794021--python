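"""Named experiments: baseline, linear growth, land sparing, sensitivity.

A :class:`ScenarioSpec` declares how the default drivers and parameters are
modified — logistic continuations, linear (tangent) extensions or scaled
consumption — and :func:`run_scenario` turns it into a stabilised
trajectory plus its transition classification.  Higher-level helpers
compute the land-sparing bookkeeping (ultimate areas saved by consuming
less) and the one-at-a-time parameter sensitivity table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .config import RunConfig, build_driver_set, build_model_params
from .core import (
    ModelParams,
    Trajectory,
    initialize_state,
    run_to_steady_state,
)
from .drivers import (
    BaseDriver,
    DriverSet,
    ScaledDriver,
    make_continuation,
    make_linear_extension,
)
from .transitions import TransitionReport, classify_phase

__all__ = [
    "DriverOverride",
    "ScenarioSpec",
    "ScenarioResult",
    "SparingReport",
    "baseline_run",
    "run_scenario",
    "wastage_factor",
    "consumption_scaling",
    "sensitivity_analysis",
    "SENSITIVITY_PARAMS",
]

log = logging.getLogger(__name__)

MHA = 1e6  # ha per Mha


class DriverOverride(BaseModel):
    """How one driver departs from its default logistic.

    ``continuation`` re-solves a logistic with asymptotic gain ``K_new``
    matching value and slope at ``t_e``; ``linear`` grows along the tangent
    at ``t_e``; ``scale`` multiplies the curve by ``factor`` ramped in
    linearly over ``ramp_years`` after ``t_e``.
    """

    model_config = ConfigDict(extra="forbid")

    mode: Literal["none", "continuation", "linear", "scale"] = "none"
    t_e: float = 2009.0
    K_new: float | None = Field(default=None, gt=0)
    factor: float | None = Field(default=None, gt=0)
    ramp_years: float = Field(default=10.0, gt=0)

    def apply(self, d: BaseDriver) -> BaseDriver:
        if self.mode == "none":
            return d
        if self.mode == "continuation":
            if self.K_new is None:
                raise ValueError("continuation override requires K_new")
            return make_continuation(d, self.t_e, self.K_new)
        if self.mode == "linear":
            return make_linear_extension(d, self.t_e)
        if self.factor is None:
            raise ValueError("scale override requires factor")
        return ScaledDriver(
            base=d, factor=self.factor, t_on=self.t_e, ramp_years=self.ramp_years
        )


class ScenarioSpec(BaseModel):
    """A named, fully deterministic experiment definition."""

    model_config = ConfigDict(extra="forbid")

    name: str = "baseline"
    p: DriverOverride = Field(default_factory=DriverOverride)
    c: DriverOverride = Field(default_factory=DriverOverride)
    y: DriverOverride = Field(default_factory=DriverOverride)
    params: dict[str, float] = Field(default_factory=dict)
    preag_forest_frac: float | None = Field(default=None, ge=0, le=1)
    t_start: float | None = None
    dt: float | None = Field(default=None, gt=0)
    horizon_cap: float | None = Field(default=None, ge=500)


@dataclass(frozen=True)
class ScenarioResult:
    trajectory: Trajectory
    report: TransitionReport


@dataclass(frozen=True)
class SparingReport:
    """Ultimate land-sparing bookkeeping of a consumption scenario, in Mha.

    ``delta_A_final``  = baseline minus scenario ultimate agricultural area
    (positive when the scenario needs less farmland);
    ``delta_FP_final`` = scenario minus baseline ultimate forest plus wild
    pasture (positive when nature retains more land).
    """

    factor: float
    delta_A_final: float
    delta_FP_final: float


def _scenario_drivers(spec: ScenarioSpec, base: DriverSet) -> DriverSet:
    return base.replace(
        p=spec.p.apply(base.p), c=spec.c.apply(base.c), y=spec.y.apply(base.y)
    )


def _scenario_params(spec: ScenarioSpec, cfg: RunConfig) -> ModelParams:
    mp = build_model_params(cfg)
    if spec.params:
        known = {"T", "alpha", "zeta", "gamma", "beta", "delta", "total_land_with_barren"}
        unknown = set(spec.params) - known
        if unknown:
            raise ValueError(f"unknown parameter overrides: {sorted(unknown)}")
        mp = mp.replace(**spec.params)
    return mp


def run_scenario(spec: ScenarioSpec, cfg: RunConfig | None = None) -> ScenarioResult:
    """Run a scenario from the pre-agricultural start to steady state.

    Deterministic given the spec and config.  If the dynamics do not
    stabilise within the horizon the report is still produced with
    ``converged=False`` (and integrator/classifier flags propagate).
    """
    cfg = cfg or RunConfig()
    base = build_driver_set(cfg)
    ds = _scenario_drivers(spec, base)
    mp = _scenario_params(spec, cfg)
    t_start = spec.t_start if spec.t_start is not None else cfg.numerics.t_start
    dt = spec.dt if spec.dt is not None else cfg.numerics.dt
    horizon = (
        spec.horizon_cap if spec.horizon_cap is not None else cfg.numerics.horizon_cap
    )
    phi = (
        spec.preag_forest_frac
        if spec.preag_forest_frac is not None
        else cfg.params.preag_forest_frac
    )
    state0 = initialize_state(mp, ds, t_start, phi)
    traj = run_to_steady_state(
        state0,
        mp,
        ds,
        t_start,
        dt,
        horizon,
        record_every=cfg.numerics.record_every,
        reexpand_from_abandoned=cfg.numerics.reexpand_from_abandoned,
    )
    report = classify_phase(traj, mp, allow_unconverged=True)
    return ScenarioResult(trajectory=traj, report=report)


def baseline_run(cfg: RunConfig | None = None) -> ScenarioResult:
    """The unmodified default scenario, integrated to steady state."""
    return run_scenario(ScenarioSpec(name="baseline"), cfg)


def wastage_factor(
    from_pct: float, to_pct: float, reading: Literal["point", "ratio"] = "point"
) -> float:
    """Consumption factor for a food-wastage reduction from/to given percents.

    ``point`` (default) treats the change as a percentage-point reduction of
    required supply: factor = 1 - (from - to)/100 (32% -> 29% gives 0.97).
    ``ratio`` holds intake fixed and rescales supply by the edible share:
    factor = (100-from)/(100-to), i.e. 68/71 ~ 0.958 for the same change.
    """
    if reading == "point":
        return 1.0 - (from_pct - to_pct) / 100.0
    return (100.0 - from_pct) / (100.0 - to_pct)


def consumption_scaling(
    factor: float,
    cfg: RunConfig | None = None,
    *,
    t_on: float = 2009.0,
    ramp_years: float = 10.0,
    baseline: ScenarioResult | None = None,
) -> SparingReport:
    """Ultimate land spared by scaling consumption to ``factor`` after ``t_on``.

    Runs the baseline and the scaled scenario to steady state and differences
    their ultimate areas (a pre-computed ``baseline`` may be passed to avoid
    re-running it).  ``factor`` must lie in (0, 1].
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError(f"factor must be in (0, 1], got {factor}")
    cfg = cfg or RunConfig()
    if baseline is None:
        baseline = baseline_run(cfg)
    spec = ScenarioSpec(
        name=f"consumption-x{factor}",
        c=DriverOverride(mode="scale", factor=factor, t_e=t_on, ramp_years=ramp_years),
    )
    scen = run_scenario(spec, cfg)
    base_end = baseline.trajectory.final_state
    scen_end = scen.trajectory.final_state
    return SparingReport(
        factor=factor,
        delta_A_final=(base_end.A - scen_end.A) / MHA,
        delta_FP_final=((scen_end.F + scen_end.P) - (base_end.F + base_end.P)) / MHA,
    )


#: parameters varied by the one-at-a-time sensitivity analysis
SENSITIVITY_PARAMS = (
    "T",
    "alpha",
    "zeta",
    "gamma",
    "beta",
    "delta",
    "s",
    "K_p",
    "r_p",
    "tI_p",
    "p0",
    "K_c",
    "r_c",
    "tI_c",
    "c0",
    "K_y",
    "r_y",
    "tI_y",
    "y0",
    "preag_forest_frac",
)


# Inflection times are calendar years, so a relative change is applied to the
# fitted horizontal translation (the offset from the start of the annual
# record, 1961) rather than to the A.D. number itself; scaling the raw year
# would shift the curve by ~200 years, which is not a 10% perturbation of
# anything the calibration fitted.
_TI_REF_YEAR = 1961.0


def _perturbed_config(cfg: RunConfig, name: str, rel: float) -> RunConfig:
    new = cfg.model_copy(deep=True)
    scale = 1.0 + rel
    if name in {"T", "alpha", "zeta", "gamma", "beta", "delta", "preag_forest_frac"}:
        setattr(new.params, name, getattr(cfg.params, name) * scale)
    elif name == "s":
        new.drivers.s = cfg.drivers.s * scale
    elif name.startswith("tI"):
        which = name.split("_")[1]
        dcfg = getattr(new.drivers, which)
        dcfg.tI = _TI_REF_YEAR + (dcfg.tI - _TI_REF_YEAR) * scale
    else:
        if name in {"p0", "c0", "y0"}:
            which, attr = name[0], "x0"
        else:
            attr, which = name.split("_")  # e.g. "K_p" -> ("K", "p")
        dcfg = getattr(new.drivers, which)
        setattr(dcfg, attr, getattr(dcfg, attr) * scale)
    return RunConfig.model_validate(new.model_dump())


def sensitivity_analysis(
    cfg: RunConfig | None = None,
    rel_range: float = 0.10,
    n_steps: int = 2,
    params: tuple[str, ...] = SENSITIVITY_PARAMS,
) -> pd.DataFrame:
    """One-at-a-time parameter scan of the ultimate land-cover fractions.

    Each parameter is varied over ``n_steps`` relative changes spanning
    ``[-rel_range, +rel_range]`` (endpoints included) with all others held
    at baseline; each run goes to steady state and the absolute changes of
    the ultimate F, P, A and U fractions of T are tabulated.  Infeasible
    perturbations are flagged rather than raised.
    """
    cfg = cfg or RunConfig()
    base = baseline_run(cfg)
    T = cfg.params.T
    end = base.trajectory.final_state
    base_fracs = np.array([end.F, end.P, end.A, end.U]) / T

    rows = []
    rels = np.linspace(-rel_range, rel_range, n_steps)
    for name in params:
        if name not in SENSITIVITY_PARAMS:
            raise ValueError(f"unknown sensitivity parameter {name!r}")
        for rel in rels:
            if abs(rel) < 1e-15:
                dF = dP = dA = dU = 0.0
                feasible = True
            else:
                try:
                    pcfg = _perturbed_config(cfg, name, float(rel))
                    res = run_scenario(ScenarioSpec(name=f"sens-{name}"), pcfg)
                    e = res.trajectory.final_state
                    fr = np.array([e.F, e.P, e.A, e.U]) / pcfg.params.T
                    dF, dP, dA, dU = (fr - base_fracs).tolist()
                    feasible = not res.trajectory.infeasible
                except Exception as exc:  # noqa: BLE001 - flagged, not raised
                    log.warning("sensitivity run %s %+0.2f failed: %s", name, rel, exc)
                    dF = dP = dA = dU = float("nan")
                    feasible = False
            rows.append(
                {
                    "parameter": name,
                    "rel_change": float(rel),
                    "dF_frac": dF,
                    "dP_frac": dP,
                    "dA_frac": dA,
                    "dU_frac": dU,
                    "max_abs_change": max(
                        abs(v) for v in (dF, dP, dA, dU)
                    )
                    if feasible
                    else float("nan"),
                    "feasible": feasible,
                }
            )
    return pd.DataFrame(rows)
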