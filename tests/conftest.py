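"""Shared fixtures: default configuration and expensive reference runs."""

from __future__ import annotations

import logging

import pytest

from landshift.config import RunConfig, build_driver_set, build_model_params
from landshift.scenarios import baseline_run

logging.getLogger("landshift").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    """The shipped default calibration."""
    return RunConfig()


@pytest.fixture(scope="session")
def ds(cfg):
    """Default driver set (population, consumption, yield, urban footprint)."""
    return build_driver_set(cfg)


@pytest.fixture(scope="session")
def mp(cfg):
    """Default land-conversion parameters."""
    return build_model_params(cfg)


@pytest.fixture(scope="session")
def baseline(cfg):
    """The baseline scenario integrated to steady state (shared, read-only)."""
    return baseline_run(cfg)


@pytest.fixture(scope="session")
def baseline_traj(baseline):
    return baseline.trajectory


@pytest.fixture(scope="session")
def scan_default(cfg, ds, mp):
    """The default 30x30 (K_y, K_c) continuation phase scan (minutes)."""
    from landshift.transitions import default_scan_grid, scan_phase_diagram

    sc = cfg.scan
    ky = default_scan_grid(ds.y, sc.t_e, sc.n_ky, sc.lo_factor, sc.hi_factor)
    kc = default_scan_grid(ds.c, sc.t_e, sc.n_kc, sc.lo_factor, sc.hi_factor)
    return scan_phase_diagram(
        ds, mp, ky, kc, sc.t_e,
        t_start=cfg.numerics.t_start,
        preag_forest_frac=cfg.params.preag_forest_frac,
        dt=cfg.numerics.dt,
        horizon_cap=cfg.numerics.horizon_cap,
    )


@pytest.fixture(scope="session")
def sensitivity_table(cfg):
    """Full one-at-a-time +-10% sensitivity scan (shared: ~40 model runs)."""
    from landshift.scenarios import sensitivity_analysis

    return sensitivity_analysis(cfg, rel_range=0.10, n_steps=2)
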