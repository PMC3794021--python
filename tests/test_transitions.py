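"""Transition detection, five-phase classification, phase-diagram scans."""

from __future__ import annotations

import numpy as np
import pytest

from landshift.core import (
    Trajectory,
    initialize_state,
    integrate,
    run_to_steady_state,
)
from landshift.drivers import DriverSet, LogisticDriver, make_continuation
from landshift.transitions import (
    PHASES,
    SteadyStateNotReached,
    TransitionReport,
    classify_phase,
    default_scan_grid,
    detect_transition,
    scan_phase_diagram,
)

T_E = 2009.0


def _synthetic_traj(times, F, mp, steady=True) -> Trajectory:
    """A minimal trajectory carrying a prescribed forest series."""
    times = np.asarray(times, dtype=float)
    F = np.asarray(F, dtype=float)
    n = len(times)
    states = np.zeros((n, 7))
    states[:, 0] = F
    states[:, 1] = mp.T - F  # park the remainder in P: conserving, inert
    rates = np.gradient(states, times, axis=0)
    D = np.full(n, 1e9)
    return Trajectory(
        times=times, states=states, rates=rates, D=D,
        drivers=None, params=mp, steady_state=steady,
    )


@pytest.fixture(scope="module")
def cft_setup(mp):
    """Drivers whose demand D rises then permanently falls: a classical
    transition fixture with an analytically known demand peak."""
    ds = DriverSet(
        p=LogisticDriver(x0=1e9, K=1.0, r=1e-9, tI=2000.0),  # static population
        c=LogisticDriver(x0=500.0, K=1500.0, r=0.08, tI=1900.0),
        y=LogisticDriver(x0=500.0, K=4500.0, r=0.08, tI=2000.0),
        s=0.06,
    )
    state0 = initialize_state(mp, ds, 1000.0, 0.575)
    # the beta = 0.01 recovery tail takes ~700 yr to drain below tolerance
    traj = run_to_steady_state(state0, mp, ds, 1000.0, 0.1, 2000.0)
    return ds, traj


@pytest.fixture(scope="module")
def scan_small(cfg, ds, mp):
    """A coarse 6x6 continuation scan sharing the default grid bounds."""
    ky = default_scan_grid(ds.y, T_E, 6)
    kc = default_scan_grid(ds.c, T_E, 6)
    return scan_phase_diagram(ds, mp, ky, kc, T_E)


class TestDetectTransition:
    def test_none_for_monotone_decline(self, mp):
        times = np.arange(0, 200.0)
        F = 5e9 - 5e6 * times
        assert detect_transition(_synthetic_traj(times, F, mp)) is None

    def test_v_shape_minimum(self, mp):
        times = np.arange(0, 200.0)
        F = 4e9 + 2e6 * np.abs(times - 120.0)
        t = detect_transition(_synthetic_traj(times, F, mp))
        assert t == pytest.approx(120.0, abs=1.5)

    def test_baseline_has_no_transition(self, baseline_traj):
        """Forest declines monotonically to equilibrium at baseline."""
        assert detect_transition(baseline_traj) is None


class TestClassifyPhase:
    def test_baseline_is_nft(self, baseline, mp):
        rep = baseline.report
        assert rep.phase == "NFT"
        assert rep.t_transition is None and rep.F_at_transition is None
        assert rep.converged

    def test_forest_exhaustion_is_nfr(self, mp):
        times = np.arange(0, 200.0)
        F = np.maximum(5e9 - 1e8 * times, 0.0) + 1e6 * (times > 150) * (times - 150)
        rep = classify_phase(_synthetic_traj(times, F, mp), mp)
        assert rep.phase == "NFR"

    def test_constructed_cft(self, cft_setup, mp):
        """One demand peak, then abandonment-driven recovery: classical."""
        ds, traj = cft_setup
        assert traj.steady_state
        rep = classify_phase(traj, mp)
        assert rep.phase == "CFT"
        assert rep.D_turning_points == 1
        t_peak = traj.times[int(np.argmax(traj.D))]
        assert rep.t_transition == pytest.approx(t_peak, abs=2.0)
        assert rep.F_final > rep.F_at_transition

    def test_unconverged_trajectory_is_flagged(self, ds, mp):
        state0 = initialize_state(mp, ds, 1000.0, 0.575)
        traj = integrate(state0, mp, ds, 1000.0, 1500.0, 0.1)
        with pytest.raises(SteadyStateNotReached):
            classify_phase(traj, mp)
        rep = classify_phase(traj, mp, allow_unconverged=True)
        assert not rep.converged

    def test_report_invariants_enforced(self):
        with pytest.raises(Exception):
            TransitionReport(
                phase="NFT", t_transition=2050.0, F_at_transition=0.3,
                F_final=0.2, D_turning_points=0,
            )
        with pytest.raises(Exception):
            TransitionReport(
                phase="XYZ", t_transition=None, F_at_transition=None,
                F_final=0.2, D_turning_points=0,
            )


class TestPhaseScan:
    def test_identity_continuation_cell_is_nft(self, ds, mp):
        """Continuing both drivers at their own gains reproduces baseline."""
        diagram = scan_phase_diagram(
            ds, mp, [ds.y.K], [ds.c.K], T_E
        )
        assert diagram.cells[0][0].phase == "NFT"

    def test_grid_is_complete_and_labels_valid(self, scan_small):
        assert len(scan_small.cells) == 6
        for row in scan_small.cells:
            assert len(row) == 6
            for rep in row:
                assert rep.phase in PHASES

    def test_transition_iff_demand_turns_down(self, scan_small):
        """Monotone demand growth can only yield NFT or NFR."""
        for row in scan_small.cells:
            for rep in row:
                if rep.D_turning_points == 0:
                    assert rep.phase in {"NFT", "NFR"}
                if rep.phase in {"CFT", "OFT", "FFT"}:
                    assert rep.t_transition is not None
                    assert rep.t_transition > T_E
                    assert 0.0 <= rep.F_at_transition <= 1.0

    def test_transition_cells_exist(self, scan_small):
        assert any(True for _ in scan_small.transition_cells())

    def test_export_long_format(self, scan_small):
        df = scan_small.to_frame()
        assert len(df) == 36
        assert {"Ky", "Kc", "phase", "t_transition", "F_final"} <= set(df.columns)
        assert df["phase"].isin(PHASES).all()

    def test_more_yield_never_costs_forest(self, ds, mp):
        """Ultimate forest is monotone in the yield ceiling at fixed K_c."""
        gain_y = ds.y.value(T_E) - ds.y.x0
        ky = np.array([1.2, 1.6, 2.0, 2.4, 2.8]) * gain_y
        diagram = scan_phase_diagram(ds, mp, ky, [ds.c.K], T_E)
        finals = [diagram.cells[i][0].F_final for i in range(len(ky))]
        assert all(b >= a - 1e-6 for a, b in zip(finals, finals[1:]))

    def test_abandonment_onset_is_beta_invariant(self, ds, mp):
        """The demand peak driving the transition does not depend on the
        re-forestation rate, and neither does the phase label; only the
        forest-rate upturn (recovery overtaking urban loss) shifts."""
        gain_y = ds.y.value(T_E) - ds.y.x0
        gain_c = ds.c.value(T_E) - ds.c.x0
        ky, kc = [2.5 * gain_y], [1.05 * gain_c]
        peaks, phases = [], []
        for beta in (0.005, 0.02):
            diagram = scan_phase_diagram(ds, mp.replace(beta=beta), ky, kc, T_E)
            rep = diagram.cells[0][0]
            phases.append(rep.phase)
            peaks.append(rep.D_turning_points)
        assert phases[0] == phases[1] == "CFT"
        assert peaks[0] == peaks[1] == 1
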