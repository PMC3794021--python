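"""Land-state system: world food equation, rates, conservation, integration."""

from __future__ import annotations

import numpy as np
import pytest

from landshift.core import (
    LandState,
    ModelError,
    ModelParams,
    initialize_state,
    integrate,
    land_rates,
    required_agricultural_area,
    required_area_rate,
    run_to_steady_state,
)
from landshift.drivers import DriverSet, LogisticDriver, make_continuation

MHA = 1e6


def _constant_driver(value: float) -> LogisticDriver:
    """A driver frozen at ``value`` (vanishing gain and rate)."""
    return LogisticDriver(x0=value, K=1e-9, r=1e-9, tI=2000.0)


@pytest.fixture()
def frozen_ds() -> DriverSet:
    """Drivers with negligible rates: D and U demand are static."""
    return DriverSet(
        p=_constant_driver(1e9),
        c=_constant_driver(600.0),
        y=_constant_driver(600.0),
        s=0.06,
    )


class TestRequiredArea:
    def test_pre_industrial_arithmetic(self, ds):
        """At the driver floors, D = 571 * 310e6 / 150 ~ 1.1801e9 ha."""
        assert required_agricultural_area(ds, -1e5) == pytest.approx(
            571.0 * 310e6 / 150.0, rel=1e-12
        )
        # the year-1000 value is within the logistic-tail correction of it
        assert required_agricultural_area(ds, 1000.0) == pytest.approx(
            1.1801e9, rel=1e-3
        )

    def test_linear_in_consumption(self, ds):
        """Doubling c at fixed p and y doubles the required area."""
        c2 = LogisticDriver(x0=2 * 571.0, K=2 * 1940.0, r=0.019, tI=1995.8)
        doubled = ds.replace(c=c2)
        t = 1990.0
        assert required_agricultural_area(doubled, t) == pytest.approx(
            2 * required_agricultural_area(ds, t), rel=1e-12
        )

    def test_2050_projection(self, ds):
        """The 2050 requirement lands on the published 5820 Mha projection."""
        assert required_agricultural_area(ds, 2050.0) / MHA == pytest.approx(
            5820.0, rel=0.03
        )

    def test_rate_matches_finite_difference(self, ds):
        for t in (1950.0, 2009.0, 2100.0):
            h = 1e-3
            fd = (
                required_agricultural_area(ds, t + h)
                - required_agricultural_area(ds, t - h)
            ) / (2 * h)
            assert required_area_rate(ds, t) == pytest.approx(fd, rel=1e-6)


class TestLandRates:
    def test_rates_sum_to_zero(self, ds, mp):
        """Total area is conserved by construction at any state and time."""
        state = [3e9, 3e9, 1e9, 2e9, 0.5e9, 0.5e9, 1.26e9]
        for t in (1500.0, 2000.0, 2050.0, 2500.0):
            rates, _ = land_rates(state, t, mp, ds)
            assert abs(sum(rates)) <= 1e-9 * mp.T

    def test_rates_sum_to_zero_during_abandonment(self, mp):
        """Conservation also holds when required area is shrinking."""
        # yield continuation with a high ceiling forces dD/dt < 0 later on
        y = LogisticDriver(x0=150.0, K=3391.0, r=0.039, tI=1995.7)
        ds = DriverSet(
            p=_constant_driver(8e9),
            c=_constant_driver(2000.0),
            y=make_continuation(y, 2009.0, 3 * 3391.0),
            s=0.06,
        )
        t = 2100.0
        assert required_area_rate(ds, t) < 0
        state = [3e9, 3e9, 1e9, 2e9, 0.5e9, 0.5e9, 1.26e9]
        rates, _ = land_rates(state, t, mp, ds)
        assert abs(sum(rates)) <= 1e-9 * mp.T

    def test_expansion_terms(self, ds, mp):
        """With no abandoned land, dF = -alpha*dD/dt - zeta*s*dp/dt exactly."""
        state = [4e9, 4e9, 1e9, 1.5e9, 0.0, 0.0, 0.76e9]
        t = 2000.0
        D_dot = required_area_rate(ds, t)
        assert D_dot > 0
        rates, infeasible = land_rates(state, t, mp, ds)
        assert not infeasible
        p_dot = ds.p.rate(t)
        assert rates[0] == pytest.approx(-mp.alpha * D_dot - mp.zeta * ds.s * p_dot, rel=1e-12)
        assert rates[1] == pytest.approx(
            -(1 - mp.alpha) * D_dot - (1 - mp.zeta) * ds.s * p_dot, rel=1e-12
        )
        assert rates[6] == pytest.approx(ds.s * p_dot, rel=1e-12)

    def test_abandonment_split(self, mp):
        """Shrinking demand abandons land in the gamma : 1-gamma split."""
        mp0 = mp.replace(beta=0.0, delta=0.0)
        y = LogisticDriver(x0=150.0, K=3391.0, r=0.039, tI=1995.7)
        ds = DriverSet(
            p=_constant_driver(8e9),  # static population: no urban demand
            c=_constant_driver(2000.0),
            y=make_continuation(y, 2009.0, 3 * 3391.0),
            s=0.06,
        )
        t = 2100.0
        state = [3e9, 3e9, 1e9, 2e9, 0.0, 0.0, 1.26e9]
        rates, _ = land_rates(state, t, mp0, ds)
        assert rates[4] > 0 and rates[5] > 0
        assert rates[4] / rates[5] == pytest.approx(mp.gamma / (1 - mp.gamma), rel=1e-9)

    def test_rejects_deeply_negative_stock(self, ds, mp):
        bad = [-1e9, 4e9, 1e9, 1.5e9, 0.0, 0.0, 0.76e9]
        with pytest.raises(ModelError):
            land_rates(bad, 2000.0, mp, ds)


class TestInitializeState:
    def test_medieval_urban_area(self, ds, mp):
        """U0 = s * p(1000) ~ 0.06 * 310e6 = 18.6e6 ha."""
        state = initialize_state(mp, ds, 1000.0, 0.575)
        assert state.U == pytest.approx(18.6e6, rel=1e-3)

    def test_components_sum_to_total(self, ds, mp):
        for phi in (0.3, 0.575, 0.8):
            state = initialize_state(mp, ds, 1000.0, phi)
            assert state.total == pytest.approx(mp.T, rel=1e-12)
            assert state.A_F == pytest.approx(mp.alpha * state.A, rel=1e-12)
            assert state.B_F == 0.0 and state.B_P == 0.0

    def test_rejects_degenerate_split(self, ds, mp):
        """No forest to carve the forest share of farmland from."""
        with pytest.raises(ModelError):
            initialize_state(mp, ds, 1000.0, 0.0)


class TestIntegration:
    def test_abandoned_land_recovery_closed_form(self, frozen_ds, mp):
        """With static drivers, B_F decays into F as B0 * (1 - e^(-beta t))."""
        B0 = 1e9
        T = mp.T
        state0 = LandState(
            F=4e9, P=T - 4e9 - B0 - 1e9 - 1e9 - 0.06e9, A_F=1e9, A_P=1e9,
            B_F=B0, B_P=0.0, U=0.06e9,
        )
        traj = integrate(state0, mp, frozen_ds, 0.0, 200.0, 0.1)
        t = traj.times
        expected = state0.F + B0 * (1 - np.exp(-mp.beta * t))
        assert np.allclose(traj.F, expected, rtol=1e-4)

    def test_world_food_tracking(self, baseline_traj):
        """Agricultural area follows D = c p / y while sources last."""
        rel = np.abs(baseline_traj.A - baseline_traj.D) / baseline_traj.D
        assert np.max(rel) < 1e-4

    def test_closed_form_forest_oracle(self, ds, mp):
        """While demand only grows, F has a quadrature-free closed form."""
        t0, t1 = 1000.0, 2200.0
        state0 = initialize_state(mp, ds, t0, 0.575)
        traj = integrate(state0, mp, ds, t0, t1, 0.1)
        D0 = required_agricultural_area(ds, t0)
        p0 = ds.p.value(t0)
        D = traj.D
        p = np.array([ds.p.value(t) for t in traj.times])
        F_expected = state0.F - mp.alpha * (D - D0) - mp.zeta * ds.s * (p - p0)
        P_expected = (
            state0.P
            - (1 - mp.alpha) * (D - D0)
            - (1 - mp.zeta) * ds.s * (p - p0)
        )
        assert np.max(np.abs(traj.F - F_expected)) < 1e-4 * mp.T
        assert np.max(np.abs(traj.P - P_expected)) < 1e-4 * mp.T

    def test_conservation_and_nonnegativity(self, baseline_traj, mp):
        sums = baseline_traj.states.sum(axis=1)
        assert np.max(np.abs(sums - mp.T)) <= 1e-6 * mp.T
        assert np.min(baseline_traj.states) >= -1e-6 * mp.T

    def test_step_halving_convergence(self, ds, mp):
        """Halving dt changes every land fraction by far less than 1e-4."""
        state0 = initialize_state(mp, ds, 1000.0, 0.575)
        a = integrate(state0, mp, ds, 1000.0, 2150.0, 0.1)
        b = integrate(state0, mp, ds, 1000.0, 2150.0, 0.05)
        fa = a.states[-1] / mp.T
        fb = b.states[-1] / mp.T
        assert np.max(np.abs(fa - fb)) < 1e-4

    def test_depletion_guard_and_infeasible_flag(self, ds, mp):
        """A world too small for demand exhausts F, then P, then flags."""
        small = mp.replace(T=3.0e9, total_land_with_barren=3.0e9 / 0.85)
        state0 = initialize_state(small, ds, 1000.0, 0.575)
        traj = run_to_steady_state(state0, small, ds, 1000.0, 0.1, 1500.0)
        assert traj.infeasible
        assert traj.termination == "infeasible"
        end = traj.final_state
        # natural land is drained to the capacity floor before the flag fires
        assert end.F + end.P < 0.02 * small.T
        # conservation holds right up to the infeasible stop
        sums = traj.states.sum(axis=1)
        assert np.max(np.abs(sums - small.T)) <= 1e-6 * small.T


class TestSteadyState:
    def test_baseline_converges_before_year_3000(self, baseline_traj):
        assert baseline_traj.steady_state
        assert baseline_traj.termination == "steady-state"
        assert baseline_traj.times[-1] < 3000.0

    def test_ultimate_forest_share(self, baseline_traj, mp):
        """Forest settles near a quarter of the non-barren land area."""
        assert baseline_traj.final_state.F / mp.T == pytest.approx(0.25, abs=0.02)

    def test_frozen_abandoned_stock_with_zero_beta(self, frozen_ds, mp):
        """beta = 0 freezes B_F; steady state is still detected."""
        mp0 = mp.replace(beta=0.0)
        B0 = 0.5e9
        state0 = LandState(
            F=4e9, P=mp.T - 4e9 - B0 - 2e9 - 0.06e9, A_F=1e9, A_P=1e9,
            B_F=B0, B_P=0.0, U=0.06e9,
        )
        traj = run_to_steady_state(state0, mp0, frozen_ds, 0.0, 0.1, 500.0)
        assert traj.steady_state
        assert traj.final_state.B_F == pytest.approx(B0, rel=1e-9)

    def test_rejects_short_horizon(self, frozen_ds, mp):
        state0 = initialize_state(mp, frozen_ds, 0.0, 0.575)
        with pytest.raises(ModelError):
            run_to_steady_state(state0, mp, frozen_ds, 0.0, 0.1, 100.0)
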