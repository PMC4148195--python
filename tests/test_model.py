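"""ODE right-hand sides and integrators: limits, conservation, mode agreement."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from il1switch import kinetics as kin
from il1switch.calibration import dbss_initial_state
from il1switch.model import (SensitivityInput, SystemState, fast_rhs,
                             fast_jacobian, reduced_residual,
                             reduced_residual_deriv, rhs_full, simulate)
from il1switch.synth import CASE_SENSITIVITY_KNOTS, TRUE_M, TRUE_TAU


class TestSensitivityInput:
    def test_validation(self):
        with pytest.raises(ValueError):
            SensitivityInput([0, 0], [90, 90])        # non-increasing times
        with pytest.raises(ValueError):
            SensitivityInput([0, 1], [90, -1])        # non-positive %S

    def test_hold_beyond_ends(self):
        s = SensitivityInput([0, 100, 200], [90, 80, 60])
        assert s.value(-50) == 90
        assert s.value(10_000) == 60

    def test_monotone_interpolation(self):
        s = SensitivityInput([0, 100, 200], [90, 80, 60])
        t = np.linspace(0, 200, 400)
        assert np.all(np.diff(s.value(t)) <= 1e-12)   # PCHIP preserves monotonicity

    def test_resistance_baseline(self, params):
        s = SensitivityInput([0, 100], [90, 45])
        assert s.resistance(0, params) == pytest.approx(params.R0)
        assert s.resistance(100, params) > params.R0


class TestRhsFull:
    def test_steady_state_at_calibrated_anchor(self, cal_params, calib):
        # fast subsystem and glucose/insulin are exactly stationary at the
        # anchor; β-cell mass grows slowly (compensation), since turnover is
        # balanced at the healthy glucose level, not at the anchor
        a = calib.anchors
        I, B = dbss_initial_state(a.G_comp, cal_params.R0, cal_params)
        state = SystemState(t=0, G=a.G_comp, I=I, B=B, L=a.L_comp, A=a.A_comp)
        d = rhs_full(state, cal_params.R0, cal_params)
        assert np.all(np.abs(d[[0, 1, 3, 4]]) < 1e-6)
        assert 0 < d[2] < 0.05

    def test_extinction_absorbing(self, params):
        d = rhs_full([5.47, 70.0, 0.0, 12.0, 6000.0], params.R0, params)
        assert d[2] == 0.0

    def test_sterile_start_produces_il1b(self, params):
        d = rhs_full([5.47, 70.0, 300.0, 0.0, 0.0], params.R0, params)
        assert d[3] == pytest.approx(params.k5 * kin.glucose_stim(5.47, params))
        assert d[3] > 0

    def test_jacobian_matches_finite_differences(self, cal_params):
        L, A, G = 30.0, 7000.0, 5.0
        J = fast_jacobian(L, A, G, cal_params)
        h = 1e-6
        for j, (dLh, dAh) in enumerate([(h * L, 0), (0, h * A)]):
            num = (fast_rhs(L + dLh, A + dAh, G, cal_params)
                   - fast_rhs(L - dLh, A - dAh, G, cal_params)) / (2 * (dLh + dAh))
            assert J[:, j] == pytest.approx(num, rel=1e-5)

    def test_reduced_residual_derivative(self, cal_params):
        L, G = 25.0, 5.6
        h = 1e-6 * L
        num = (reduced_residual(L + h, G, cal_params)
               - reduced_residual(L - h, G, cal_params)) / (2 * h)
        assert reduced_residual_deriv(L, G, cal_params) == pytest.approx(num, rel=1e-5)


class TestPureDecayLimit:
    def test_exponential_decay(self, params):
        p = params.replace(k1=0.0, k2=0.0, k5=0.0, k6=0.0)
        L0, A0, T = 40.0, 9000.0, 0.05
        sol = solve_ivp(lambda t, y: fast_rhs(y[0], y[1], 5.0, p), (0, T),
                        [L0, A0], method="DOP853", rtol=1e-12, atol=1e-14)
        assert sol.y[0, -1] == pytest.approx(L0 * np.exp(-p.dL * T), rel=1e-8)
        assert sol.y[1, -1] == pytest.approx(A0 * np.exp(-p.dA * T), rel=1e-8)


class TestGlucoseInsulinClosedForm:
    def test_convergence_to_algebraic_solution(self, cal_params):
        # freeze β-cell mass (τ=0): (G, I) must converge to the unique
        # intersection of the supply and demand curves
        p = cal_params.replace(tau=1e-300)
        B, R = 280.0, 11.0

        def demand_minus_supply(G):
            return R * (p.r0 / G - p.dG) - p.h * B * kin.insulin_secretion_factor(G, p) / p.dI

        G_star = brentq(demand_minus_supply, 1.0, p.r0 / p.dG - 1e-6)
        I_star = R * (p.r0 / G_star - p.dG)
        init = SystemState(t=0, G=4.0, I=40.0, B=B, L=12.0, A=6000.0)
        traj = simulate(init, R, 60.0, p, mode="stiff-full", n_out=50)
        assert traj.G[-1] == pytest.approx(G_star, rel=1e-6)
        assert traj.I[-1] == pytest.approx(I_star, rel=1e-6)


class TestSimulate:
    def test_fixed_point_is_stationary(self, cal_params, calib):
        # the healthy-glucose state is a genuine fixed point of all five
        # equations: β-cell turnover is balanced there by construction of λ
        a = calib.anchors
        from il1switch.equilibria import find_equilibria
        low = min((e for e in find_equilibria(a.healthy_G, cal_params)
                   if e.stable), key=lambda e: e.L_star)
        # resistance consistent with G=4.5 at the DBSS insulin/β-mass
        I, B = dbss_initial_state(a.healthy_G, cal_params.R0, cal_params)
        init = SystemState(t=0, G=a.healthy_G, I=I, B=B,
                           L=low.L_star, A=low.A_star)
        traj = simulate(init, cal_params.R0, 3650.0, cal_params, mode="qssa",
                        n_out=40)
        for name, ref in (("G", a.healthy_G), ("I", I), ("B", B),
                          ("L", low.L_star)):
            drift = np.max(np.abs(getattr(traj, name) - ref)) / ref
            assert drift < 1e-3, f"{name} drifted by {drift:.2e}"
        assert traj.events == []

    def test_nonnegativity(self, cal_params):
        # start far from equilibrium with a harsh resistance input
        init = SystemState(t=0, G=2.0, I=5.0, B=20.0, L=0.5, A=50.0)
        traj = simulate(init, 20.0, 2000.0, cal_params, mode="stiff-full",
                        n_out=100)
        for name in ("G", "I", "B", "L", "A"):
            assert np.all(getattr(traj, name) >= -1e-9)

    def test_invalid_inputs(self, params):
        init = SystemState(t=0, G=5.0, I=70.0, B=300.0, L=12.0, A=6000.0)
        with pytest.raises(ValueError):
            simulate(init, params.R0, -1.0, params)
        with pytest.raises(ValueError):
            simulate(init, params.R0, 10.0, params, mode="magic")


@pytest.fixture(scope="module")
def disease_course(cal_params):
    """Case-cohort simulation in both modes (shared across tests)."""
    p = cal_params.replace(m=TRUE_M, tau=TRUE_TAU)
    knots = np.array(CASE_SENSITIVITY_KNOTS)
    sens = SensitivityInput(knots[:, 0] * 365.0, knots[:, 1])
    I0, B0 = dbss_initial_state(5.47, p.R0, p)
    init = SystemState(t=0, G=5.47, I=I0, B=B0, L=12.0, A=6000.0)
    qssa = simulate(init, sens, 13 * 365.0, p, mode="qssa", n_out=300)
    full = simulate(init, sens, 13 * 365.0, p, mode="stiff-full", n_out=300)
    return qssa, full


class TestDiseaseCourse:
    def test_switch_recorded_and_glucose_history_shape(self, disease_course):
        qssa, _ = disease_course
        jumps = [t for t, kind in qssa.events if kind == "branch-jump"]
        assert len(jumps) == 1
        t_jump = jumps[0]
        # slow rise then rapid rise: crossing of the critical level happens
        # in the final quarter of the observation window
        assert 0.6 * 13 * 365 < t_jump < 0.95 * 13 * 365
        assert qssa.G[-1] > 6.5

    def test_beta_mass_declines_after_switch(self, disease_course):
        qssa, _ = disease_course
        t_jump = qssa.events[0][0]
        B_after = qssa.B[qssa.t > t_jump + 20]
        assert np.all(np.diff(B_after) < 0)

    def test_qssa_matches_stiff_integration(self, disease_course):
        qssa, full = disease_course
        t_jump = qssa.events[0][0]
        G_q = np.interp(full.t, qssa.t, qssa.G)
        away = np.abs(full.t - t_jump) > 120.0
        rel = np.abs(G_q - full.G) / full.G
        assert np.max(rel[away]) < 0.01
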