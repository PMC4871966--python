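"""Method-of-steps integrator: correctness against the Volterra integral
identity and an independent ODE solver, order of accuracy, the comparison
and monotonicity structure of the equation, and the radius-form cross-check."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import tumordde as td


def test_zero_history_stays_zero():
    params = td.ModelParams(5.0, 1.0, tau=1.0)
    sched = td.SinusoidalTherapy(1.0, 1.0)
    traj = td.integrate(params, sched, td.HistoryFunction.constant(0.0), 20.0)
    ts = np.linspace(0.0, 20.0, 200)
    assert np.max(traj(ts)) == 0.0


def test_constant_therapy_converges_to_stationary_state(fig2, fig2_traj):
    xs = td.stationary_state(fig2.params, 4.0).x_s
    assert abs(fig2_traj(200.0) - xs) <= 1e-4


def test_supercritical_constant_therapy_extinguishes(fig3):
    traj = td.integrate(fig3.params, fig3.schedule,
                        td.HistoryFunction.constant(2.0), 200.0, 0.01)
    assert traj(200.0) <= 1e-3


def test_integral_form_residual(fig2_traj):
    """The dense solution satisfies the equivalent Volterra identity."""
    assert td.integral_form_residual(fig2_traj) <= 1e-6


def test_integral_form_residual_zero_trajectory():
    params = td.ModelParams(5.0, 1.0, tau=1.0)
    sched = td.ConstantTherapy(2.0)
    traj = td.integrate(params, sched, td.HistoryFunction.constant(0.0), 10.0)
    assert td.integral_form_residual(traj, n_checkpoints=5) <= 1e-12


def test_residual_shrinks_with_step(fig2):
    """Halving dt cuts the integral-form residual by roughly 2^4."""
    h = td.HistoryFunction.constant(2.0)
    res = [td.integral_form_residual(
        td.integrate(fig2.params, fig2.schedule, h, 50.0, dtv),
        n_checkpoints=9) for dtv in (0.08, 0.04)]
    assert 8.0 <= res[0] / res[1] <= 32.0


def test_fourth_order_convergence(fig2):
    order, _ = td.step_halving_order(fig2.params, fig2.schedule,
                                     td.HistoryFunction.constant(2.0),
                                     10.0, 0.05)
    assert 3.5 <= order <= 4.5


def test_tau_zero_matches_reference_ode_solver():
    """With no delay the equation is a plain ODE; cross-check at a tight
    tolerance against scipy's adaptive RK."""
    params = td.ModelParams(5.0, 0.0, tau=0.0)
    sched = td.ConstantTherapy(4.0)
    traj = td.integrate(params, sched, td.HistoryFunction.constant(2.0),
                        20.0, 0.01)
    sol = solve_ivp(lambda t, y: [15.0 * td.f(max(y[0], 0.0)) - 4.0 * y[0]],
                    (0.0, 20.0), [2.0], rtol=1e-11, atol=1e-12)
    assert traj(20.0) == pytest.approx(sol.y[0, -1], abs=1e-8)


def test_nonnegativity_random_scenarios():
    for i, regime in enumerate(("extinct", "persistent", "indeterminate")):
        for k in range(3):
            sc = td.random_scenario(100 * i + k, regime)
            traj = td.integrate(sc.params, sc.schedule,
                                td.HistoryFunction.constant(sc.histories[0]),
                                10.0 * sc.params.tau, sc.params.tau / 20.0)
            ts = np.linspace(0.0, traj.t_end, 300)
            assert np.min(traj(ts)) >= 0.0


def test_comparison_principle_upper_bound(fig4):
    """When gamma(t) <= sigma_inf, x0*exp(int (sigma_inf - gamma)) dominates
    the solution started from the constant history x0."""
    h = td.HistoryFunction.constant(2.0)
    traj = td.integrate(fig4.params, fig4.schedule, h, 30.0, 0.01)
    ts = np.linspace(0.0, 30.0, 400)
    sched, st_ = fig4.schedule, fig4.params.sigma_tilde
    bound = 2.0 * np.exp([fig4.params.sigma_inf * t
                          - sched.gamma_integral(0.0, t, st_) for t in ts])
    assert np.all(traj(ts) <= bound * (1.0 + 1e-9))


def test_monotone_dependence_on_history(fig6):
    """A pointwise-larger nonnegative history gives a pointwise-larger
    solution (monotonicity of the proliferation kernel)."""
    lo = td.integrate(fig6.params, fig6.schedule,
                      td.HistoryFunction.constant(2.0), 30.0, 0.01)
    hi = td.integrate(fig6.params, fig6.schedule,
                      td.HistoryFunction.constant(3.0), 30.0, 0.01)
    ts = np.linspace(0.0, 30.0, 500)
    assert np.all(lo(ts) <= hi(ts) + 1e-10)


def test_continuity_across_segment_boundaries(fig2_traj):
    tau = fig2_traj.params.tau
    for k in range(1, 20):
        t = k * tau
        left = fig2_traj(t - 1e-12)
        right = fig2_traj(t + 1e-12)
        assert abs(left - right) <= 1e-10 * max(1.0, abs(right))


def test_dense_output_satisfies_equation_off_nodes(fig2_traj):
    """At off-node points the interpolant's derivative matches the
    right-hand side — a strong whole-solution check."""
    params, sched = fig2_traj.params, fig2_traj.schedule
    rng = np.random.default_rng(3)
    ts = rng.uniform(2.0, 190.0, 50)
    for t in ts:
        xdot = float(fig2_traj._spline.derivative()(t))
        rhs = td.rhs_x(float(fig2_traj(t)), float(fig2_traj(t - params.tau)),
                       t, params, sched)
        assert xdot == pytest.approx(rhs, rel=1e-6, abs=1e-8)


class TestRadiusForm:
    def test_consistency_with_x_form(self, fig2):
        h = td.HistoryFunction.constant(2.0)
        tr_x = td.integrate(fig2.params, fig2.schedule, h, 50.0, 0.01)
        tr_R = td.integrate_radius(fig2.params, fig2.schedule, h, 50.0, 0.01)
        ts = np.linspace(0.0, 50.0, 500)
        rel = np.abs(tr_R(ts) ** 3 - tr_x(ts)) / np.maximum(tr_x(ts), 1e-9)
        assert np.max(rel) <= 1e-6

    def test_stationary_history_stays_constant(self, fig2):
        eq = td.stationary_state(fig2.params, 4.0)
        traj = td.integrate_radius(fig2.params, fig2.schedule,
                                   td.HistoryFunction.constant(eq.x_s),
                                   50.0, 0.01)
        ts = np.linspace(0.0, 50.0, 300)
        assert np.max(np.abs(traj(ts) - eq.R_s)) <= 1e-8

    def test_tiny_history_raises_extinction_flag(self, fig3):
        traj = td.integrate_radius(fig3.params, fig3.schedule,
                                   td.HistoryFunction.constant(1e-6),
                                   400.0, 0.02)
        assert traj.extinct
        assert traj.t_end < 400.0

    def test_requires_positive_history(self, fig3):
        with pytest.raises(ValueError):
            td.integrate_radius(fig3.params, fig3.schedule,
                                td.HistoryFunction.constant(0.0), 10.0)


def test_piecewise_schedule_breakpoint_alignment():
    """Pulsed dosing: the solver aligns steps to the jumps and still passes
    the integral-identity check and self-convergence."""
    sched = td.PiecewiseTherapy([0.0, 1.0, 2.0, 4.0], [2.0, 0.5, 3.0, 2.0],
                                omega=4.0, interp="previous")
    params = td.ModelParams(5.0, 1.0, tau=1.0)
    h = td.HistoryFunction.constant(2.0)
    coarse = td.integrate(params, sched, h, 30.0, 0.02)
    fine = td.integrate(params, sched, h, 30.0, 0.005)
    ts = np.linspace(0.0, 30.0, 500)
    assert np.max(np.abs(coarse(ts) - fine(ts))) <= 1e-4
    assert td.integral_form_residual(coarse, n_checkpoints=7) <= 1e-5


def test_dt_larger_than_tau_quarter_is_reduced_with_warning():
    params = td.ModelParams(5.0, 1.0, tau=1.0)
    sched = td.ConstantTherapy(2.0)
    traj = td.integrate(params, sched, td.HistoryFunction.constant(1.0),
                        5.0, dt=0.9)
    assert traj.meta["dt"] == pytest.approx(0.25)
    assert any("exceeds tau/4" in w for w in traj.meta["warnings"])


def test_history_callable_and_phi_form():
    params = td.ModelParams(5.0, 1.0, tau=1.0)
    sched = td.ConstantTherapy(2.0)
    h_phi = td.HistoryFunction.from_phi(lambda t: 1.0 + 0.1 * t)
    assert h_phi.x0(-1.0) == pytest.approx(0.9**3)
    traj = td.integrate(params, sched, h_phi, 5.0, 0.01)
    assert np.all(np.isfinite(traj.values))


def test_trajectory_csv_round_trip(tmp_path, fig2_traj):
    path = tmp_path / "traj.csv"
    fig2_traj.to_csv(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    assert data.shape[1] == 3
    np.testing.assert_allclose(data[:, 2] ** 3, data[:, 1], rtol=1e-12)
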