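"""Compass-pendulum single-stance dynamics against independent oracles."""

import math

import numpy as np
import pytest

from gaitfuse.errors import SingularMassMatrixError
from gaitfuse.single_stance import (
    PendulumParams,
    PendulumState,
    PendulumTrajectory,
    cog_from_pendulum,
    equation_residuals,
    heel_strike_residual,
    integrate_single_stance,
    mechanical_energy,
    single_stance_derivatives,
)


def random_state(rng, t=0.0):
    return PendulumState(
        t,
        rng.uniform(-0.5, 0.5),
        rng.uniform(-0.9, 0.9),
        rng.uniform(-1.5, 1.5),
        rng.uniform(-1.5, 1.5),
    )


# ------------------------------------------------------------ oracles

_SYMPY_ORACLE = None


def _build_sympy_oracle():
    """Independent route: assemble the Lagrangian of hip mass M and swing
    foot mass m = beta*M symbolically, solve the Euler-Lagrange system for
    the angular accelerations and lambdify once."""
    import sympy as sp

    t = sp.symbols("t")
    th, ph = sp.Function("th")(t), sp.Function("ph")(t)
    beta, l0, g, gam = sp.symbols("beta l0 g gam", positive=True, real=True)

    hip = sp.Matrix([l0 * sp.sin(th), l0 * sp.cos(th)])
    alpha = th - ph
    foot = hip - sp.Matrix([l0 * sp.sin(alpha), l0 * sp.cos(alpha)])
    vhip, vfoot = hip.diff(t), foot.diff(t)
    # true vertical height with gravity tilted by the slope gam
    h = lambda p: -p[0] * sp.sin(gam) + p[1] * sp.cos(gam)
    M, m = 1, beta  # per unit hip mass
    T = (M * vhip.dot(vhip) + m * vfoot.dot(vfoot)) / 2
    V = M * g * h(hip) + m * g * h(foot)
    L = T - V

    q = [th, ph]
    eqs = [sp.diff(sp.diff(L, qi.diff(t)), t) - sp.diff(L, qi) for qi in q]
    acc = sp.solve(eqs, [th.diff(t, 2), ph.diff(t, 2)], dict=True)[0]
    th_s, ph_s, thd_s, phd_s = sp.symbols("th_s ph_s thd_s phd_s")
    repl = {th.diff(t): thd_s, ph.diff(t): phd_s, th: th_s, ph: ph_s}
    exprs = (acc[th.diff(t, 2)].subs(repl), acc[ph.diff(t, 2)].subs(repl))
    return sp.lambdify(
        (th_s, ph_s, thd_s, phd_s, beta, l0, g, gam), exprs, modules="math"
    )


def sympy_accelerations(state, params):
    global _SYMPY_ORACLE
    if _SYMPY_ORACLE is None:
        _SYMPY_ORACLE = _build_sympy_oracle()
    return _SYMPY_ORACLE(
        state.theta, state.phi, state.theta_dot, state.phi_dot,
        params.beta, params.l0, params.g, params.slope,
    )


def rk4_reference(state0, params, t_end, n_steps):
    """Fixed-step RK4 integrator, independent of scipy."""
    y = np.array(state0.y, dtype=float)
    h = t_end / n_steps
    out = [(0.0, y.copy())]

    def f(y):
        s = PendulumState(0.0, *y)
        return np.array(single_stance_derivatives(s, params))

    for i in range(n_steps):
        k1 = f(y)
        k2 = f(y + h / 2 * k1)
        k3 = f(y + h / 2 * k2)
        k4 = f(y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(((i + 1) * h, y.copy()))
    return out


# ------------------------------------------------------------ derivatives

def test_equation_residuals_vanish(rng):
    """Returned accelerations satisfy both equations of motion."""
    params = PendulumParams(beta=0.01, l0=1.0, g=9.81, slope=0.009)
    for _ in range(100):
        s = random_state(rng)
        _, _, thdd, phdd = single_stance_derivatives(s, params)
        res = equation_residuals(s, params, thdd, phdd)
        assert np.max(np.abs(res)) <= 1e-10


def test_zero_gravity_at_rest_gives_zero_acceleration():
    params = PendulumParams(beta=0.05, l0=1.2, g=0.0, slope=0.0)
    s = PendulumState(0.0, 0.3, 0.4, 0.0, 0.0)
    _, _, thdd, phdd = single_stance_derivatives(s, params)
    assert abs(thdd) < 1e-14 and abs(phdd) < 1e-14


def test_accelerations_match_symbolic_oracle(rng):
    """Spot state plus random states against the sympy Lagrangian route."""
    params = PendulumParams(beta=0.01, l0=1.0, g=9.81, slope=0.0)
    fixed = PendulumState(0.0, 0.2, 0.5, -0.3, 0.1)
    states = [fixed] + [random_state(rng) for _ in range(12)]
    for s in states:
        _, _, thdd, phdd = single_stance_derivatives(s, params)
        o_th, o_ph = sympy_accelerations(s, params)
        assert abs(thdd - o_th) < 1e-8
        assert abs(phdd - o_ph) < 1e-8


def test_symbolic_oracle_with_slope(rng):
    params = PendulumParams(beta=0.05, l0=0.95, g=9.81, slope=0.03)
    for _ in range(5):
        s = random_state(rng)
        _, _, thdd, phdd = single_stance_derivatives(s, params)
        o_th, o_ph = sympy_accelerations(s, params)
        assert abs(thdd - o_th) < 1e-8
        assert abs(phdd - o_ph) < 1e-8


def test_singular_mass_matrix_raises():
    params = PendulumParams(beta=1e-15, l0=1.0, g=9.81)
    s = PendulumState(0.0, 0.1, 0.2, 0.1, 0.1)
    with pytest.raises(SingularMassMatrixError):
        single_stance_derivatives(s, params)


# ------------------------------------------------------------ heel strike

@pytest.mark.parametrize(
    "theta, phi, expected",
    [(0.15, 0.30, 0.0), (0.0, 0.0, 0.0), (0.1, 0.35, 0.15)],
)
def test_heel_strike_residual_definition(theta, phi, expected):
    s = PendulumState(0.0, theta, phi, 0.0, 0.0)
    assert heel_strike_residual(s) == pytest.approx(expected, abs=1e-15)


def test_immediate_event_detection():
    """A state already on the contact surface with nonzero crossing
    velocity terminates at t0."""
    params = PendulumParams()
    s = PendulumState(2.5, 0.15, 0.30, 0.5, 0.2)
    traj, t_event = integrate_single_stance(s, params, max_time=1.0)
    assert t_event == 2.5
    assert len(traj) == 1


def test_event_residual_below_tolerance(normal_traj):
    """|phi - 2 theta| <= 1e-9 at every detected heel strike."""
    from gaitfuse.fusion import preset_params

    p = preset_params("normal")
    s0 = p.resolved_initial_state()
    traj, t_event = integrate_single_stance(s0, p.pendulum_params(), 5.0, tol=1e-9)
    assert t_event is not None
    final = traj.state(len(traj) - 1)
    assert abs(heel_strike_residual(final)) <= 1e-9


def test_event_time_matches_bisection_oracle():
    """Heel-strike time against bisection on an independent fixed-step
    RK4 reference integration."""
    from gaitfuse.fusion import preset_params

    p = preset_params("normal")
    params = p.pendulum_params()
    s0 = p.resolved_initial_state()
    traj, t_event = integrate_single_stance(s0, params, 5.0)
    assert t_event is not None

    ref = rk4_reference(s0, params, t_event + 0.05, 8000)
    # find the bracketing step of the accepted crossing (theta > 0)
    res = [(t, y[1] - 2 * y[0], y[0]) for t, y in ref]
    bracket = None
    for (t1, r1, th1), (t2, r2, th2) in zip(res, res[1:]):
        if r1 * r2 <= 0 and th2 > 0.05:
            bracket = (t1, r1, t2, r2)
            break
    assert bracket is not None
    t1, r1, t2, r2 = bracket
    # linear interpolation inside one fine step
    t_oracle = t1 - r1 * (t2 - t1) / (r2 - r1)
    assert abs(t_event - t_oracle) < 1e-6


def test_no_event_returns_none():
    params = PendulumParams()
    # swinging backward: no heel strike forward of vertical
    s = PendulumState(0.0, -0.2, -0.4, -0.2, 0.0)
    traj, t_event = integrate_single_stance(s, params, max_time=0.3)
    assert t_event is None
    assert len(traj) > 10


# ------------------------------------------------------------ invariants

def test_energy_conservation_zero_slope():
    params = PendulumParams(beta=0.01, l0=1.0, g=9.81, slope=0.0)
    s0 = PendulumState(0.0, -0.2, -0.4, 0.65, 0.05)
    traj, _ = integrate_single_stance(s0, params, max_time=1.0)
    e = np.array(
        [mechanical_energy(traj.state(i), params) for i in range(len(traj))]
    )
    assert np.max(np.abs(e - e[0])) / abs(e[0]) < 1e-6


def test_time_reversal():
    """Forward then backward integration returns the initial state
    (conservative system)."""
    params = PendulumParams(beta=0.01, slope=0.0)
    s0 = PendulumState(0.0, -0.15, -0.3, 0.6, 0.1)
    traj, _ = integrate_single_stance(s0, params, max_time=0.4)
    end = traj.state(len(traj) - 1)
    back = PendulumState(0.0, end.theta, end.phi, -end.theta_dot, -end.phi_dot)
    traj2, _ = integrate_single_stance(back, params, max_time=end.t)
    final = traj2.state(len(traj2) - 1)
    assert abs(final.theta - s0.theta) < 1e-6
    assert abs(final.phi - s0.phi) < 1e-6
    assert abs(final.theta_dot + s0.theta_dot) < 1e-6
    assert abs(final.phi_dot + s0.phi_dot) < 1e-6


# ------------------------------------------------------------ CoG mapping

@pytest.mark.parametrize(
    "theta, l0, expected",
    [
        (0.0, 1.0, (0.0, 1.0)),
        (np.pi / 6, 1.0, (0.5, np.sqrt(3) / 2)),
        (-np.pi / 6, 2.0, (-1.0, np.sqrt(3))),
    ],
)
def test_cog_from_pendulum_trigonometry(theta, l0, expected):
    params = PendulumParams(l0=l0)
    cog = cog_from_pendulum(np.array([theta]), params)
    assert cog[0, 0] == pytest.approx(expected[0], abs=1e-12)
    assert cog[0, 1] == pytest.approx(expected[1], abs=1e-12)


def test_state_validation():
    with pytest.raises(ValueError):
        PendulumState(0.0, 2.0, 0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        PendulumState(0.0, np.nan, 0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        PendulumParams(beta=-0.1)


def test_trajectory_csv_round_trip(tmp_path):
    t = np.linspace(0, 1, 11)
    traj = PendulumTrajectory(t, np.sin(t), np.cos(t), t * 0.1, t * 0.2)
    path = tmp_path / "arc.csv"
    traj.to_csv(path)
    header = path.read_text().splitlines()[0]
    assert header == "t,theta,phi,theta_dot,phi_dot"
    back = PendulumTrajectory.from_csv(path)
    np.testing.assert_allclose(back.theta, traj.theta, atol=1e-12)
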