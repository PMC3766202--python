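"""Planar two-leg spring-mass dynamics of the double-support phase.

The CoG is a point mass ``M`` connected to two ground contacts by massless
leg springs: the trailing contact at the origin and the leading contact at
``(d, 0)``.  Each leg contributes a force-per-unit-length coefficient

    ll = k * (l0 / |(x, y)|     - 1)      (trailing)
    lr = k * (l0 / |(d-x, y)|   - 1)      (leading)

so that the Cartesian force components are ``ll*(x, y)`` and
``lr*(d-x, y)``; equivalently each leg is a linear spring of stiffness
``k`` and rest length ``l0`` acting along the leg axis.  Gravity acts in
``-y``.  The phase ends at toe-off, when the trailing spring returns to
its rest length (zero force) while lengthening.

Per-leg stiffness may differ (``k_left`` trailing vs ``k_right`` leading)
to emulate asymmetric disorders such as diplegia.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import GroundPenetrationError, IntegrationFailure

__all__ = [
    "SpringMassState",
    "SpringParams",
    "SpringTrajectory",
    "leg_force_coefficients",
    "double_stance_derivatives",
    "integrate_double_stance",
    "mechanical_energy",
]


@dataclass(frozen=True)
class SpringMassState:
    """CoG state in the two-contact frame (trailing foot at the origin)."""

    t: float
    x: float
    y: float
    x_dot: float
    y_dot: float

    def __post_init__(self):
        vals = (self.t, self.x, self.y, self.x_dot, self.y_dot)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite spring-mass state: {vals}")

    @property
    def vec(self) -> np.ndarray:
        return np.array([self.x, self.y, self.x_dot, self.y_dot])


@dataclass(frozen=True)
class SpringParams:
    """Double-stance parameters.

    M      body (CoG) mass, kg
    k      leg spring stiffness, N/m (per leg); ``k_left``/``k_right``
           override trailing/leading stiffness when asymmetry is wanted
    l0     rest leg length, m
    d      inter-foot distance, m
    g      gravity, m/s^2
    """

    M: float = 70.0
    k: float = 15000.0
    l0: float = 1.0
    d: float = 0.5
    g: float = 9.81
    k_left: float | None = None
    k_right: float | None = None

    def __post_init__(self):
        if self.M <= 0 or self.k <= 0 or self.l0 <= 0:
            raise ValueError("M, k, l0 must be > 0")
        if self.d < 0:
            raise ValueError("d must be >= 0")

    @property
    def k_trailing(self) -> float:
        return self.k if self.k_left is None else self.k_left

    @property
    def k_leading(self) -> float:
        return self.k if self.k_right is None else self.k_right


def leg_force_coefficients(state: SpringMassState, params: SpringParams) -> tuple[float, float]:
    """(ll, lr): force-per-unit-length coefficients of trailing/leading legs.

    Positive when the leg is compressed, zero at rest length, negative
    when stretched beyond ``l0``.
    """
    r_l = np.hypot(state.x, state.y)
    r_r = np.hypot(params.d - state.x, state.y)
    if r_l == 0.0 or r_r == 0.0:
        raise ZeroDivisionError("CoG coincides with a contact point")
    ll = params.k_trailing * (params.l0 / r_l - 1.0)
    lr = params.k_leading * (params.l0 / r_r - 1.0)
    return ll, lr


def double_stance_derivatives(
    state: SpringMassState, params: SpringParams
) -> tuple[float, float, float, float]:
    """Return (x_dot, y_dot, x_ddot, y_ddot)."""
    ll, lr = leg_force_coefficients(state, params)
    ax = (ll * state.x - lr * (params.d - state.x)) / params.M
    ay = (ll * state.y + lr * state.y) / params.M - params.g
    return state.x_dot, state.y_dot, ax, ay


def mechanical_energy(state: SpringMassState, params: SpringParams) -> float:
    """Kinetic + gravitational + both elastic potentials (J).

    The adopted force law is a linear spring along each leg, so the
    elastic term has the closed form ``0.5*k*(l0 - l)^2`` per leg.
    """
    r_l = np.hypot(state.x, state.y)
    r_r = np.hypot(params.d - state.x, state.y)
    kin = 0.5 * params.M * (state.x_dot**2 + state.y_dot**2)
    pot = params.M * params.g * state.y
    el = 0.5 * params.k_trailing * (params.l0 - r_l) ** 2
    el += 0.5 * params.k_leading * (params.l0 - r_r) ** 2
    return kin + pot + el


class SpringTrajectory:
    """Dense sampled double-stance arc (with per-sample force coefficients)."""

    def __init__(self, t, x, y, x_dot, y_dot, ll, lr):
        self.t = np.asarray(t, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.x_dot = np.asarray(x_dot, dtype=float)
        self.y_dot = np.asarray(y_dot, dtype=float)
        self.ll = np.asarray(ll, dtype=float)
        self.lr = np.asarray(lr, dtype=float)

    def __len__(self):
        return self.t.size

    def state(self, i: int) -> SpringMassState:
        return SpringMassState(self.t[i], self.x[i], self.y[i], self.x_dot[i], self.y_dot[i])

    def to_csv(self, path_or_buf) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "t": self.t,
                "x": self.x,
                "y": self.y,
                "x_dot": self.x_dot,
                "y_dot": self.y_dot,
                "ll": self.ll,
                "lr": self.lr,
            }
        ).to_csv(path_or_buf, index=False)

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def integrate_double_stance(
    state0: SpringMassState,
    params: SpringParams,
    max_time: float,
    tol: float = 1e-9,
    dt: float = 0.002,
    rtol: float = 1e-10,
    atol: float = 1e-10,
) -> tuple[SpringTrajectory, float | None]:
    """Integrate double stance until toe-off or ``max_time``.

    Toe-off is the instant the trailing-leg force coefficient ``ll``
    crosses zero from above (the leg regains rest length while
    lengthening); the event is located so that ``|ll| <= tol``.  Returns
    ``(trajectory, toe_off_time)`` with ``toe_off_time`` ``None`` if no
    toe-off occurs within ``max_time``.

    Raises :class:`GroundPenetrationError` if the CoG reaches ``y <= 0``.
    """
    if max_time <= 0:
        raise ValueError("max_time must be > 0")
    t0 = state0.t

    def coeffs(y):
        s = SpringMassState(0.0, y[0], y[1], y[2], y[3])
        return leg_force_coefficients(s, params)

    ll0, _ = coeffs(state0.vec)
    # immediate toe-off: trailing leg at rest length and lengthening
    r_l = np.hypot(state0.x, state0.y)
    r_dot = (state0.x * state0.x_dot + state0.y * state0.y_dot) / r_l
    if abs(ll0) <= tol and r_dot > 1e-9:
        ll, lr = coeffs(state0.vec)
        traj = SpringTrajectory(
            [t0], [state0.x], [state0.y], [state0.x_dot], [state0.y_dot], [ll], [lr]
        )
        return traj, t0

    def rhs(t, y):
        s = SpringMassState(t, y[0], y[1], y[2], y[3])
        return double_stance_derivatives(s, params)

    def toe_off(t, y):
        return coeffs(y)[0]

    toe_off.direction = -1.0  # ll decreasing through zero (compression released)
    toe_off.terminal = True

    def ground(t, y):
        return y[1]

    ground.direction = -1.0
    ground.terminal = True

    sol = solve_ivp(
        rhs,
        (t0, t0 + max_time),
        state0.vec,
        method="DOP853",
        dense_output=True,
        events=[toe_off, ground],
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationFailure(f"double-stance integration failed: {sol.message}")
    if sol.t_events[1].size > 0:
        raise GroundPenetrationError(
            f"CoG reached the ground at t={sol.t_events[1][0]:.4f} s "
            "(parameters cannot support the body)"
        )

    t_event = None
    valid = [te for te in sol.t_events[0] if te > t0]
    if valid:
        te = valid[0]
        h = min(1e-6, (te - t0) / 2)
        f = lambda t: coeffs(sol.sol(t))[0]
        lo, hi = te - h, min(te + h, sol.t[-1])
        if f(lo) * f(hi) < 0:
            t_event = brentq(f, lo, hi, xtol=1e-15, rtol=1e-15)
        else:
            t_event = te

    t_end = t_event if t_event is not None else sol.t[-1]
    grid = np.arange(t0, t_end, dt)
    if grid.size == 0 or grid[-1] < t_end:
        grid = np.append(grid, t_end)
    ys = sol.sol(grid)
    lls, lrs = [], []
    for col in ys.T:
        ll, lr = coeffs(col)
        lls.append(ll)
        lrs.append(lr)
    traj = SpringTrajectory(grid, ys[0], ys[1], ys[2], ys[3], lls, lrs)
    return traj, t_event
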