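"""Compass-pendulum dynamics of the single-support phase.

The body is reduced to a hip point mass ``M`` carried by a rigid stance leg
of length ``l0`` pivoting on the stance foot, plus a foot point mass
``m = beta * M`` at the end of the swing leg.  Generalized coordinates are

* ``theta`` -- angle of the stance leg w.r.t. the slope normal, positive
  when the hip is ahead of the stance foot (direction of travel),
* ``phi``   -- inter-leg angle, measured from the stance leg to the swing
  leg, so that the swing-leg absolute angle is ``theta - phi``.

With these conventions the swing foot touches the ground exactly when
``phi - 2*theta = 0`` (legs symmetric about the slope normal), which is the
heel-strike event that terminates the phase.  The equations of motion are
obtained from the Lagrangian of the two point masses; both lines are linear
in the angular accelerations, so each evaluation assembles a 2x2 mass
matrix and solves it.  The system is conservative: mechanical energy along
any integrated arc is a strict accuracy diagnostic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import IntegrationFailure, SingularMassMatrixError

__all__ = [
    "PendulumState",
    "PendulumParams",
    "PendulumTrajectory",
    "single_stance_derivatives",
    "heel_strike_residual",
    "integrate_single_stance",
    "cog_from_pendulum",
    "mechanical_energy",
]

#: condition-number bound above which the mass matrix is declared singular
COND_BOUND = 1e12


@dataclass(frozen=True)
class PendulumState:
    """Instantaneous state of the compass pendulum (angles in rad)."""

    t: float
    theta: float
    phi: float
    theta_dot: float
    phi_dot: float

    def __post_init__(self):
        vals = (self.t, self.theta, self.phi, self.theta_dot, self.phi_dot)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite pendulum state: {vals}")
        if not (-np.pi / 2 < self.theta < np.pi / 2):
            raise ValueError(f"theta={self.theta} outside (-pi/2, pi/2)")
        if not (-np.pi / 2 < self.phi < np.pi / 2):
            raise ValueError(f"phi={self.phi} outside (-pi/2, pi/2)")

    @property
    def y(self) -> np.ndarray:
        """State vector [theta, phi, theta_dot, phi_dot]."""
        return np.array([self.theta, self.phi, self.theta_dot, self.phi_dot])


@dataclass(frozen=True)
class PendulumParams:
    """Parameters of the compass pendulum.

    beta
        Foot-to-hip mass ratio m/M (dimensionless).  Small values give
        the classic passive-walking regime.
    l0
        Leg length in metres (both legs equal).
    g
        Gravitational acceleration, m/s^2.
    slope
        Ground slope in radians.  Angles are measured from the slope
        normal; gravity is tilted by ``slope`` in this frame.
    """

    beta: float = 0.01
    l0: float = 1.0
    g: float = 9.81
    slope: float = 0.009

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.l0 <= 0:
            raise ValueError("l0 must be > 0")
        if self.g < 0:
            raise ValueError("g must be >= 0")


def _mass_matrix(phi: float, beta: float) -> np.ndarray:
    c = beta * (1.0 - np.cos(phi))
    return np.array([[1.0 + 2.0 * c, -c], [-c, beta]])


def _forcing(theta, phi, theta_dot, phi_dot, params: PendulumParams) -> np.ndarray:
    beta, g_l = params.beta, params.g / params.l0
    s_phi = np.sin(phi)
    swing = theta - phi + params.slope  # absolute swing-leg angle + gravity tilt
    return np.array(
        [
            beta * s_phi * (phi_dot**2 - 2.0 * theta_dot * phi_dot)
            + g_l * ((1.0 + beta) * np.sin(theta + params.slope) - beta * np.sin(swing)),
            beta * theta_dot**2 * s_phi + g_l * beta * np.sin(swing),
        ]
    )


def single_stance_derivatives(
    state: PendulumState, params: PendulumParams
) -> tuple[float, float, float, float]:
    """Return (theta_dot, phi_dot, theta_ddot, phi_ddot).

    Raises :class:`SingularMassMatrixError` when the assembled 2x2 system
    is conditioned worse than ``COND_BOUND``.
    """
    acc = _accelerations(state.theta, state.phi, state.theta_dot, state.phi_dot, params)
    return state.theta_dot, state.phi_dot, acc[0], acc[1]


def _accelerations(theta, phi, theta_dot, phi_dot, params) -> np.ndarray:
    a = _mass_matrix(phi, params.beta)
    if np.linalg.cond(a) > COND_BOUND:
        raise SingularMassMatrixError(
            f"mass matrix condition number {np.linalg.cond(a):.2e} exceeds "
            f"{COND_BOUND:.0e} (phi={phi}, beta={params.beta})"
        )
    return np.linalg.solve(a, _forcing(theta, phi, theta_dot, phi_dot, params))


def equation_residuals(
    state: PendulumState, params: PendulumParams, theta_ddot: float, phi_ddot: float
) -> np.ndarray:
    """Residual of both equations of motion for given accelerations.

    Zero (to solver round-off) iff the accelerations satisfy the dynamics;
    used as the defining self-check of :func:`single_stance_derivatives`.
    """
    a = _mass_matrix(state.phi, params.beta)
    rhs = _forcing(state.theta, state.phi, state.theta_dot, state.phi_dot, params)
    return a @ np.array([theta_ddot, phi_ddot]) - rhs


def heel_strike_residual(state: PendulumState) -> float:
    """phi - 2*theta; zero when the swing foot reaches the ground."""
    return state.phi - 2.0 * state.theta


def mechanical_energy(state: PendulumState, params: PendulumParams, M: float = 1.0) -> float:
    """Total mechanical energy (J) of the two point masses.

    Constant along any single-stance arc; the default ``M=1`` gives energy
    per unit hip mass, which is all the conservation diagnostic needs.
    """
    beta, l0, g = params.beta, params.l0, params.g
    td, pd = state.theta_dot, state.phi_dot
    kin = 0.5 * M * l0**2 * (
        td**2 + beta * (td**2 + (td - pd) ** 2 - 2.0 * td * (td - pd) * np.cos(state.phi))
    )
    pot = M * g * l0 * (
        (1.0 + beta) * np.cos(state.theta + params.slope)
        - beta * np.cos(state.theta - state.phi + params.slope)
    )
    return kin + pot


def cog_from_pendulum(theta_series: np.ndarray, params: PendulumParams) -> np.ndarray:
    """CoG path (N, 2) in stance-foot-anchored coordinates.

    During single stance the CoG rides the hip: (l0 sin(theta), l0 cos(theta)).
    """
    th = np.asarray(theta_series, dtype=float)
    return np.column_stack([params.l0 * np.sin(th), params.l0 * np.cos(th)])


class PendulumTrajectory:
    """Dense sampled single-stance arc."""

    def __init__(self, t, theta, phi, theta_dot, phi_dot):
        self.t = np.asarray(t, dtype=float)
        self.theta = np.asarray(theta, dtype=float)
        self.phi = np.asarray(phi, dtype=float)
        self.theta_dot = np.asarray(theta_dot, dtype=float)
        self.phi_dot = np.asarray(phi_dot, dtype=float)

    def __len__(self):
        return self.t.size

    def state(self, i: int) -> PendulumState:
        return PendulumState(
            self.t[i], self.theta[i], self.phi[i], self.theta_dot[i], self.phi_dot[i]
        )

    def to_csv(self, path_or_buf) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "t": self.t,
                "theta": self.theta,
                "phi": self.phi,
                "theta_dot": self.theta_dot,
                "phi_dot": self.phi_dot,
            }
        ).to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "PendulumTrajectory":
        import pandas as pd

        df = pd.read_csv(path_or_buf)
        return cls(df.t, df.theta, df.phi, df.theta_dot, df.phi_dot)

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def integrate_single_stance(
    state0: PendulumState,
    params: PendulumParams,
    max_time: float,
    tol: float = 1e-9,
    dt: float = 0.002,
    min_theta: float = 0.0,
    rtol: float = 1e-10,
    atol: float = 1e-10,
) -> tuple[PendulumTrajectory, float | None]:
    """Integrate the compass pendulum until heel strike or ``max_time``.

    The heel-strike surface ``phi - 2*theta = 0`` is monitored for zero
    crossings; crossings with ``theta <= min_theta`` are discarded as the
    swing foot scuffing the ground mid-swing (the well-known artifact of
    compass models -- a genuine heel strike needs the stance leg past the
    slope normal).  If the initial state already satisfies the condition
    with nonzero crossing velocity (and clears the scuff filter), the
    event time is ``t0``.

    Returns ``(trajectory, event_time)``; ``event_time`` is ``None`` when
    no heel strike occurs within ``max_time`` (not an error).  The
    trajectory is truncated at the event, whose final sample satisfies
    ``|phi - 2*theta| <= tol``.
    """
    if max_time <= 0:
        raise ValueError("max_time must be > 0")
    t0 = state0.t
    r0 = heel_strike_residual(state0)
    rdot0 = state0.phi_dot - 2.0 * state0.theta_dot
    if abs(r0) <= tol and rdot0 != 0 and state0.theta > min_theta:
        traj = PendulumTrajectory(
            [t0], [state0.theta], [state0.phi], [state0.theta_dot], [state0.phi_dot]
        )
        return traj, t0

    def rhs(t, y):
        return [y[2], y[3], *_accelerations(y[0], y[1], y[2], y[3], params)]

    def event(t, y):
        return y[1] - 2.0 * y[0]

    event.direction = 0.0  # either direction; scuff filter applied below
    event.terminal = False

    sol = solve_ivp(
        rhs,
        (t0, t0 + max_time),
        state0.y,
        method="DOP853",
        dense_output=True,
        events=[event],
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationFailure(f"single-stance integration failed: {sol.message}")

    t_event = None
    for te in sol.t_events[0]:
        if te <= t0:
            continue
        y_e = sol.sol(te)
        if y_e[0] > min_theta:
            # polish the root on the dense output to machine precision
            h = min(1e-6, (te - t0) / 2)
            f = lambda t: sol.sol(t)[1] - 2.0 * sol.sol(t)[0]
            lo, hi = te - h, min(te + h, sol.t[-1])
            if f(lo) * f(hi) < 0:
                t_event = brentq(f, lo, hi, xtol=1e-15, rtol=1e-15)
            else:
                t_event = te
            break

    t_end = t_event if t_event is not None else sol.t[-1]
    grid = np.arange(t0, t_end, dt)
    if grid.size == 0 or grid[-1] < t_end:
        grid = np.append(grid, t_end)
    ys = sol.sol(grid)
    traj = PendulumTrajectory(grid, ys[0], ys[1], ys[2], ys[3])
    return traj, t_event
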