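"""Fused gait cycles: alternate compass-pendulum and spring-mass phases.

A full gait cycle (ipsilateral heel strike to ipsilateral heel strike,
i.e. two steps) is assembled by switching between the two dynamical
regimes:

* single stance while ``phi - 2*theta < 0`` (compass pendulum),
* double stance from heel strike until the trailing spring returns to
  rest length (toe-off).

State hand-off preserves the CoG position exactly at both switches.  At
heel strike both legs have length ``l0`` so the mapping into the
two-contact spring frame is the plain polar-to-Cartesian change of
coordinates.  At toe-off the leading leg is in general still slightly
compressed; the new pendulum pivot is therefore projected along the leg
axis so the CoG does not jump, and the CoG velocity component radial to
the new pivot is dropped (a rigid stance leg cannot carry it) -- the
model's only source of dissipation.

Pathology presets fix ``(k, d, l0)`` per gait class: the printed crouch
and Parkinson values drive shorter steps (``d``) and altered leg
stiffness (``k``).  Pathological stiffnesses are expressed per unit body
mass (model mass 1 kg); the normal preset uses a 70 kg body with an
absolute leg stiffness calibrated so that double stance occupies about
20% of the cycle.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .double_stance import (
    SpringMassState,
    SpringParams,
    integrate_double_stance,
)
from .errors import NonWalkingParamsError
from .single_stance import (
    PendulumParams,
    PendulumState,
    integrate_single_stance,
)

__all__ = [
    "GaitParams",
    "CoGTrajectory",
    "GaitEvent",
    "preset_params",
    "handoff_pendulum_to_spring",
    "handoff_spring_to_pendulum",
    "simulate_gait",
    "normalize_to_cycle",
    "NormalizedCycle",
    "PRESETS",
    "PARKINSON_STAGE_TABLE",
]

log = logging.getLogger(__name__)

#: (k, d) learned per Parkinson stage (stiffness per kg of model mass, m)
PARKINSON_STAGE_TABLE: dict[int, tuple[float, float]] = {
    2: (52.3, 0.76105),
    3: (67.42, 0.5576),
    4: (96.8, 0.4356),
}

GAIT_CLASSES = (
    "normal",
    "crouch",
    "parkinson",
    "parkinson_stage2",
    "parkinson_stage3",
    "parkinson_stage4",
    "custom",
)


@dataclass(frozen=True)
class GaitParams:
    """Complete parameter record consumed by every pipeline stage."""

    gait_class: str = "custom"
    M: float = 70.0
    m: float = 0.7
    l0: float = 1.0
    k: float = 15000.0
    d: float = 0.5
    g: float = 9.81
    slope: float = 0.009
    launch: float = 1.2  # initial stance angular rate, in units of the
    # minimum rate needed to vault the pendulum over its apex
    step_angle: float | None = None  # stance amplitude theta* (rad); None
    # derives it from d as asin(d / (2*l0))
    regulate: bool = True  # steady-gait regulation: at every toe-off the
    # new step is launched with a stance rate just above the vault
    # threshold of its starting geometry (factor ``launch``) and a swing
    # rate proportional to the leg's remaining excursion (gain
    # ``swing_gain``), emulating the active step-to-step control of real
    # walking; the passive dynamics evolve untouched within each phase.
    # False gives the raw passive hybrid, which has no stable limit
    # cycle in this parameter regime and soon stops striking.
    swing_gain: float = 1.0  # dimensionless swing-initiation gain
    k_left: float | None = None
    k_right: float | None = None
    initial_state: PendulumState | None = None

    def __post_init__(self):
        if self.gait_class not in GAIT_CLASSES:
            raise ValueError(f"unknown gait class {self.gait_class!r}")
        if self.M <= 0 or self.m <= 0 or self.l0 <= 0 or self.k <= 0:
            raise ValueError("M, m, l0, k must be > 0")
        if not 0 <= self.d < 2 * self.l0:
            raise ValueError("d must satisfy 0 <= d < 2*l0")

    @property
    def beta(self) -> float:
        """Mass ratio m/M, recomputed (never stored independently)."""
        return self.m / self.M

    def pendulum_params(self) -> PendulumParams:
        return PendulumParams(beta=self.beta, l0=self.l0, g=self.g, slope=self.slope)

    def spring_params(self, d_eff: float | None = None) -> SpringParams:
        return SpringParams(
            M=self.M,
            k=self.k,
            l0=self.l0,
            d=self.d if d_eff is None else d_eff,
            g=self.g,
            k_left=self.k_left,
            k_right=self.k_right,
        )

    def nominal_rate(self) -> float:
        """Template stance angular rate at the start of a step (rad/s)."""
        theta_star = (
            self.step_angle
            if self.step_angle is not None
            else math.asin(self.d / (2 * self.l0))
        )
        vault = math.sqrt(
            2 * self.g * (1 - math.cos(theta_star - self.slope)) / self.l0
        )
        return self.launch * vault

    def default_initial_state(self) -> PendulumState:
        """Start of a step: stance leg at -theta*, swing foot on the
        previous contact, stance rate set by the launch factor."""
        theta_star = (
            self.step_angle
            if self.step_angle is not None
            else math.asin(self.d / (2 * self.l0))
        )
        # launch rate carries the stance leg over the potential apex at
        # theta = -slope (gravity is tilted by the ground slope)
        theta_dot0 = self.nominal_rate()
        phi0 = -2 * theta_star
        # swing foot momentarily at rest on the ground
        phi_dot0 = theta_dot0 * (1 - math.cos(phi0))
        return PendulumState(0.0, -theta_star, phi0, theta_dot0, phi_dot0)

    def resolved_initial_state(self) -> PendulumState:
        return self.initial_state if self.initial_state is not None else self.default_initial_state()

    # -- JSON config round trip -------------------------------------
    def to_dict(self) -> dict:
        d = {
            "gait_class": self.gait_class,
            "M": self.M,
            "m": self.m,
            "l0": self.l0,
            "k": self.k,
            "d": self.d,
            "g": self.g,
            "slope": self.slope,
            "launch": self.launch,
            "step_angle": self.step_angle,
            "regulate": self.regulate,
            "swing_gain": self.swing_gain,
            "k_left": self.k_left,
            "k_right": self.k_right,
        }
        if self.initial_state is not None:
            s = self.initial_state
            d["initial_state"] = {
                "t": s.t,
                "theta": s.theta,
                "phi": s.phi,
                "theta_dot": s.theta_dot,
                "phi_dot": s.phi_dot,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GaitParams":
        d = dict(d)
        init = d.pop("initial_state", None)
        if init is not None:
            init = PendulumState(**init)
        return cls(initial_state=init, **d)

    def to_json(self, path_or_buf=None) -> str | None:
        s = json.dumps(self.to_dict(), indent=2)
        if path_or_buf is None:
            return s
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(s)
        else:
            with open(path_or_buf, "w", encoding="utf-8") as fh:
                fh.write(s)
        return None

    @classmethod
    def from_json(cls, path_or_buf) -> "GaitParams":
        if hasattr(path_or_buf, "read"):
            d = json.load(path_or_buf)
        elif isinstance(path_or_buf, str) and path_or_buf.lstrip().startswith("{"):
            d = json.loads(path_or_buf)
        else:
            with open(path_or_buf, encoding="utf-8") as fh:
                d = json.load(fh)
        return cls.from_dict(d)


# Frozen presets.  The normal-gait k, d, step angle and launch were
# calibrated once so that the simulated double-stance fraction is ~20% of
# the cycle with the contralateral toe-off near 60% (the clinical timing
# landmarks), and its initial state is the steady periodic step of that
# parameter set; they are not meant to be edited.  The pathological
# entries take the printed disease parameters verbatim (stiffness per
# unit model mass, see module docstring); their launch / swing-gain /
# step-angle values are the gait-control settings under which the
# printed (k, d) produce a sustained walk.
_NORMAL_STEADY = dict(
    t=0.0,
    theta=-0.17612330250056998,
    phi=-0.5146901564206234,
    theta_dot=0.5489784293944772,
    phi_dot=0.911923980609254,
)
PRESETS: dict[str, dict] = {
    "normal": dict(
        M=70.0, m=0.7, l0=1.0, k=9150.0, d=0.5, slope=0.009,
        step_angle=0.2, launch=1.05, swing_gain=1.0,
        initial_state=PendulumState(**_NORMAL_STEADY),
    ),
    "crouch": dict(M=1.0, m=0.01, l0=0.95, k=400.0, d=0.65, slope=0.009,
                   launch=1.05, swing_gain=1.0),
    "parkinson": dict(M=1.0, m=0.01, l0=1.0, k=500.0, d=0.58, slope=0.009,
                      launch=1.05, swing_gain=1.0),
    "parkinson_stage2": dict(M=1.0, m=0.01, l0=1.0, k=52.3, d=0.76105,
                             slope=0.009, step_angle=0.30, launch=1.05,
                             swing_gain=1.0),
    "parkinson_stage3": dict(M=1.0, m=0.01, l0=1.0, k=67.42, d=0.5576,
                             slope=0.009, launch=1.05, swing_gain=1.3),
    "parkinson_stage4": dict(M=1.0, m=0.01, l0=1.0, k=96.8, d=0.4356,
                             slope=0.009, launch=1.05, swing_gain=1.0),
}


def preset_params(gait_class: str, stage_table: dict[int, tuple[float, float]] | None = None) -> GaitParams:
    """Parameter record for a named gait class.

    ``stage_table`` overrides the per-stage ``(k, d)`` pairs of the
    Parkinson presets (default: the learned-from-patients table).
    """
    if gait_class not in PRESETS:
        raise ValueError(
            f"unknown gait class {gait_class!r}; expected one of {sorted(PRESETS)}"
        )
    cfg = dict(PRESETS[gait_class])
    if gait_class.startswith("parkinson_stage"):
        stage = int(gait_class[-1])
        table = PARKINSON_STAGE_TABLE if stage_table is None else stage_table
        k, d = table[stage]
        cfg["k"], cfg["d"] = k, d
    return GaitParams(gait_class=gait_class, **cfg)


# ---------------------------------------------------------------- handoffs

def handoff_pendulum_to_spring(
    state: PendulumState, params: GaitParams, tol: float = 1e-6
) -> tuple[SpringMassState, float]:
    """Map a heel-strike pendulum state into the two-contact spring frame.

    Returns ``(spring_state, d_eff)`` where ``d_eff = 2*l0*sin(theta)`` is
    the geometric landing separation of the feet (both legs have length
    ``l0`` at heel strike, so position and velocity carry over exactly).
    A warning is logged when ``d_eff`` is incompatible with the configured
    ``d`` (the step the passive dynamics produced differs from the step
    the preset asked for).
    """
    r = state.phi - 2 * state.theta
    if abs(r) > 1e-6:
        log.warning("handoff at |phi-2theta|=%.2e, not on the heel-strike surface", abs(r))
    l0 = params.l0
    x = l0 * math.sin(state.theta)
    y = l0 * math.cos(state.theta)
    vx = l0 * state.theta_dot * math.cos(state.theta)
    vy = -l0 * state.theta_dot * math.sin(state.theta)
    d_eff = 2 * l0 * math.sin(state.theta)
    if params.d > 0 and abs(d_eff - params.d) > 0.25 * params.d:
        log.warning(
            "landing separation %.3f m deviates from configured d=%.3f m", d_eff, params.d
        )
    return SpringMassState(state.t, x, y, vx, vy), d_eff


def handoff_spring_to_pendulum(
    state: SpringMassState,
    params: GaitParams,
    d_eff: float,
    stance: str = "leading",
) -> tuple[PendulumState, float]:
    """Map a toe-off spring state back onto the compass pendulum.

    With ``stance="leading"`` (the gait-cycle direction) the leading
    contact becomes the stance pivot and the trailing contact the swing
    foot.  The pivot is projected along the leading-leg axis so the CoG
    position is preserved exactly even if that leg is not at rest length;
    the returned second value is the signed pivot shift ``l0 - l_leading``
    (how far the effective contact point slid).  Angular rates follow by
    the chain rule with both feet momentarily at rest.

    ``stance="trailing"`` performs the algebraic inverse of
    :func:`handoff_pendulum_to_spring` (same leg assignment), used to
    verify the round trip.
    """
    l0 = params.l0
    v = np.array([state.x_dot, state.y_dot])
    if stance == "trailing":
        w = np.array([state.x, state.y])
    elif stance == "leading":
        w = np.array([state.x - d_eff, state.y])
    else:
        raise ValueError("stance must be 'leading' or 'trailing'")
    ell = float(np.hypot(*w))
    if ell == 0:
        raise ValueError("CoG coincides with the stance contact")
    theta = math.atan2(w[0], w[1])
    shift = l0 - ell
    if abs(shift) > 0.1 * l0:
        log.warning(
            "stance leg length %.3f m far from l0=%.3f m at toe-off; pivot shifted %.3f m",
            ell, l0, shift,
        )
    t_hat = np.array([math.cos(theta), -math.sin(theta)])
    theta_dot = float(v @ t_hat) / l0
    # swing leg: the other contact
    if stance == "trailing":
        ws = np.array([state.x - d_eff, state.y])
    else:
        ws = np.array([state.x, state.y])
    alpha = math.atan2(ws[0], ws[1])
    ts_hat = np.array([math.cos(alpha), -math.sin(alpha)])
    alpha_dot = float(v @ ts_hat) / float(np.hypot(*ws))
    phi = theta - alpha
    phi_dot = theta_dot - alpha_dot
    return PendulumState(state.t, theta, phi, theta_dot, phi_dot), shift


# ---------------------------------------------------------------- trajectory

SINGLE = "single_stance"
DOUBLE = "double_stance"


@dataclass(frozen=True)
class GaitEvent:
    t: float
    kind: str  # "heel_strike" | "toe_off"
    foot: str  # foot that strikes (heel_strike) / leaves the ground (toe_off)


@dataclass
class CoGTrajectory:
    """Time-indexed CoG path with phase labels and cycle events."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phase: np.ndarray  # array of SINGLE/DOUBLE strings
    cycle_events: list[GaitEvent] = field(default_factory=list)
    percent_cycle: np.ndarray | None = None
    boundary_jumps: list[float] = field(default_factory=list)  # CoG
    # position discontinuity at each phase handoff (continuity audit)
    support_y: np.ndarray | None = None  # height of the current support
    # surface; y - support_y is the CoG height above ground, the periodic
    # quantity gait laboratories plot (the absolute y slowly descends with
    # the effective contact point, see the toe-off handoff)

    def __len__(self):
        return self.t.size

    def height_above_support(self) -> np.ndarray:
        if self.support_y is None:
            return self.y
        return self.y - self.support_y

    def heel_strikes(self) -> list[GaitEvent]:
        return [e for e in self.cycle_events if e.kind == "heel_strike"]

    def toe_offs(self) -> list[GaitEvent]:
        return [e for e in self.cycle_events if e.kind == "toe_off"]

    def n_cycles(self) -> int:
        return max(0, (len(self.heel_strikes()) - 1) // 2)

    def cycle_bounds(self, i: int) -> tuple[float, float]:
        """Time bounds of cycle ``i`` (ipsilateral heel strike to heel strike)."""
        hs = self.heel_strikes()
        if len(hs) < 2 * i + 3:
            raise IndexError(f"cycle {i} not present ({self.n_cycles()} cycles)")
        return hs[2 * i].t, hs[2 * i + 2].t

    def _compute_percent(self) -> None:
        pc = np.full(self.t.shape, np.nan)
        for i in range(self.n_cycles()):
            t0, t1 = self.cycle_bounds(i)
            mask = (self.t >= t0) & (self.t <= t1)
            pc[mask] = 100.0 * (self.t[mask] - t0) / (t1 - t0)
        self.percent_cycle = pc

    def to_csv(self, path_or_buf) -> None:
        import pandas as pd

        if self.percent_cycle is None:
            self._compute_percent()
        cols = {
            "t": self.t,
            "percent_cycle": self.percent_cycle,
            "x": self.x,
            "y": self.y,
            "phase": self.phase,
        }
        if self.support_y is not None:
            cols["support_y"] = self.support_y
        pd.DataFrame(cols).to_csv(path_or_buf, index=False)

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()

    # -- cycle summaries --------------------------------------------
    def double_stance_fraction(self, cycle: int) -> float:
        """Percent of cycle time spent in double stance."""
        t0, t1 = self.cycle_bounds(cycle)
        ds = 0.0
        for hs in self.heel_strikes():
            if t0 <= hs.t < t1:
                tos = [e.t for e in self.toe_offs() if e.t > hs.t]
                if tos and tos[0] <= t1:
                    ds += tos[0] - hs.t
        return 100.0 * ds / (t1 - t0)

    def event_percents(self, cycle: int) -> dict[str, float]:
        """Positions (% of cycle) of the interior phase-transition events.

        ``contralateral_heel_strike`` is the opposite foot's landing near
        mid-cycle; ``contralateral_toe_off`` the transition ending the
        double stance it initiates (the clinical "about 60%" landmark).
        """
        t0, t1 = self.cycle_bounds(cycle)
        span = t1 - t0
        out = {}
        hs_in = [e for e in self.heel_strikes() if t0 < e.t < t1]
        if hs_in:
            out["contralateral_heel_strike"] = 100.0 * (hs_in[0].t - t0) / span
            tos = [e for e in self.toe_offs() if e.t > hs_in[0].t]
            if tos and tos[0].t <= t1:
                out["contralateral_toe_off"] = 100.0 * (tos[0].t - t0) / span
        first_to = [e for e in self.toe_offs() if t0 < e.t < t1]
        if first_to:
            out["first_toe_off"] = 100.0 * (first_to[0].t - t0) / span
        return out

    def stride_length(self, cycle: int) -> float:
        """Forward CoG displacement over one cycle (m)."""
        t0, t1 = self.cycle_bounds(cycle)
        x0 = float(np.interp(t0, self.t, self.x))
        x1 = float(np.interp(t1, self.t, self.x))
        return x1 - x0


def simulate_gait(
    params: GaitParams,
    n_cycles: int,
    seed: int = 0,
    dt: float = 0.002,
    phase_time_cap: float = 5.0,
    rtol: float = 1e-10,
    atol: float = 1e-10,
) -> CoGTrajectory:
    """Simulate ``n_cycles`` full gait cycles of the fused hybrid model.

    The simulation starts at the beginning of a single-stance phase (just
    after a toe-off) and runs until ``2*n_cycles + 1`` heel strikes have
    occurred, so the trajectory contains ``n_cycles`` complete
    heel-strike-to-ipsilateral-heel-strike cycles plus a leading partial
    step.  Deterministic given ``params`` (the model itself has no random
    component; ``seed`` is accepted for interface uniformity).

    Raises :class:`NonWalkingParamsError` naming the phase that failed
    when a phase does not terminate within ``phase_time_cap`` seconds.
    """
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    if n_cycles == 0:
        return CoGTrajectory(
            np.empty(0), np.empty(0), np.empty(0), np.empty(0, dtype=object), []
        )

    pend = params.pendulum_params()
    state = params.resolved_initial_state()
    pivot = np.zeros(2)  # stance contact, world (slope-frame) coordinates
    feet = ("right", "left")
    swing_idx = 0  # the swing foot strikes at each heel strike; start: right swings

    ts, xs, ys, sups, phases = [], [], [], [], []
    events: list[GaitEvent] = []
    jumps: list[float] = []
    needed_hs = 2 * n_cycles + 1

    def extend(t_arr, x_arr, y_arr, support, label):
        if ts and t_arr.size and ts[-1].size and t_arr[0] <= ts[-1][-1] + 1e-12:
            t_arr, x_arr, y_arr = t_arr[1:], x_arr[1:], y_arr[1:]
        ts.append(t_arr)
        xs.append(x_arr)
        ys.append(y_arr)
        sups.append(np.full(t_arr.shape, support))
        phases.append(np.full(t_arr.shape, label, dtype=object))

    while len([e for e in events if e.kind == "heel_strike"]) < needed_hs:
        # --- single stance ---
        traj, t_hs = integrate_single_stance(
            state, pend, max_time=phase_time_cap, dt=dt, rtol=rtol, atol=atol
        )
        extend(
            traj.t,
            pivot[0] + params.l0 * np.sin(traj.theta),
            pivot[1] + params.l0 * np.cos(traj.theta),
            pivot[1],
            SINGLE,
        )
        if t_hs is None:
            raise NonWalkingParamsError(
                "single_stance",
                f"no heel strike within {phase_time_cap} s "
                f"(theta ended at {traj.theta[-1]:.3f} rad)",
            )
        hs_state = traj.state(len(traj) - 1)
        events.append(GaitEvent(t_hs, "heel_strike", feet[swing_idx]))
        swing_idx = 1 - swing_idx
        if len([e for e in events if e.kind == "heel_strike"]) >= needed_hs:
            break

        # --- hand off to double stance ---
        # the leading foot is planted at the configured inter-foot distance
        # (the step anticipates the CoG travel of the coming double stance);
        # the handoff warns when this is geometrically far from where the
        # swing leg actually points.
        spring_state, _d_geo = handoff_pendulum_to_spring(hs_state, params)
        d_eff = params.d
        spring = params.spring_params(d_eff)
        cog_before = pivot + params.l0 * np.array(
            [math.sin(hs_state.theta), math.cos(hs_state.theta)]
        )
        cog_after = pivot + np.array([spring_state.x, spring_state.y])
        jumps.append(float(np.hypot(*(cog_after - cog_before))))
        straj, t_to = integrate_double_stance(
            spring_state, spring, max_time=phase_time_cap, dt=dt, rtol=rtol, atol=atol
        )
        extend(straj.t, pivot[0] + straj.x, pivot[1] + straj.y, pivot[1], DOUBLE)
        if t_to is None:
            raise NonWalkingParamsError(
                "double_stance", f"no toe-off within {phase_time_cap} s"
            )
        to_state = straj.state(len(straj) - 1)
        # the foot that leaves the ground is the old stance foot (trailing)
        events.append(GaitEvent(t_to, "toe_off", feet[1 - swing_idx]))

        # --- hand off back to single stance ---
        new_state, shift = handoff_spring_to_pendulum(to_state, params, d_eff)
        if params.regulate:
            # steady-gait regulation (active step-to-step control): the
            # stance launches just fast enough to vault its apex from the
            # current geometry, and the swing leg is driven in proportion
            # to the excursion it still has to cover before the next
            # symmetric contact
            barrier = math.sqrt(
                2 * params.g
                * (1 - math.cos(new_state.theta + params.slope))
                / params.l0
            )
            rate = params.launch * barrier
            theta_hat = (
                params.step_angle
                if params.step_angle is not None
                else math.asin(params.d / (2 * params.l0))
            )
            t_half = math.pi * math.sqrt(params.l0 / params.g)
            phi_rate = params.swing_gain * (2 * theta_hat - new_state.phi) / t_half
            new_state = replace(new_state, theta_dot=rate, phi_dot=phi_rate)
        # world position of the new pivot: CoG minus l0 along the leading leg
        cog_world = pivot + np.array([to_state.x, to_state.y])
        u = np.array(
            [math.sin(new_state.theta), math.cos(new_state.theta)]
        )
        pivot = cog_world - params.l0 * u
        jumps.append(float(np.hypot(*(pivot + params.l0 * u - cog_world))))
        state = new_state

    traj_out = CoGTrajectory(
        np.concatenate(ts),
        np.concatenate(xs),
        np.concatenate(ys),
        np.concatenate(phases),
        events,
        support_y=np.concatenate(sups),
        boundary_jumps=jumps,
    )
    if np.any(np.diff(traj_out.t) <= 0):
        # defensive: drop any residual duplicate time stamps
        keep = np.concatenate([[True], np.diff(traj_out.t) > 0])
        traj_out = CoGTrajectory(
            traj_out.t[keep], traj_out.x[keep], traj_out.y[keep],
            traj_out.phase[keep], events,
            support_y=traj_out.support_y[keep],
            boundary_jumps=jumps,
        )
    traj_out._compute_percent()
    return traj_out


# ---------------------------------------------------------------- cycles

@dataclass
class NormalizedCycle:
    """CoG cycle resampled onto a uniform percent-of-cycle grid.

    ``x`` is relative to the cycle-start CoG position so that cycles are
    directly comparable; event positions are carried along in percent.
    """

    percent: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phase: np.ndarray
    events_percent: dict[str, float] = field(default_factory=dict)
    duration: float = 0.0

    def planar(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def to_csv(self, path_or_buf) -> None:
        import pandas as pd

        pd.DataFrame({"percent": self.percent, "x": self.x, "y": self.y}).to_csv(
            path_or_buf, index=False
        )

    @classmethod
    def from_csv(cls, path_or_buf) -> "NormalizedCycle":
        import pandas as pd

        df = pd.read_csv(path_or_buf)
        n = len(df)
        return cls(
            percent=df.percent.to_numpy(),
            x=df.x.to_numpy(),
            y=df.y.to_numpy(),
            phase=np.full(n, SINGLE, dtype=object),
        )


def normalize_to_cycle(
    traj: CoGTrajectory,
    n_points: int = 101,
    cycle: int | None = None,
    discard_first: bool = True,
) -> NormalizedCycle:
    """Resample one complete cycle onto a uniform 0-100% grid.

    By default the first (transient) cycle is discarded and the next one
    used.  Linear interpolation; ``x`` re-anchored at the cycle start.
    """
    n = traj.n_cycles()
    if n == 0:
        raise ValueError("no complete gait cycle in trajectory")
    if cycle is None:
        cycle = 1 if (discard_first and n > 1) else 0
    t0, t1 = traj.cycle_bounds(cycle)
    grid_t = np.linspace(t0, t1, n_points)
    x = np.interp(grid_t, traj.t, traj.x)
    # height above the current support surface -- the periodic quantity
    y = np.interp(grid_t, traj.t, traj.height_above_support())
    # phase label via nearest sample
    idx = np.searchsorted(traj.t, grid_t).clip(0, len(traj) - 1)
    phase = traj.phase[idx]
    percent = np.linspace(0.0, 100.0, n_points)
    return NormalizedCycle(
        percent=percent,
        x=x - x[0],
        y=y,
        phase=phase,
        events_percent=traj.event_percents(cycle),
        duration=t1 - t0,
    )
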