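"""Two-link inverse kinematics: hip and knee flexion-extension recovery.

The leg is a planar two-link chain hinged at the hip (taken at the CoG):
thigh and shank of equal length ``l0/2`` (the knee joint sits at the
mid-leg point).  For a heel target at distance ``c`` from the hip the
knee flexion follows the law of cosines,

    gamma = acos((c^2 - a^2 - b^2) / (2ab)),        a = b = l0/2,

with ``gamma = 0`` the fully extended knee, and the hip flexion is the
bearing of the hip-to-heel line plus the interior offset of the thigh,

    omega = atan2(dx, -dy) + atan2(b sin gamma, a + b cos gamma),

measured from the downward vertical, positive forward (flexion).  The
knee bends anatomically (knee ahead of the hip-heel line, heel behind
the thigh line); the elbow-up branch is fixed globally, not per sample.
A cyclic-coordinate-descent (CCD) solver provides the same answer
iteratively and is cross-checked against the closed form.

Angles are radians internally; CSV export uses degrees, flexion
positive, the clinical gait-plot convention.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CCDConvergenceError, UnreachableTargetError

__all__ = [
    "LegChain",
    "JointAngleSeries",
    "knee_angle",
    "hip_angle",
    "forward_kinematics",
    "ccd_solve",
    "fuse_trajectories",
]

log = logging.getLogger(__name__)


def _u(angle):
    """Unit vector at ``angle`` from vertical-down, positive forward (+x)."""
    return np.array([math.sin(angle), -math.cos(angle)])


@dataclass(frozen=True)
class LegChain:
    """Hip anchor, heel target and leg length for one IK solve."""

    hip: tuple[float, float]
    target: tuple[float, float]
    l0: float

    def __post_init__(self):
        if self.l0 <= 0:
            raise ValueError("l0 must be > 0")

    @property
    def segment(self) -> float:
        return self.l0 / 2.0

    def clamped_target(self) -> tuple[np.ndarray, bool]:
        """Target projected onto the reach disc if needed."""
        hip = np.asarray(self.hip, dtype=float)
        tgt = np.asarray(self.target, dtype=float)
        delta = tgt - hip
        c = float(np.hypot(*delta))
        if c <= self.l0 or c == 0.0:
            return tgt, False
        return hip + delta * (self.l0 / c), True


def knee_angle(hip, heel, l0: float) -> float:
    """Knee flexion (rad) in [0, pi]; 0 is the fully straight knee.

    Targets beyond reach are clamped onto the reach circle (gamma = 0).
    """
    a = b = l0 / 2.0
    c = min(float(np.hypot(heel[0] - hip[0], heel[1] - hip[1])), l0)
    cosg = (c**2 - a**2 - b**2) / (2.0 * a * b)
    return math.acos(min(1.0, max(-1.0, cosg)))


def hip_angle(hip, heel, gamma: float, l0: float) -> float:
    """Hip flexion (rad) from the downward vertical, positive forward."""
    a = b = l0 / 2.0
    dx, dy = heel[0] - hip[0], heel[1] - hip[1]
    psi = math.atan2(dx, -dy)
    return psi + math.atan2(b * math.sin(gamma), a + b * math.cos(gamma))


def forward_kinematics(hip, omega: float, gamma: float, l0: float):
    """Knee and heel positions for hip/knee flexion angles.

    The thigh points along ``omega`` and the shank along ``omega - gamma``
    (anatomical flexion bends the shank backward relative to the thigh).
    """
    hip = np.asarray(hip, dtype=float)
    knee = hip + (l0 / 2.0) * _u(omega)
    heel = knee + (l0 / 2.0) * _u(omega - gamma)
    return knee, heel


def ccd_solve(
    chain: LegChain,
    max_iter: int = 20000,
    tol: float = 1e-9,
    init: tuple[float, float] | None = None,
    return_trace: bool = False,
):
    """Cyclic coordinate descent for the two-link chain.

    Sweeps distal (knee) to proximal (hip), each sweep rotating one joint
    to point its distal chain at the target.  Initialized slightly flexed
    toward the anatomical branch unless ``init=(omega, gamma)`` is given.
    Returns ``(omega, gamma)``; raises :class:`CCDConvergenceError` if the
    end-effector error does not reach ``tol`` within ``max_iter`` sweeps.
    Convergence is linear with a rate approaching one near full
    extension, hence the generous default iteration budget; a target at
    (or clamped onto) the reach circle is answered with the straight-leg
    configuration directly, where coordinate descent cannot converge.
    """
    hip = np.asarray(chain.hip, dtype=float)
    tgt, clamped = chain.clamped_target()
    if clamped:
        log.debug("CCD target clamped onto reach circle")
    a = chain.segment
    dx, dy = tgt - hip
    if math.hypot(dx, dy) >= chain.l0 * (1.0 - 1e-12):
        omega = math.atan2(dx, -dy)
        if return_trace:
            return omega, 0.0, [0.0]
        return omega, 0.0
    if init is None:
        dx, dy = tgt - hip
        psi = math.atan2(dx, -dy)
        omega, sigma = psi + 0.05, psi - 0.05  # slight anatomical flexion
    else:
        omega, sigma = init[0], init[0] - init[1]

    err = np.inf
    trace = []
    for _ in range(max_iter):
        knee = hip + a * _u(omega)
        # knee joint: point the shank at the target
        v = tgt - knee
        if np.hypot(*v) > 0:
            sigma = math.atan2(v[0], -v[1])
        heel = knee + a * _u(sigma)
        # hip joint: rotate the whole chain about the hip
        ve, vt = heel - hip, tgt - hip
        dang = math.atan2(ve[0] * vt[1] - ve[1] * vt[0], float(ve @ vt))
        omega += dang
        sigma += dang
        knee = hip + a * _u(omega)
        heel = knee + a * _u(sigma)
        err = float(np.hypot(*(heel - tgt)))
        trace.append(err)
        if err < tol:
            if return_trace:
                return omega, omega - sigma, trace
            return omega, omega - sigma
    raise CCDConvergenceError(err, max_iter)


@dataclass
class JointAngleSeries:
    """Hip and knee flexion-extension trajectories for both legs (rad)."""

    percent: np.ndarray
    hip_r: np.ndarray
    knee_r: np.ndarray
    hip_l: np.ndarray
    knee_l: np.ndarray
    n_clamped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arrs = [self.percent, self.hip_r, self.knee_r, self.hip_l, self.knee_l]
        if len({np.asarray(a).size for a in arrs}) != 1:
            raise ValueError("angle series must share the percent grid")
        if not all(np.all(np.isfinite(a)) for a in arrs):
            raise ValueError("non-finite joint angles")

    def __len__(self):
        return np.asarray(self.percent).size

    def channels(self) -> dict[str, np.ndarray]:
        """Clinical channel naming, degrees."""
        return {
            "R.Hip": np.degrees(self.hip_r),
            "R.Knee": np.degrees(self.knee_r),
            "L.Hip": np.degrees(self.hip_l),
            "L.Knee": np.degrees(self.knee_l),
        }

    def to_csv(self, path_or_buf) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "percent": self.percent,
                "hip_R_deg": np.degrees(self.hip_r),
                "knee_R_deg": np.degrees(self.knee_r),
                "hip_L_deg": np.degrees(self.hip_l),
                "knee_L_deg": np.degrees(self.knee_l),
            }
        ).to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "JointAngleSeries":
        import pandas as pd

        df = pd.read_csv(path_or_buf)
        return cls(
            df.percent.to_numpy(),
            np.radians(df.hip_R_deg.to_numpy()),
            np.radians(df.knee_R_deg.to_numpy()),
            np.radians(df.hip_L_deg.to_numpy()),
            np.radians(df.knee_L_deg.to_numpy()),
        )

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def _heel_both_feet(mix, percent, step_length, dx_align=0.0):
    """Ipsilateral and contralateral heel positions on the common frame.

    The contralateral foot runs the same learned path shifted by half a
    cycle; its ground-frame x is offset by one step length (it is one
    step behind before mid-cycle and one ahead after).  ``dx_align``
    shifts both paths so the plant point matches the CoG contact
    geometry.
    """
    from .heel_paths import evaluate_heel_path

    p = np.asarray(percent, dtype=float)
    rx, ry = evaluate_heel_path(mix, p)
    pc = np.mod(p + 50.0, 100.0)
    lx, ly = evaluate_heel_path(mix, pc)
    lx = lx + np.where(p < 50.0, -step_length, step_length)
    return (rx + dx_align, ry), (lx + dx_align, ly)


def fuse_trajectories(
    cog,
    mix,
    l0: float,
    step_length: float | None = None,
    max_unreachable_frac: float = 0.25,
    use_ccd: bool = False,
) -> JointAngleSeries:
    """Fuse a normalized CoG cycle with a class heel path into joint angles.

    For every percent sample the hip is anchored at the CoG and the heel
    targets are read from the mixture (contralateral leg shifted by 50%
    of the cycle); the two-link IK then yields hip and knee flexion for
    both legs.  Unreachable targets are clamped onto the reach circle and
    counted (``n_clamped``); around foot contact a small systematic
    overshoot is expected, because the model plants the leading foot at
    the configured inter-foot distance while the leading spring is still
    slightly stretched.  Only targets beyond reach by more than 5% of
    the leg length count toward the consistency guard: if their fraction
    exceeds ``max_unreachable_frac``, the CoG cycle and the heel path do
    not belong together (wrong class or leg length) and
    :class:`UnreachableTargetError` is raised.
    """
    if step_length is None:
        from .fusion import PRESETS

        if mix.gait_class in PRESETS:
            step_length = PRESETS[mix.gait_class]["d"]
        else:
            raise ValueError("step_length required for custom gait classes")
    p = np.asarray(cog.percent, dtype=float)
    hips = np.column_stack([cog.x, cog.y])

    # anchor the heel path on the CoG geometry: at mid single stance the
    # hip vaults directly over the planted foot (the CoG height apex), so
    # the stance plateau of the heel path is aligned there; the class
    # plant offset then shifts the plant toward the body for flexed-limb
    # contact classes (e.g. crouch)
    from .heel_paths import class_plant_offset, evaluate_heel_path

    first_half = slice(0, p.size // 2 + 1)
    apex_x = float(np.asarray(cog.x)[first_half][np.argmax(np.asarray(cog.y)[first_half])])
    plateau = np.linspace(15.0, 45.0, 7)
    mx_plateau = float(np.mean(evaluate_heel_path(mix, plateau)[0]))
    dx_align = apex_x + class_plant_offset(mix.gait_class) - mx_plateau

    (rx, ry), (lx, ly) = _heel_both_feet(mix, p, step_length, dx_align=dx_align)

    out = {"hip_r": [], "knee_r": [], "hip_l": [], "knee_l": []}
    n_clamped = 0
    n_far = 0  # clamped by more than 5% of leg length
    for i in range(p.size):
        hip = hips[i]
        for side, hx, hy in (("r", rx[i], ry[i]), ("l", lx[i], ly[i])):
            chain = LegChain(tuple(hip), (hx, hy), l0)
            tgt, clamped = chain.clamped_target()
            n_clamped += clamped
            if clamped:
                c = math.hypot(hx - hip[0], hy - hip[1])
                n_far += (c - l0) / l0 > 0.05
            if use_ccd:
                omega, gamma = ccd_solve(chain, tol=1e-9)
            else:
                gamma = knee_angle(hip, tgt, l0)
                omega = hip_angle(hip, tgt, gamma, l0)
            out[f"hip_{side}"].append(omega)
            out[f"knee_{side}"].append(gamma)

    if n_far > max_unreachable_frac * 2 * p.size:
        raise UnreachableTargetError(
            f"{n_far} of {2 * p.size} heel targets lie well outside leg reach"
        )
    if n_clamped:
        log.info("clamped %d of %d heel targets onto the reach circle",
                 n_clamped, 2 * p.size)
    return JointAngleSeries(
        p,
        np.array(out["hip_r"]),
        np.array(out["knee_r"]),
        np.array(out["hip_l"]),
        np.array(out["knee_l"]),
        n_clamped=n_clamped,
        meta={"l0": l0, "step_length": step_length},
    )
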