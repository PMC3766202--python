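"""Sagittal 12-segment stick figure animated from simulated trajectories.

The figure comprises pelvis, trunk, and per side thigh, shank, foot,
upper arm and forearm (12 rigid segments).  Lower limbs are placed by
forward kinematics from the pelvis (anchored at the CoG) using the hip
and knee flexion angles; the upper body follows smooth parametric
arm-swing templates (synthetic fixtures, not patient data: arms swing in
anti-phase with the ipsilateral leg, elbows slightly flexed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ik import forward_kinematics, _u

__all__ = [
    "SkeletonPose",
    "SEGMENT_NAMES",
    "arm_swing_template",
    "build_pose",
    "build_pose_sequence",
    "export_animation",
    "load_animation",
]

SEGMENT_NAMES = (
    "pelvis",
    "trunk",
    "thigh_r",
    "shank_r",
    "foot_r",
    "thigh_l",
    "shank_l",
    "foot_l",
    "upper_arm_r",
    "forearm_r",
    "upper_arm_l",
    "forearm_l",
)

# segment lengths as fractions of leg length l0
_FRACTIONS = dict(
    pelvis=0.16, trunk=0.45, foot=0.15, upper_arm=0.28, forearm=0.25
)


@dataclass
class SkeletonPose:
    """12 rigid segments, each (proximal, distal) in sagittal-plane metres."""

    segments: dict[str, tuple[tuple[float, float], tuple[float, float]]]
    percent: float = 0.0

    def __post_init__(self):
        if set(self.segments) != set(SEGMENT_NAMES):
            raise ValueError(
                f"expected exactly the 12 segments {SEGMENT_NAMES}, "
                f"got {sorted(self.segments)}"
            )

    def lengths(self) -> dict[str, float]:
        return {
            name: float(np.hypot(d[0] - p[0], d[1] - p[1]))
            for name, (p, d) in self.segments.items()
        }


def arm_swing_template(percent, amplitude: float = 0.25, elbow_flexion: float = 0.35):
    """Synthetic arm-swing fixture curves (shoulder and elbow angles, rad).

    Smooth parametric templates standing in for the study's upper-limb
    recordings: the right arm swings in anti-phase with the right leg
    (peak forward swing near contralateral heel strike), amplitude
    ``amplitude`` rad about the vertical, with constant elbow flexion.
    Returns (shoulder_r, elbow_r, shoulder_l, elbow_l).
    """
    p = np.asarray(percent, dtype=float)
    phase = 2.0 * np.pi * p / 100.0
    shoulder_r = -amplitude * np.cos(phase)
    shoulder_l = amplitude * np.cos(phase)
    elbow_r = np.full_like(p, elbow_flexion)
    elbow_l = np.full_like(p, elbow_flexion)
    return shoulder_r, elbow_r, shoulder_l, elbow_l


def build_pose(
    cog,
    hip_r: float,
    knee_r: float,
    hip_l: float,
    knee_l: float,
    l0: float,
    percent: float = 0.0,
    upper_limbs: tuple[float, float, float, float] | None = None,
) -> SkeletonPose:
    """Assemble the 12-segment pose for one frame.

    ``cog`` is the pelvis anchor (hip joint in the sagittal projection);
    angles are flexion values in radians.  ``upper_limbs`` supplies
    (shoulder_r, elbow_r, shoulder_l, elbow_l); by default the arm-swing
    template at ``percent`` is used.
    """
    cog = np.asarray(cog, dtype=float)
    if upper_limbs is None:
        sr, er, sl, el = (float(v) for v in arm_swing_template(percent))
    else:
        sr, er, sl, el = upper_limbs

    half_pelvis = _FRACTIONS["pelvis"] * l0 / 2.0
    pelvis = (cog - [half_pelvis, 0.0], cog + [half_pelvis, 0.0])
    trunk_top = cog + [0.0, _FRACTIONS["trunk"] * l0]
    trunk = (cog, trunk_top)

    segs = {"pelvis": tuple(map(tuple, pelvis)), "trunk": (tuple(cog), tuple(trunk_top))}

    for side, hip_a, knee_a in (("r", hip_r, knee_r), ("l", hip_l, knee_l)):
        knee, heel = forward_kinematics(cog, hip_a, knee_a, l0)
        segs[f"thigh_{side}"] = (tuple(cog), tuple(knee))
        segs[f"shank_{side}"] = (tuple(knee), tuple(heel))
        toe = heel + [_FRACTIONS["foot"] * l0, 0.0]
        segs[f"foot_{side}"] = (tuple(heel), tuple(toe))

    for side, sh_a, el_a in (("r", sr, er), ("l", sl, el)):
        ua = _FRACTIONS["upper_arm"] * l0
        fa = _FRACTIONS["forearm"] * l0
        elbow = trunk_top + ua * _u(sh_a)
        wrist = elbow + fa * _u(sh_a + el_a)
        segs[f"upper_arm_{side}"] = (tuple(trunk_top), tuple(elbow))
        segs[f"forearm_{side}"] = (tuple(elbow), tuple(wrist))

    return SkeletonPose(segs, percent=float(percent))


def build_pose_sequence(cog_cycle, angles, l0: float) -> list[SkeletonPose]:
    """Poses for every sample of a normalized cycle + joint-angle series."""
    if len(cog_cycle.percent) != len(angles):
        raise ValueError("CoG cycle and angle series use different grids")
    poses = []
    for i, p in enumerate(np.asarray(cog_cycle.percent, dtype=float)):
        poses.append(
            build_pose(
                (cog_cycle.x[i], cog_cycle.y[i]),
                angles.hip_r[i],
                angles.knee_r[i],
                angles.hip_l[i],
                angles.knee_l[i],
                l0,
                percent=p,
            )
        )
    return poses


def export_animation(poses, path, fmt: str = "csv") -> None:
    """Write a pose sequence as long-form CSV or an animated/plot file.

    CSV schema: ``frame,segment,prox_x,prox_y,dist_x,dist_y`` (lossless
    round trip via :func:`load_animation`).  ``fmt="png"`` draws every
    5th frame overlaid; ``fmt="gif"`` writes an animation.
    """
    poses = list(poses)
    if not poses:
        raise ValueError("need at least one pose")
    if fmt == "csv":
        import pandas as pd

        rows = []
        for f, pose in enumerate(poses):
            for name in SEGMENT_NAMES:
                (px, py), (dx, dy) = pose.segments[name]
                rows.append(
                    (f, name, repr(float(px)), repr(float(py)),
                     repr(float(dx)), repr(float(dy)))
                )
        pd.DataFrame(
            rows, columns=["frame", "segment", "prox_x", "prox_y", "dist_x", "dist_y"]
        ).to_csv(path, index=False)
        return
    if fmt in ("png", "gif"):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if fmt == "png":
            fig, ax = plt.subplots(figsize=(8, 4))
            for pose in poses[::5]:
                for (p, d) in pose.segments.values():
                    ax.plot([p[0], d[0]], [p[1], d[1]], "k-", lw=1, alpha=0.5)
            ax.set_aspect("equal")
            ax.set_xlabel("x (m)")
            ax.set_ylabel("y (m)")
            fig.savefig(path, dpi=100)
            plt.close(fig)
            return
        from matplotlib.animation import FuncAnimation, PillowWriter

        fig, ax = plt.subplots(figsize=(5, 5))
        lines = [ax.plot([], [], "k-", lw=2)[0] for _ in SEGMENT_NAMES]
        allpts = np.array(
            [pt for pose in poses for seg in pose.segments.values() for pt in seg]
        )
        ax.set_xlim(allpts[:, 0].min() - 0.2, allpts[:, 0].max() + 0.2)
        ax.set_ylim(allpts[:, 1].min() - 0.1, allpts[:, 1].max() + 0.1)
        ax.set_aspect("equal")

        def update(i):
            for line, name in zip(lines, SEGMENT_NAMES):
                (p, d) = poses[i].segments[name]
                line.set_data([p[0], d[0]], [p[1], d[1]])
            return lines

        anim = FuncAnimation(fig, update, frames=len(poses), blit=True)
        anim.save(path, writer=PillowWriter(fps=20))
        plt.close(fig)
        return
    raise ValueError(f"unknown format {fmt!r}")


def load_animation(path) -> list[SkeletonPose]:
    """Read back a long-form pose CSV written by :func:`export_animation`."""
    import pandas as pd

    df = pd.read_csv(
        path,
        dtype={"prox_x": float, "prox_y": float, "dist_x": float, "dist_y": float},
        float_precision="round_trip",
    )
    poses = []
    for f, sub in df.groupby("frame"):
        segs = {
            r.segment: ((r.prox_x, r.prox_y), (r.dist_x, r.dist_y))
            for r in sub.itertuples()
        }
        poses.append(SkeletonPose(segs, percent=float(f)))
    return poses
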