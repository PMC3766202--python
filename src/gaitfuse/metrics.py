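"""Trajectory-similarity measures for gait curves.

Two measures drive the evaluation of simulated against reference gait
patterns: the Pearson correlation coefficient between equally sampled
series, and the discrete Frechet distance between curves -- the minimal,
over all monotone couplings of the two point sequences, of the largest
coupled point-pair distance (the "dog-leash" distance).  The Hausdorff
distance is included for contrast: two curves can lie close as point
sets (small Hausdorff) yet require a large leash when traversed in order
(large Frechet), which is why the Frechet measure is preferred for
temporal trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import directed_hausdorff

__all__ = [
    "MetricsReport",
    "correlation_coefficient",
    "frechet_distance",
    "hausdorff_distance",
    "compare",
]

CHANNELS = ("R.Hip", "R.Knee", "L.Hip", "L.Knee", "CoG")


def correlation_coefficient(a, b) -> float:
    """Pearson product-moment correlation of two equal-length series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("series must be 1-D, equal length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance input")
    return float(np.corrcoef(a, b)[0, 1])


def _as_curve(P) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValueError("curve must be a non-empty (n, d) point sequence")
    return P


def frechet_distance(P, Q) -> float:
    """Discrete Frechet distance (Euclidean ground metric).

    Dynamic programming over the coupling lattice: the coupling measure
    at (i, j) is the larger of d(P_i, Q_j) and the best measure over the
    three monotone predecessors.  Symmetric in its arguments.
    """
    P, Q = _as_curve(P), _as_curve(Q)
    if P.shape[1] != Q.shape[1]:
        raise ValueError("curves must share the embedding dimension")
    d = np.sqrt(((P[:, None, :] - Q[None, :, :]) ** 2).sum(axis=2))
    n, m = d.shape
    ca = np.empty_like(d)
    ca[0, 0] = d[0, 0]
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        row_prev, row = ca[i - 1], ca[i]
        for j in range(1, m):
            row[j] = max(min(row_prev[j], row_prev[j - 1], row[j - 1]), d[i, j])
    return float(ca[-1, -1])


def hausdorff_distance(P, Q) -> float:
    """Symmetric Hausdorff distance between two point sets."""
    P, Q = _as_curve(P), _as_curve(Q)
    if P.shape[1] != Q.shape[1]:
        raise ValueError("curves must share the embedding dimension")
    return max(directed_hausdorff(P, Q)[0], directed_hausdorff(Q, P)[0])


@dataclass
class MetricsReport:
    """Per-channel similarity summary in the evaluation-table layout."""

    correlation: dict[str, float]
    frechet: dict[str, float]
    hausdorff: dict[str, float]
    n_points: int = 0
    channels: tuple = CHANNELS

    def to_json(self, path_or_buf=None) -> str | None:
        d = {
            "channels": list(self.channels),
            "n_points": self.n_points,
            "correlation": self.correlation,
            "frechet": self.frechet,
            "hausdorff": self.hausdorff,
        }
        s = json.dumps(d, indent=2)
        if path_or_buf is None:
            return s
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(s)
        else:
            with open(path_or_buf, "w", encoding="utf-8") as fh:
                fh.write(s)
        return None

    def table(self) -> str:
        """Rows laid out like the evaluation tables: one row per metric."""
        cols = list(self.channels)
        lines = ["Metric\t" + "\t".join(cols)]
        lines.append(
            "Correlation factor\t"
            + "\t".join(f"{self.correlation[c]:.4f}" for c in cols)
        )
        lines.append(
            "Frechet distance\t" + "\t".join(f"{self.frechet[c]:.4f}" for c in cols)
        )
        return "\n".join(lines)


def _angle_curve(percent, values, mode: str):
    """Embed an angle-vs-percent series for the curve metrics.

    ``planar``: percent rescaled to the series' value range so both axes
    carry comparable weight; ``values``: 1-D value sequence only.
    """
    v = np.asarray(values, dtype=float)
    if mode == "values":
        return v[:, None]
    p = np.asarray(percent, dtype=float)
    span = np.ptp(v)
    scale = span / np.ptp(p) if np.ptp(p) > 0 and span > 0 else 1.0
    return np.column_stack([p * scale, v])


def compare(
    angles_sim,
    cog_sim,
    angles_ref,
    cog_ref,
    frechet_mode: str = "planar",
) -> MetricsReport:
    """Per-channel correlation and Frechet distance of two gait patterns.

    The four joint channels are compared as angle-vs-percent curves (the
    percent axis rescaled into the angle range for the curve metrics, or
    ``frechet_mode="values"`` for 1-D comparison); the CoG is compared as
    the planar (x, y) curve, its correlation the mean of the per-axis
    correlations.
    """
    pa = np.asarray(angles_sim.percent, dtype=float)
    if pa.size != np.asarray(angles_ref.percent).size:
        raise ValueError("simulated and reference series use different grids")
    if len(cog_sim.percent) != len(cog_ref.percent):
        raise ValueError("simulated and reference CoG use different grids")

    ch_sim = angles_sim.channels()
    ch_ref = angles_ref.channels()
    corr, fre, hau = {}, {}, {}
    for name in ("R.Hip", "R.Knee", "L.Hip", "L.Knee"):
        a, b = ch_sim[name], ch_ref[name]
        corr[name] = correlation_coefficient(a, b)
        ca = _angle_curve(pa, a, frechet_mode)
        cb = _angle_curve(pa, b, frechet_mode)
        fre[name] = frechet_distance(ca, cb)
        hau[name] = hausdorff_distance(ca, cb)

    xs, ys = np.asarray(cog_sim.x), np.asarray(cog_sim.y)
    xr, yr = np.asarray(cog_ref.x), np.asarray(cog_ref.y)
    corr["CoG"] = 0.5 * (
        correlation_coefficient(xs, xr) + correlation_coefficient(ys, yr)
    )
    Ps, Pr = np.column_stack([xs, ys]), np.column_stack([xr, yr])
    fre["CoG"] = frechet_distance(Ps, Pr)
    hau["CoG"] = hausdorff_distance(Ps, Pr)

    return MetricsReport(corr, fre, hau, n_points=pa.size)
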