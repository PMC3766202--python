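"""Heel-trajectory models: Gaussian-basis mixtures and synthetic corpora.

A learned heel path is represented per coordinate as a weighted sum of
Gaussian densities over the normalized gait cycle,

    psi(t) = c + sum_i  w_i * N(t | mu_i, sigma_i^2),       t in [0, 100] %

with signed weights (the mixture models a coordinate trajectory, not a
probability density) and an intercept ``c`` for the nonzero baseline.
Fitting places the means on a uniform grid with a shared width tied to the
grid spacing (radial-basis regression, weights by linear least squares);
an optional nonlinear refinement of ``(w, mu, sigma)`` is available for
small component counts.

Because the underlying patient recordings are not public, the module also
generates synthetic per-class heel corpora that emulate their structure:
a stance plateau (foot planted), a swing advance of one stride with a
clearance arc, class-specific distortions (crouch: reduced clearance and
a persistent backward shift of the plant point relative to the body;
Parkinsonian: short steps tied to the preset ``d`` and a shuffling, low
clearance), smooth within-cycle noise and subject-level offsets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import IllConditionedBasisError

__all__ = [
    "HeelPathMixture",
    "HeelCycleSet",
    "fit_heel_mixture",
    "evaluate_heel_path",
    "sample_heel_variation",
    "generate_synthetic_heel_data",
]

PERCENT_GRID = np.linspace(0.0, 100.0, 101)

#: per-class shape parameters of the synthetic generator.  ``lift`` is
#: the peak heel height of the heel-off/swing hump (the heel leaves the
#: ground in late stance, rises as the knee folds through swing and
#: drops to the next contact); ``plant_offset`` pulls the plant toward
#: the body for flexed-limb contact classes; ``baseline`` is a
#: persistent heel elevation during stance (toe-walking, the crouch /
#: equinus signature -- the heel never reaches the ground, so the limb
#: stays flexed throughout the cycle).
_CLASS_SHAPES = {
    "normal": dict(lift=0.24, plant_offset=0.0, baseline=0.0),
    "crouch": dict(lift=0.28, plant_offset=-0.10, baseline=0.06),
    "parkinson": dict(lift=0.22, plant_offset=-0.04, baseline=0.0),
    "parkinson_stage2": dict(lift=0.26, plant_offset=-0.06, baseline=0.0),
    "parkinson_stage3": dict(lift=0.20, plant_offset=-0.04, baseline=0.0),
    "parkinson_stage4": dict(lift=0.16, plant_offset=-0.04, baseline=0.0),
    "custom": dict(lift=0.24, plant_offset=0.0, baseline=0.0),
}


def class_plant_offset(gait_class: str) -> float:
    """Forward offset of the heel plant relative to the fully extended
    contact point (m); negative values pull the plant toward the body
    (flexed-limb contact, e.g. crouch)."""
    return _CLASS_SHAPES.get(gait_class, _CLASS_SHAPES["custom"])["plant_offset"]


def _gauss(t, mu, var):
    return np.exp(-0.5 * (t - mu) ** 2 / var) / np.sqrt(2.0 * np.pi * var)


@dataclass
class HeelPathMixture:
    """Per-coordinate Gaussian-basis representation of a heel path.

    ``weights_*`` are signed basis coefficients in metres; ``means_*`` in
    percent of cycle; ``vars_*`` in (percent)^2.  ``intercept_*`` is the
    constant term.
    """

    gait_class: str
    weights_x: np.ndarray
    means_x: np.ndarray
    vars_x: np.ndarray
    weights_y: np.ndarray
    means_y: np.ndarray
    vars_y: np.ndarray
    intercept_x: float = 0.0
    intercept_y: float = 0.0
    residual: float = 0.0

    def __post_init__(self):
        for name in ("x", "y"):
            w = np.asarray(getattr(self, f"weights_{name}"), dtype=float)
            m = np.asarray(getattr(self, f"means_{name}"), dtype=float)
            v = np.asarray(getattr(self, f"vars_{name}"), dtype=float)
            if w.size < 1 or w.shape != m.shape or w.shape != v.shape:
                raise ValueError("mixture components malformed")
            if np.any(v <= 0):
                raise ValueError("variances must be > 0")
            setattr(self, f"weights_{name}", w)
            setattr(self, f"means_{name}", m)
            setattr(self, f"vars_{name}", v)

    @property
    def n_components(self) -> int:
        return self.weights_x.size

    def __call__(self, percent):
        return evaluate_heel_path(self, percent)

    # ---- JSON serialization ----------------------------------------
    def to_json(self, path_or_buf=None) -> str | None:
        d = {
            "gait_class": self.gait_class,
            "residual": self.residual,
        }
        for c in ("x", "y"):
            d[c] = {
                "weights": list(getattr(self, f"weights_{c}")),
                "means": list(getattr(self, f"means_{c}")),
                "vars": list(getattr(self, f"vars_{c}")),
                "intercept": getattr(self, f"intercept_{c}"),
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

    @classmethod
    def from_json(cls, path_or_buf) -> "HeelPathMixture":
        if hasattr(path_or_buf, "read"):
            d = json.load(path_or_buf)
        elif isinstance(path_or_buf, str) and path_or_buf.lstrip().startswith("{"):
            d = json.loads(path_or_buf)
        else:
            with open(path_or_buf, encoding="utf-8") as fh:
                d = json.load(fh)
        kw = dict(gait_class=d["gait_class"], residual=d.get("residual", 0.0))
        for c in ("x", "y"):
            kw[f"weights_{c}"] = np.array(d[c]["weights"])
            kw[f"means_{c}"] = np.array(d[c]["means"])
            kw[f"vars_{c}"] = np.array(d[c]["vars"])
            kw[f"intercept_{c}"] = d[c].get("intercept", 0.0)
        return cls(**kw)


@dataclass
class HeelCycleSet:
    """Collection of per-cycle heel trajectories on a shared percent grid.

    ``x``/``y`` have shape (n_cycles, n_samples); ``x`` is measured from
    the CoG position at the cycle start (body-anchored ground frame), so
    a cycle advances by one stride (two step lengths).
    """

    percent: np.ndarray
    x: np.ndarray
    y: np.ndarray
    subjects: np.ndarray
    gait_class: str

    def __post_init__(self):
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.shape[0] < 1:
            raise ValueError("x/y cycle arrays malformed")
        if self.x.shape[1] != np.asarray(self.percent).size:
            raise ValueError("cycles do not share the percent grid")

    @property
    def n_cycles(self) -> int:
        return self.x.shape[0]

    def mean_path(self) -> tuple[np.ndarray, np.ndarray]:
        return self.x.mean(axis=0), self.y.mean(axis=0)

    def step_length(self) -> float:
        """Mean forward displacement per cycle divided by two (m)."""
        return float(np.mean(self.x[:, -1] - self.x[:, 0])) / 2.0

    # ---- CSV round trip --------------------------------------------
    def to_csv(self, path_or_buf) -> None:
        import pandas as pd

        rows = []
        for i in range(self.n_cycles):
            rows.append(
                pd.DataFrame(
                    {
                        "subject": self.subjects[i],
                        "cycle": i,
                        "percent": self.percent,
                        "heel_x": self.x[i],
                        "heel_y": self.y[i],
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, gait_class: str = "custom") -> "HeelCycleSet":
        import pandas as pd

        df = pd.read_csv(path_or_buf)
        cycles = sorted(df.cycle.unique())
        percent = np.array(sorted(df.percent.unique()))
        xs, ys, subs = [], [], []
        for c in cycles:
            sub = df[df.cycle == c].sort_values("percent")
            xs.append(sub.heel_x.to_numpy())
            ys.append(sub.heel_y.to_numpy())
            subs.append(sub.subject.iloc[0])
        return cls(percent, np.array(xs), np.array(ys), np.array(subs), gait_class)


def evaluate_heel_path(mix: HeelPathMixture, percent):
    """Evaluate the mixture at ``percent`` (scalar or array) -> (x, y) in m."""
    t = np.atleast_1d(np.asarray(percent, dtype=float))
    x = mix.intercept_x + np.sum(
        mix.weights_x[:, None] * _gauss(t[None, :], mix.means_x[:, None], mix.vars_x[:, None]),
        axis=0,
    )
    y = mix.intercept_y + np.sum(
        mix.weights_y[:, None] * _gauss(t[None, :], mix.means_y[:, None], mix.vars_y[:, None]),
        axis=0,
    )
    if np.isscalar(percent) or np.asarray(percent).ndim == 0:
        return float(x[0]), float(y[0])
    return x, y


def _design_matrix(t, means, var, intercept=True):
    cols = [_gauss(t[:, None], means[None, :], var)]
    if intercept:
        cols.insert(0, np.ones((t.size, 1)))
    return np.hstack(cols)


def fit_heel_mixture(
    data: HeelCycleSet,
    n_components: int = 12,
    refine: bool = False,
    cond_limit: float = 1e10,
) -> HeelPathMixture:
    """Least-squares fit of the Gaussian-basis mixture to the mean path.

    Means are fixed on a uniform grid over [0, 100] with shared variance
    set by the grid spacing; weights (and the intercept) are solved by
    linear least squares.  With ``refine=True`` the component parameters
    ``(w, mu, log sigma)`` and intercept are then polished by nonlinear
    least squares -- required for exact recovery of a generating mixture.

    Raises :class:`IllConditionedBasisError` when the basis is too
    collinear to solve reliably.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    t = np.asarray(data.percent, dtype=float)
    mx, my = data.mean_path()

    if n_components == 1:
        means = np.array([50.0])
        spacing = 50.0
    else:
        means = np.linspace(0.0, 100.0, n_components)
        spacing = means[1] - means[0]
    var = spacing**2

    A = _design_matrix(t, means, var)
    cond = np.linalg.cond(A)
    if cond > cond_limit:
        raise IllConditionedBasisError(
            f"Gaussian basis condition number {cond:.2e} exceeds {cond_limit:.0e} "
            f"(I={n_components}, sigma={math.sqrt(var):.2f}%)"
        )
    coef_x, *_ = np.linalg.lstsq(A, mx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(A, my, rcond=None)

    out = dict(
        gait_class=data.gait_class,
        intercept_x=float(coef_x[0]),
        weights_x=coef_x[1:],
        means_x=means.copy(),
        vars_x=np.full(n_components, var),
        intercept_y=float(coef_y[0]),
        weights_y=coef_y[1:],
        means_y=means.copy(),
        vars_y=np.full(n_components, var),
    )

    if refine:
        from scipy.optimize import least_squares

        for c, target in (("x", mx), ("y", my)):
            w0 = out[f"weights_{c}"]
            m0 = out[f"means_{c}"]
            v0 = out[f"vars_{c}"]
            p0 = np.concatenate([[out[f"intercept_{c}"]], w0, m0, 0.5 * np.log(v0)])

            def resid(p, target=target):
                c0 = p[0]
                w = p[1 : 1 + n_components]
                mu = p[1 + n_components : 1 + 2 * n_components]
                sig = np.exp(p[1 + 2 * n_components :])
                model = c0 + np.sum(
                    w[:, None] * _gauss(t[None, :], mu[:, None], (sig**2)[:, None]),
                    axis=0,
                )
                return model - target

            sol = least_squares(resid, p0, method="lm", xtol=1e-15, ftol=1e-15)
            p = sol.x
            out[f"intercept_{c}"] = float(p[0])
            out[f"weights_{c}"] = p[1 : 1 + n_components]
            out[f"means_{c}"] = p[1 + n_components : 1 + 2 * n_components]
            out[f"vars_{c}"] = np.exp(2 * p[1 + 2 * n_components :])

    mix = HeelPathMixture(**out)
    fx, fy = evaluate_heel_path(mix, t)
    mix.residual = float(
        np.sqrt(np.mean((fx - mx) ** 2 + (fy - my) ** 2))
    )
    return mix


def sample_heel_variation(
    mix: HeelPathMixture, seed: int, scale: float, percent=None
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic-in-seed perturbed heel path on the percent grid.

    Component weights (and intercepts) are jittered with relative
    standard deviation ``scale``; ``scale=0`` returns the mean path.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    t = PERCENT_GRID if percent is None else np.asarray(percent, dtype=float)
    if scale == 0.0:
        return evaluate_heel_path(mix, t)
    rng = np.random.default_rng(seed)
    jittered = HeelPathMixture(
        gait_class=mix.gait_class,
        weights_x=mix.weights_x * (1.0 + scale * rng.standard_normal(mix.n_components)),
        means_x=mix.means_x.copy(),
        vars_x=mix.vars_x.copy(),
        weights_y=mix.weights_y * (1.0 + scale * rng.standard_normal(mix.n_components)),
        means_y=mix.means_y.copy(),
        vars_y=mix.vars_y.copy(),
        intercept_x=mix.intercept_x,
        intercept_y=mix.intercept_y,
    )
    return evaluate_heel_path(jittered, t)


def _smoothstep(u):
    """Quintic minimum-jerk ramp 0->1 with zero end velocity/acceleration."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def nominal_heel_path(
    gait_class: str,
    step_length: float,
    percent=None,
    stance_fraction: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free template heel path of one foot over its own cycle.

    Frame: ``x`` relative to the CoG position at the cycle start (the
    foot has just struck, a half step ahead of the body); the cycle
    advances the foot by one stride (two step lengths).  ``y`` is height
    above ground: zero during stance apart from a pre-swing heel rise,
    with a clearance arc during swing.
    """
    t = PERCENT_GRID if percent is None else np.asarray(percent, dtype=float)
    shape = _CLASS_SHAPES.get(gait_class, _CLASS_SHAPES["custom"])
    s = step_length
    x0 = s / 2.0 + shape["plant_offset"]
    swing = (t / 100.0 - stance_fraction) / (1.0 - stance_fraction)
    x = x0 + 2.0 * s * _smoothstep(swing)
    # flat plant, then one smooth heel-off/swing hump: the heel leaves
    # the ground well before toe-off (the hip travels far past the
    # plant), is already high at swing onset, peaks near two-thirds of
    # the hump and returns to ground at the next contact
    lift_start = stance_fraction - 0.22
    v = np.clip((t / 100.0 - lift_start) / (1.0 - lift_start), 0.0, 1.0)
    y = shape["baseline"] + shape["lift"] * np.sin(np.pi * v**0.85) ** 1.2
    return x, y


def generate_synthetic_heel_data(
    gait_class: str,
    n_subjects: int = 10,
    n_cycles: int = 30,
    seed: int = 0,
    step_length: float | None = None,
    params=None,
    noise_x: float = 0.008,
    noise_y: float = 0.003,
) -> HeelCycleSet:
    """Synthetic per-class heel corpus emulating a small gait-lab study.

    ``n_cycles`` is the corpus total, distributed evenly over the
    subjects (default 10 subjects x 3 cycles = 30 cycles).  Step length
    defaults to the class preset's inter-foot distance ``d``.  Noise is
    smooth within each cycle (low-order sinusoids vanishing at the cycle
    endpoints so displacement per cycle is exactly one stride) plus
    subject-level plant offsets; deterministic in ``seed``.
    """
    if n_subjects < 1 or n_cycles < 1:
        raise ValueError("n_subjects and n_cycles must be >= 1")
    if step_length is None:
        if params is not None:
            step_length = params.d
        else:
            from .fusion import PRESETS

            step_length = PRESETS.get(gait_class, {"d": 0.5})["d"]

    rng = np.random.default_rng(seed)
    t = PERCENT_GRID
    base_x, base_y = nominal_heel_path(gait_class, step_length)

    per_subject = [n_cycles // n_subjects] * n_subjects
    for i in range(n_cycles - sum(per_subject)):
        per_subject[i] += 1

    xs, ys, subs = [], [], []
    u = t / 100.0
    for s_id, n_c in enumerate(per_subject):
        sub_dx = rng.normal(0.0, 0.01)
        sub_dy = rng.normal(0.0, 0.002)
        for _ in range(n_c):
            # smooth noise, zero at both cycle endpoints
            nx = np.zeros_like(t)
            ny = np.zeros_like(t)
            for h in (1, 2, 3):
                nx += rng.normal(0.0, noise_x / h) * np.sin(np.pi * h * u)
                ny += rng.normal(0.0, noise_y / h) * np.sin(np.pi * h * u)
            xs.append(base_x + sub_dx + nx)
            ys.append(np.maximum(base_y + sub_dy + ny, 0.0))
            subs.append(s_id)
    return HeelCycleSet(t, np.array(xs), np.array(ys), np.array(subs), gait_class)
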