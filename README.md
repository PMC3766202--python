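# gaitfuse

A sagittal-plane simulator of normal and pathological human walking that
fuses two information sources: a physics-based centre-of-gravity (CoG)
trajectory and learned heel paths, from which hip and knee
flexion–extension curves are recovered by two-link inverse kinematics.
It is aimed at gait researchers and clinician-scientists who want a
small, fully inspectable model that reproduces the coarse structure of
clinical gait curves — including crouch gait (spastic diplegia) and
Parkinsonian gait at disease stages 2–4 — without a gait laboratory.

## The model

One gait cycle (ipsilateral heel strike to ipsilateral heel strike) is a
hybrid dynamical system with two regimes:

* **Single stance** — a compass pendulum: hip point mass *M* on a rigid
  stance leg of length *l₀*, swing leg with foot mass *m = βM*.  With
  stance angle *θ* and inter-leg angle *φ* (both measured from the slope
  normal), the equations of motion follow from the Lagrangian; each
  evaluation solves the 2×2 mass-matrix system

  ```
  [1+2β(1−cos φ)   −β(1−cos φ)] [θ̈]   [ β sin φ (φ̇² − 2θ̇φ̇) + (g/l₀)((1+β) sin(θ+γ) − β sin(θ−φ+γ)) ]
  [ −β(1−cos φ)         β     ] [φ̈] = [ β θ̇² sin φ + (g/l₀) β sin(θ−φ+γ) ]
  ```

  The phase ends at heel strike, the root of **φ − 2θ = 0** (legs
  symmetric about the slope normal).

* **Double stance** — a planar two-leg spring-mass system: the CoG at
  (x, y) is held by two linear leg springs of stiffness *k* and rest
  length *l₀* anchored at the trailing contact (origin) and the leading
  contact (d, 0):

  ```
  M ẍ = ll·x − lr·(d−x),    M ÿ = (ll + lr)·y − Mg,
  ll = k (l₀/√(x²+y²) − 1),  lr = k (l₀/√((d−x)²+y²) − 1)
  ```

  The phase ends at toe-off, when the trailing spring returns to rest
  length.  Per-leg stiffness can differ to emulate asymmetric disorders.

Hand-offs between regimes preserve the CoG position exactly; at each
toe-off a steady-gait regulation re-launches the step (active
step-to-step control — the raw passive hybrid has no stable walking
cycle; see `docs/methods.md`).

Heel trajectories are modelled per gait class as Gaussian-basis mixtures
over the normalized cycle, ψ(t) = c + Σᵢ wᵢ N(t | μᵢ, σᵢ²), fitted by
radial-basis least squares to per-cycle corpora (a synthetic gait-lab
corpus generator is included: 10 subjects × 3 cycles by default).  The
fusion step anchors the class heel path on the CoG geometry and solves,
per percent sample and per leg, the two-link inverse kinematics with
thigh = shank = l₀/2:

```
γ = acos((c² − a² − b²) / 2ab)            (knee flexion, law of cosines)
ω = atan2(Δx, −Δy) + atan2(b sin γ, a + b cos γ)   (hip flexion)
```

with a cyclic-coordinate-descent (CCD) solver as an iterative
alternative.  Similarity of gait patterns is quantified per channel
(R.Hip, R.Knee, L.Hip, L.Knee, CoG) by the Pearson correlation
coefficient and the discrete Fréchet distance (plus Hausdorff for
contrast).

## Worked example

```python
import numpy as np
from gaitfuse.fusion import preset_params, simulate_gait, normalize_to_cycle
from gaitfuse.heel_paths import generate_synthetic_heel_data, fit_heel_mixture
from gaitfuse.ik import fuse_trajectories

params = preset_params("normal")
traj = simulate_gait(params, n_cycles=2)
print(f"double-stance fraction: {traj.double_stance_fraction(1):.2f} %")
ev = traj.event_percents(1)
print(f"contralateral heel strike at {ev['contralateral_heel_strike']:.2f} % "
      f"/ toe-off at {ev['contralateral_toe_off']:.2f} %")

cycle = normalize_to_cycle(traj)                       # 101-point 0-100% grid
corpus = generate_synthetic_heel_data("normal", seed=3)  # 30 cycles, 10 subjects
mixture = fit_heel_mixture(corpus, n_components=12)
angles = fuse_trajectories(cycle, mixture, params.l0)
print(f"knee flexion range: {np.degrees(angles.knee_r).min():.1f} - "
      f"{np.degrees(angles.knee_r).max():.1f} deg")
```

prints

```
double-stance fraction: 19.99 %
contralateral heel strike at 50.07 % / toe-off at 60.10 %
knee flexion range: 0.0 - 91.0 deg
```

i.e. the simulated normal gait spends a fifth of the cycle in double
support, the opposite foot lands at mid-cycle and releases at 60% — the
classical clinical timing landmarks — and the knee goes from full
extension at contact to deep swing flexion.  Swapping in the crouch
preset (`k=400`, `d=0.65`, `l₀=0.95`) yields a knee that never extends
past ~21° of flexion, the crouch signature; the Parkinson stage presets
(Table-learned `k`, `d`) produce strides that shorten monotonically with
disease stage.

The same pipeline is scriptable from the shell:

```bash
gaitfuse simulate --preset parkinson_stage3 --cycles 3 --seed 7 \
    --out cog.csv --normalized-out cycle.csv
gaitfuse gen-fixtures --gait-class parkinson_stage3 --out heels.csv
gaitfuse fit-heel --data heels.csv --gait-class parkinson_stage3 --out mix.json
gaitfuse ik --cog cycle.csv --mixture mix.json --out angles.csv
gaitfuse evaluate --angles-sim angles.csv --angles-ref ref_angles.csv \
    --cog-sim cycle.csv --cog-ref ref_cycle.csv
gaitfuse animate --cog cycle.csv --angles angles.csv --fmt gif --out gait.gif
```

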