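# Methods

## Model structure

The simulator treats one walking stride as a hybrid dynamical system in
the sagittal plane, switching between two regimes of CoG dynamics.

**Single stance.** The body is reduced to a hip point mass `M` riding a
rigid stance leg of length `l0` pivoting about the stance contact, with
a point mass `m = beta*M` at the swing foot.  Generalized coordinates
are the stance angle `theta` and the inter-leg angle `phi`, measured
from the slope normal; gravity is tilted by the ground slope.  The
equations of motion are derived from the Lagrangian of the two point
masses (the mass matrix and forcing terms are hand-assembled and
verified in the test suite against an independently constructed
symbolic derivation, against energy conservation to 1e-6 relative, and
against time reversal).  The system is conservative within the phase.
Heel strike is the event `phi - 2*theta = 0`: the two legs symmetric
about the slope normal, hence the swing foot at ground height.  The
same surface is crossed mid-swing when the swing foot scuffs the ground
near `theta ~ 0` (a well-known artifact of compass models); crossings
are only accepted as heel strikes when the stance leg is past the
vertical (`theta > 0` by default), and the solver-located event time is
polished on the dense output so the residual is below 1e-9 rad.

**Double stance.** The CoG is a point mass between two massless leg
springs anchored at the trailing contact (origin) and the leading
contact `(d, 0)`.  The printed force law `k(l0/sqrt(x^2+y^2) - 1)` is a
force-per-unit-length coefficient, which makes each leg exactly a
linear spring of stiffness `k` and rest length `l0` acting along the
leg axis; this reading is enforced in tests by a vector-form oracle
(`F = k(l0 - l) u_leg`) and gives the closed-form elastic potential
`k(l0-l)^2/2` used by the energy invariant.  The phase is conservative.
Toe-off is the event at which the trailing spring returns to rest
length while lengthening (zero-force take-off).  With coincident
contacts the linearized vertical mode has period `2*pi*sqrt(M/(2k))` —
mass `M` on two parallel springs; a bare `sqrt(m/k)` reading of the
period applies to a single spring only, so the test pins the effective
mass and stiffness that actually oscillate.

## Hand-offs and their consequences

At heel strike both legs have length exactly `l0`, so mapping the polar
pendulum state into the two-contact Cartesian frame preserves position
and velocity identically.  The leading foot is planted at the
*configured* inter-foot distance `d` — the step anticipates the CoG
travel of the coming double stance — which generally leaves the leading
spring slightly strained at contact.  (Planting at the instantaneous
geometric separation `2*l0*sin(theta*)` instead destroys the gait: the
next stance then starts too close to the vertical and no parameter set
sustains more than one cycle.)

At toe-off the leading leg is in general still compressed, so a rigid
`l0` pendulum about the leading contact cannot match both the CoG
position and the contact point.  The implementation preserves the CoG
position exactly (the phase-boundary continuity audit demands jumps
below 1e-9 m) and projects the effective pivot along the leg axis; the
contact point therefore slides by the residual compression, and the
absolute trajectory height drifts down by that amount each step.  The
trajectory records the support level per sample (`support_y`), and all
cycle-normalized consumers work with height above support, which is the
periodic quantity gait laboratories plot.  The CoG velocity component
radial to the new pivot is discarded (a rigid leg cannot carry it) —
the model's only dissipation.

## Steady-gait regulation

The raw passive hybrid has no stable walking limit cycle in the
physically sensible parameter region: the double-stance height drop is
returned as stance rotation that is systematically faster than the
passive swing leg (natural half-period `pi*sqrt(l0/g)` ~ 1 s) can
match, and the pivot projection acts as an additional energy pump, so
the map from one step to the next diverges within two or three steps.
This was established numerically (fixed-point searches and parameter
sweeps over stiffness, slope, step geometry and launch rate).  Real
walking is not passive either: speed and swing initiation are actively
controlled step by step.  `simulate_gait` therefore applies a
*steady-gait regulation* at every toe-off: the new stance is launched
at `launch` times the minimum rate needed to vault its apex from the
current geometry, and the freed swing leg receives a rate proportional
to the excursion it still has to cover (`swing_gain`).  Positions are
never touched, so the trajectory remains continuous and each phase
evolves under the unmodified passive dynamics.  With regulation the
gait settles into a periodic pattern within one cycle (cycle-to-cycle
RMS difference of the normalized CoG below 0.3%).  `regulate=False`
exposes the raw hybrid, which the test suite shows stops striking.

## Parameters and presets

| preset | M (kg) | l0 (m) | k | d (m) | notes |
|---|---|---|---|---|---|
| normal | 70 | 1.00 | 9150 N/m | 0.50 | calibrated, see below |
| crouch | 1 | 0.95 | 400 | 0.65 | leg shortened by 5% |
| parkinson | 1 | 1.00 | 500 | 0.58 | generic |
| stage 2 | 1 | 1.00 | 52.3 | 0.76105 | learned per stage |
| stage 3 | 1 | 1.00 | 67.42 | 0.5576 | |
| stage 4 | 1 | 1.00 | 96.8 | 0.4356 | |

All presets use slope 0.009 rad, `beta = m/M = 0.01`, `launch = 1.05`
and `swing_gain = 1.0` unless noted (stage 2 uses a 0.30 rad step
angle, stage 3 `swing_gain = 1.3`; these are the gait-control settings
under which those stiffness/step values walk).  The disease presets'
stiffnesses span 52–500 in the literature they encode, far too soft to
carry a 70 kg body under the adopted force law; they are therefore read
as stiffness per unit body mass (model mass 1 kg), which keeps every
printed value usable without rescaling it.  The normal preset's `k`,
`d`, step angle and launch were calibrated once so that the simulated
cycle reproduces the two clinical timing landmarks — double stance
~20% of the cycle, contralateral toe-off at ~60% — and frozen together
with the steady periodic step as the preset's initial state; they are
not fitting knobs.

## Heel paths and the synthetic corpus

Per gait class, heel trajectories are represented coordinate-wise as a
signed-weight Gaussian-basis expansion over the normalized cycle with
an intercept (a coordinate trajectory is not a density: weights may be
negative and the baseline is nonzero).  Fitting places the means on a
uniform grid with shared width equal to the grid spacing and solves the
weights by linear least squares — reproducible and well conditioned —
with an optional nonlinear polish of means/widths used when exact
recovery of a generating component matters.

The study-style corpus (10 subjects, 30 cycles) is synthetic: each
cycle is a parametric template — flat plant for the first ~38% of the
cycle, then a single smooth heel-off/swing hump peaking near two-thirds
of its span, with the foot advancing one stride per cycle by a
minimum-jerk profile — plus smooth within-cycle noise (low-order
sinusoids vanishing at the endpoints, so per-cycle displacement is
exactly one stride) and subject-level offsets.  Class distortions:
crouch plants the heel 10 cm short of full extension and keeps a 6 cm
persistent heel elevation (toe-walking, which is what keeps the knee
flexed all cycle); Parkinsonian classes shorten the step with the
preset `d` and lower the lift.  What the generator does *not* emulate:
marker noise spectra, foot-rollover shape, inter-subject kinematic
variability beyond offsets, or any upper-body influence — so passing
tests show internal consistency of the pipeline on structurally
realistic inputs, not agreement with any individual patient.

## Inverse kinematics

Thigh and shank are both `l0/2` (the knee at mid-leg).  The closed-form
solution is the law-of-cosines knee angle and the hip bearing plus
interior offset; the anatomical branch (knee ahead of the hip–heel
line) is fixed globally.  CCD provides the same answer iteratively;
its convergence is linear with rate approaching one near full
extension, hence a generous iteration budget, and a target at (or
clamped onto) the reach circle is answered with the straight-leg
configuration directly, where coordinate descent cannot make progress.

Fusing a CoG cycle with a heel mixture anchors the heel path's stance
plateau under the CoG apex (mid single stance, when the hip vaults
directly over the planted foot) and shifts the contralateral copy by
half a cycle and one step length.  Around foot contact the model's
anticipated plant lies a few percent beyond rigid-leg reach (the
leading spring is strained there), so those samples clamp to the reach
circle — a straight knee at contact, which is also the clinical
picture.  Only samples beyond reach by more than 5% of `l0` count
toward the consistency guard, which rejects input pairs (wrong class
or leg length) where more than a quarter of samples are far out of
reach.

## Numerical choices

Integration uses DOP853 at `rtol = atol = 1e-10` with dense output;
events are located by bisection on the dense interpolant to machine
precision (heel-strike residual <= 1e-9 rad, trailing-leg force
coefficient <= 1e-9 at toe-off).  Trajectories are sampled at 2 ms with
exact event endpoints.  Cycle normalization resamples linearly onto a
101-point 0–100% grid, the gait-analysis convention; the first
simulated cycle is discarded as transient by default.  The degenerate
mass-matrix configuration (vanishing `beta`) raises a conditioning
error at condition number 1e12.  Curve metrics: the discrete Fréchet
distance is computed by dynamic programming over the coupling lattice
and is checked exhaustively against all monotone couplings for short
curves; joint-angle channels are embedded for it with the percent axis
rescaled into the angle range (a 1-D values-only mode is available);
the CoG correlation averages the per-axis coefficients.

## Known limitations

The model is two-dimensional and foot-rollover free; stance is rigid,
so the simulated normal knee is fully extended throughout single
support (real knees flex ~15 degrees in early stance).  The steady-gait
regulation stabilizes cadence but is not a biomechanical controller
model; between-step variability is therefore absent unless injected
through the heel-path sampler.  The pathological presets inherit the
printed per-unit-mass stiffnesses, whose double-stance fractions
(25–27%) are plausible for slow pathological gait but are not fitted
to patient timing data.  Joint-angle magnitudes are indicative: the
hip and knee ranges exceed clinical means by roughly a third because
the CoG excursion of the point-mass model is larger than that of an
articulated trunk.
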