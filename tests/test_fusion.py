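"""Fused gait cycles: presets, handoffs, phase structure, periodicity."""

import io
import math

import numpy as np
import pytest

from gaitfuse.errors import NonWalkingParamsError
from gaitfuse.fusion import (
    DOUBLE,
    SINGLE,
    CoGTrajectory,
    GaitEvent,
    GaitParams,
    NormalizedCycle,
    handoff_pendulum_to_spring,
    handoff_spring_to_pendulum,
    normalize_to_cycle,
    preset_params,
    simulate_gait,
)
from gaitfuse.single_stance import PendulumState


# ------------------------------------------------------------ presets

@pytest.mark.parametrize(
    "gait_class, k, d",
    [
        ("parkinson_stage2", 52.3, 0.76105),
        ("parkinson_stage3", 67.42, 0.5576),
        ("parkinson_stage4", 96.8, 0.4356),
        ("parkinson", 500.0, 0.58),
        ("crouch", 400.0, 0.65),
    ],
)
def test_preset_disease_parameters(gait_class, k, d):
    p = preset_params(gait_class)
    assert p.k == k
    assert p.d == d


def test_crouch_leg_shortening():
    assert preset_params("crouch").l0 == 0.95
    assert preset_params("parkinson").l0 == 1.0


def test_parkinson_step_separation_decreases_with_stage():
    d2 = preset_params("parkinson_stage2").d
    d4 = preset_params("parkinson_stage4").d
    assert d4 < d2


def test_unknown_class_rejected():
    with pytest.raises(ValueError):
        preset_params("limping")
    with pytest.raises(ValueError):
        GaitParams(gait_class="nope")


def test_stage_table_override():
    p = preset_params("parkinson_stage3", stage_table={3: (80.0, 0.5)})
    assert p.k == 80.0 and p.d == 0.5


def test_beta_recomputed_not_stored():
    p = GaitParams(M=50.0, m=1.0)
    assert p.beta == pytest.approx(0.02)


def test_params_json_round_trip(tmp_path):
    p = preset_params("normal")
    path = tmp_path / "cfg.json"
    p.to_json(path)
    q = GaitParams.from_json(path)
    assert q == p


# ------------------------------------------------------------ handoffs

def test_heel_strike_handoff_preserves_position_and_velocity():
    p = preset_params("normal")
    hs = PendulumState(1.2, 0.18, 0.36, 0.6, 0.1)
    ss, d_geo = handoff_pendulum_to_spring(hs, p)
    l0 = p.l0
    assert ss.x == pytest.approx(l0 * math.sin(0.18), abs=1e-15)
    assert ss.y == pytest.approx(l0 * math.cos(0.18), abs=1e-15)
    assert ss.x_dot == pytest.approx(l0 * 0.6 * math.cos(0.18), abs=1e-15)
    assert ss.y_dot == pytest.approx(-l0 * 0.6 * math.sin(0.18), abs=1e-15)
    assert d_geo == pytest.approx(2 * l0 * math.sin(0.18), abs=1e-15)


def test_handoff_round_trip_algebraic_inverse():
    """pendulum -> spring -> pendulum (same leg assignment) is the
    identity to 1e-12."""
    p = preset_params("normal")
    hs = PendulumState(0.0, 0.2, 0.4, 0.55, 0.15)
    ss, d_geo = handoff_pendulum_to_spring(hs, p)
    back, shift = handoff_spring_to_pendulum(ss, p, d_geo, stance="trailing")
    assert abs(back.theta - hs.theta) < 1e-12
    assert abs(back.phi - hs.phi) < 1e-12
    assert abs(back.theta_dot - hs.theta_dot) < 1e-12
    assert abs(shift) < 1e-12


def test_toe_off_handoff_preserves_cog():
    """The new pivot is projected along the leading leg so the CoG does
    not move even when that leg is not at rest length."""
    p = preset_params("normal")
    from gaitfuse.double_stance import SpringMassState

    to = SpringMassState(0.0, 0.31, 0.955, 0.6, 0.3)
    st, shift = handoff_spring_to_pendulum(to, p, p.d, stance="leading")
    # CoG reconstructed from the pendulum state about the shifted pivot
    w = np.array([to.x - p.d, to.y])
    ell = np.hypot(*w)
    pivot = np.array([to.x, to.y]) - p.l0 * w / ell
    cog = pivot + p.l0 * np.array([math.sin(st.theta), math.cos(st.theta)])
    assert np.hypot(cog[0] - to.x, cog[1] - to.y) < 1e-12
    assert shift == pytest.approx(p.l0 - ell, abs=1e-12)


# ------------------------------------------------------------ simulation

def test_zero_cycles_empty_trajectory():
    traj = simulate_gait(preset_params("normal"), 0)
    assert len(traj) == 0
    assert traj.cycle_events == []


def test_phase_alternation_and_event_bracketing(normal_traj):
    kinds = [e.kind for e in normal_traj.cycle_events]
    # strictly alternating heel_strike / toe_off, starting with a strike
    assert kinds[0] == "heel_strike"
    for a, b in zip(kinds, kinds[1:]):
        assert a != b
    # feet alternate between successive heel strikes
    feet = [e.foot for e in normal_traj.heel_strikes()]
    for a, b in zip(feet, feet[1:]):
        assert a != b
    # time strictly increasing, phases delimited by the events
    assert np.all(np.diff(normal_traj.t) > 0)
    for ev in normal_traj.cycle_events:
        i = np.searchsorted(normal_traj.t, ev.t) - 1
        j = min(i + 2, len(normal_traj) - 1)
        expected = (
            {SINGLE, DOUBLE} if ev.kind == "heel_strike" else {DOUBLE, SINGLE}
        )
        assert {normal_traj.phase[i], normal_traj.phase[j]} <= expected


def test_cog_continuity_across_phase_boundaries(normal_traj):
    assert len(normal_traj.boundary_jumps) > 0
    assert max(normal_traj.boundary_jumps) < 1e-9


def test_determinism(normal_traj):
    again = simulate_gait(preset_params("normal"), 2)
    assert np.array_equal(again.t, normal_traj.t)
    assert np.array_equal(again.x, normal_traj.x)
    assert np.array_equal(again.y, normal_traj.y)


def test_double_stance_fraction_near_clinical(normal_traj):
    """The normal preset spends about a fifth of the cycle in double
    stance, the classical clinical figure."""
    assert normal_traj.double_stance_fraction(1) == pytest.approx(20.0, abs=1.0)


def test_contralateral_events_near_clinical(normal_traj):
    ev = normal_traj.event_percents(1)
    assert ev["contralateral_heel_strike"] == pytest.approx(50.0, abs=1.5)
    assert ev["contralateral_toe_off"] == pytest.approx(60.0, abs=1.5)


def test_parkinson_stride_monotone_across_stages():
    strides = []
    for stage in (2, 3, 4):
        traj = simulate_gait(preset_params(f"parkinson_stage{stage}"), 2)
        strides.append(traj.stride_length(1))
    assert strides[0] > strides[1] > strides[2]


def test_periodicity_after_transient():
    traj = simulate_gait(preset_params("normal"), 3)
    c1 = normalize_to_cycle(traj, cycle=1)
    c2 = normalize_to_cycle(traj, cycle=2)
    rms = np.sqrt(np.mean((c1.x - c2.x) ** 2 + (c1.y - c2.y) ** 2))
    scale = np.sqrt(np.mean(c1.x**2 + (c1.y - c1.y.mean()) ** 2))
    assert rms / scale < 0.01


def test_non_walking_parameters_name_the_phase():
    p = GaitParams(gait_class="custom", M=70, m=0.7, l0=1.0, k=9150.0, d=0.5,
                   slope=0.009, step_angle=0.2, launch=0.2)  # cannot vault
    with pytest.raises(NonWalkingParamsError) as exc:
        simulate_gait(p, 1, phase_time_cap=2.0)
    assert exc.value.phase == "single_stance"


def test_unregulated_hybrid_does_not_sustain_walking():
    """Without the steady-gait regulation the passive hybrid loses the
    swing-stance synchrony and stops striking within a few steps."""
    from dataclasses import replace

    p = replace(preset_params("normal"), regulate=False)
    with pytest.raises(NonWalkingParamsError):
        simulate_gait(p, 3)


# ------------------------------------------------------------ normalization

def _synthetic_traj(n=801, t_end=2.0):
    t = np.linspace(0.0, t_end, n)
    x = np.sin(2 * np.pi * t / t_end)
    y = 1.0 + 0.05 * np.cos(2 * np.pi * t / t_end)
    phase = np.full(n, SINGLE, dtype=object)
    events = [
        GaitEvent(0.0, "heel_strike", "right"),
        GaitEvent(t_end / 2, "heel_strike", "left"),
        GaitEvent(t_end, "heel_strike", "right"),
    ]
    return CoGTrajectory(t, x, y, phase, events)


def test_normalize_output_length():
    traj = _synthetic_traj()
    for n_points in (51, 101, 200):
        cyc = normalize_to_cycle(traj, n_points=n_points, cycle=0)
        assert len(cyc.percent) == n_points
        assert cyc.percent[0] == 0.0 and cyc.percent[-1] == 100.0


def test_normalize_uniform_input_identity():
    traj = _synthetic_traj(n=101)
    cyc = normalize_to_cycle(traj, n_points=101, cycle=0)
    np.testing.assert_allclose(cyc.x, traj.x - traj.x[0], atol=1e-12)
    np.testing.assert_allclose(cyc.y, traj.y, atol=1e-12)


def test_normalize_resamples_sine_from_irregular_grid():
    """Linear resampling of an irregularly sampled sine reproduces the
    closed form to 1e-3 at 101 points."""
    rng = np.random.default_rng(7)
    t = np.sort(rng.uniform(0.0, 2.0, 4000))
    t[0], t[-1] = 0.0, 2.0
    x = np.sin(np.pi * t)
    y = np.cos(np.pi * t)
    phase = np.full(t.size, SINGLE, dtype=object)
    events = [
        GaitEvent(0.0, "heel_strike", "right"),
        GaitEvent(1.0, "heel_strike", "left"),
        GaitEvent(2.0, "heel_strike", "right"),
    ]
    traj = CoGTrajectory(t, x, y, phase, events)
    cyc = normalize_to_cycle(traj, n_points=101, cycle=0)
    expected = np.sin(np.pi * np.linspace(0, 2, 101))
    np.testing.assert_allclose(cyc.x, expected - expected[0], atol=1e-3)


def test_normalize_requires_complete_cycle():
    t = np.linspace(0, 1, 11)
    traj = CoGTrajectory(
        t, t, t, np.full(11, SINGLE, dtype=object),
        [GaitEvent(0.0, "heel_strike", "right")],
    )
    with pytest.raises((ValueError, IndexError)):
        normalize_to_cycle(traj)


def test_trajectory_csv_schema(normal_traj):
    buf = io.StringIO()
    normal_traj.to_csv(buf)
    header = buf.getvalue().splitlines()[0]
    assert header.startswith("t,percent_cycle,x,y,phase")


def test_normalized_cycle_csv_round_trip(tmp_path, normal_cycle):
    path = tmp_path / "cycle.csv"
    normal_cycle.to_csv(path)
    back = NormalizedCycle.from_csv(path)
    np.testing.assert_allclose(back.x, normal_cycle.x, atol=1e-12)
    np.testing.assert_allclose(back.y, normal_cycle.y, atol=1e-12)
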