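"""Control layer: hybrid systems, the active-control law and its
Mittag-Leffler error decay, salience ranking, scheduling, and lock counting."""

import math

import numpy as np
import pytest

from oscatt.control import (
    AttentionSchedule,
    ControlGains,
    active_control,
    build_schedule,
    count_transitions,
    hybrid_drift,
    hybrid_state,
    rank_groups_by_salience,
    run_attention,
)
from oscatt.network import layer1_rhs, simulate_layer1
from oscatt.pipeline import RunConfig, encode_image
from oscatt.rossler import RosslerParams
from oscatt.solver import FractionalConfig

from test_solver import mittag_leffler


@pytest.fixture(scope="module")
def recorded_run(two_region_encoded_module):
    image, labels, contrast, scene, o_r = two_region_encoded_module
    frac = FractionalConfig(t_end=15.0, seed=6)
    layer1 = simulate_layer1(scene, frac, record_states=True)
    return layer1, labels, scene, o_r


@pytest.fixture(scope="module")
def two_region_encoded_module():
    from oscatt.scenes import SceneObject, SceneSpec, make_scene

    spec = SceneSpec(canvas=(8, 12), background=(30, 30, 30),
                     objects=(SceneObject("rectangle", (2, 2), (4, 5), (255, 255, 230)),))
    image, labels = make_scene(spec)
    contrast, scene, o_r = encode_image(image, RunConfig())
    return image, labels, contrast, scene, o_r


class TestHybrid:
    def test_identical_members(self):
        states = np.tile([1.0, 2.0, 3.0], (4, 1))
        w = hybrid_state(states, np.array([True, True, False, False]))
        assert np.allclose(w, [1.0, 2.0, 3.0])

    def test_two_member_mean(self):
        states = np.array([[0.0, 1.0, 4.0], [2.0, 3.0, 0.0]])
        assert np.allclose(hybrid_state(states, np.array([True, True])), [1.0, 2.0, 2.0])

    def test_union_linearity(self):
        rng = np.random.default_rng(0)
        states = rng.normal(size=(6, 3))
        a = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        b = ~a
        w_union = hybrid_state(states, a | b)
        assert np.allclose(w_union, (hybrid_state(states, a) + hybrid_state(states, b)) / 2)

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            hybrid_state(np.zeros((3, 3)), np.zeros(3, dtype=bool))

    def test_drift_single_member(self, two_region_encoded_module):
        _, labels, _, scene, _ = two_region_encoded_module
        rng = np.random.default_rng(1)
        state = rng.normal(size=scene.shape + (3,))
        members = np.zeros(scene.shape, dtype=bool)
        members[3, 4] = True
        omega = hybrid_drift(state, members, scene)
        assert np.allclose(omega, layer1_rhs(state, scene)[3, 4])

    def test_drift_is_mean_derivative_alpha_one(self, two_region_encoded_module):
        """At alpha = 1 the hybrid's one-step increment equals h * Omega."""
        _, labels, _, scene, _ = two_region_encoded_module
        frac = FractionalConfig(alpha=1.0, h=0.01, t_end=0.1, seed=3)
        res = simulate_layer1(scene, frac, subsample=1, record_states=True)
        members = labels == 1
        k = 5
        w_now = hybrid_state(res.states[k], members)
        w_next = hybrid_state(res.states[k + 1], members)
        omega = hybrid_drift(res.states[k], members, scene)
        assert np.allclose((w_next - w_now) / frac.h, omega, rtol=1e-9, atol=1e-9)


class TestActiveControl:
    def test_nothing_to_correct(self):
        p = RosslerParams()
        response = np.array([0.5, -0.2, 0.9])
        o_r = 1.0
        f_r = np.array([-o_r * response[1] - response[2],
                        o_r * response[0] + p.a * response[1],
                        p.b + response[2] * (response[0] - p.c)])
        u = active_control(response, hybrid=response, drift=f_r,
                           gains=ControlGains(), o_r=o_r, params=p)
        assert np.allclose(u, 0.0, atol=1e-14)

    def test_pure_feedback_term(self):
        p = RosslerParams()
        response = np.array([1.0, 0.0, 0.0])
        o_r = 1.0
        f_r = np.array([0.0, o_r * 1.0, p.b + 0.0 * (1.0 - p.c)])
        hybrid = response - np.array([1.0, 0.0, 0.0])  # e = (1, 0, 0)
        u = active_control(response, hybrid, drift=f_r, gains=ControlGains(), o_r=o_r, params=p)
        assert np.allclose(u, [-1.0, 0.0, 0.0])

    def test_gains_must_be_positive(self):
        with pytest.raises(ValueError):
            ControlGains(k=np.array([1.0, -1.0, 1.0]))

    def test_closed_loop_mittag_leffler_decay(self, recorded_run):
        """During an epoch starting at t = 0 the error contracts like
        E_alpha(-K t^alpha) (exact linear error dynamics by construction)."""
        layer1, labels, scene, o_r = recorded_run
        schedule = build_schedule([1], t1=0.0, span=10.0)
        res = run_attention(layer1, labels.ravel(), schedule, scene, o_r,
                            subsample=10)
        members = labels.ravel() == 1
        # reconstruct the hybrid trajectory at the subsampled times
        w = layer1.states[::10][:, labels == 1, :].mean(axis=1)
        e = res.central_states - w
        e0 = e[0]
        alpha = layer1.config.alpha
        for ti in (20, 50, 100):
            t = res.times[ti]
            expected = mittag_leffler(alpha, -(t**alpha))
            for comp in range(3):
                assert e[ti, comp] == pytest.approx(e0[comp] * expected, abs=5e-3 * max(1, abs(e0[comp])))

    def test_error_decays_below_threshold(self, recorded_run):
        layer1, labels, scene, o_r = recorded_run
        schedule = build_schedule([1], t1=0.0, span=10.0)
        res = run_attention(layer1, labels.ravel(), schedule, scene, o_r)
        w = layer1.states[::10][:, labels == 1, :].mean(axis=1)
        err = np.linalg.norm(res.central_states - w, axis=1)
        assert err[99] < 1e-2  # by t = 9.9, deep into the epoch


class TestSalienceRanking:
    def test_faster_group_first(self):
        t = np.linspace(0, 30, 301)
        phases = np.column_stack([1.02 * t, 1.02 * t, 0.98 * t])
        labels = np.array([0, 0, 1])
        order = rank_groups_by_salience(phases, t, labels, window=(5, 25))
        assert order == [0, 1]

    def test_singleton(self):
        t = np.linspace(0, 10, 101)
        order = rank_groups_by_salience(np.outer(t, [1.0]), t, np.array([3]), (1, 9))
        assert order == [3]

    def test_tie_breaks_by_group_id(self):
        t = np.linspace(0, 10, 101)
        phases = np.column_stack([t, t])
        order = rank_groups_by_salience(phases, t, np.array([7, 2]), (1, 9))
        assert order == [2, 7]

    def test_window_validation(self):
        t = np.linspace(0, 10, 101)
        with pytest.raises(ValueError):
            rank_groups_by_salience(np.outer(t, [1.0]), t, np.array([0]), (9.99, 9.995))


class TestSchedule:
    def test_paper_onsets(self):
        sched = build_schedule([3, 1, 2, 0], t1=20.0, span=10.0)
        assert sched.epochs[0].onset == pytest.approx(20.0)
        assert sched.epochs[1].onset == pytest.approx(30.01)
        assert sched.epochs[2].onset == pytest.approx(40.02)
        assert sched.epochs[3].offset == pytest.approx(60.03, abs=1e-9)

    def test_single_group(self):
        sched = build_schedule([0], t1=20.0, span=10.0)
        assert len(sched.epochs) == 1
        assert (sched.epochs[0].onset, sched.epochs[0].offset) == (20.0, 30.0)

    def test_arithmetic_progression(self):
        sched = build_schedule(list(range(6)), t1=5.0, span=3.0, gap=0.01)
        onsets = [e.onset for e in sched.epochs]
        steps = np.diff(onsets)
        assert np.allclose(steps, 3.01)

    def test_duplicate_groups_rejected(self):
        with pytest.raises(ValueError):
            build_schedule([1, 1], t1=0.0, span=1.0)

    def test_invalid_times(self):
        with pytest.raises(ValueError):
            build_schedule([0], t1=-1.0, span=1.0)
        with pytest.raises(ValueError):
            build_schedule([0], t1=0.0, span=0.0)


class TestRunAttention:
    def test_empty_schedule_is_free_run(self, recorded_run):
        layer1, labels, scene, o_r = recorded_run
        sched = AttentionSchedule(epochs=(), span=10.0)
        res = run_attention(layer1, labels.ravel(), sched, scene, o_r)
        assert res.lock_report == []
        assert count_transitions(res) == 0
        # phase grows roughly linearly at the free-running rate
        assert res.central_phase[-1] > res.central_phase[0]

    def test_schedule_overrun_rejected(self, recorded_run):
        layer1, labels, scene, o_r = recorded_run
        sched = build_schedule([1], t1=10.0, span=10.0)  # ends at 20 > t_end 15
        with pytest.raises(ValueError, match="beyond"):
            run_attention(layer1, labels.ravel(), sched, scene, o_r)

    def test_lock_during_epoch(self, recorded_run):
        layer1, labels, scene, o_r = recorded_run
        sched = build_schedule([1, 0], t1=0.0, span=7.0)
        res = run_attention(layer1, labels.ravel(), sched, scene, o_r)
        assert count_transitions(res) == 2
        for rep in res.lock_report:
            assert rep["locked"]
            assert rep["mean_abs_err"] < 0.5

    def test_one_way_drive(self, recorded_run):
        """Attaching the central unit never perturbs layer 1."""
        layer1, labels, scene, o_r = recorded_run
        phases_before = layer1.phases.copy()
        states_before = layer1.states.copy()
        sched = build_schedule([0], t1=2.0, span=5.0)
        run_attention(layer1, labels.ravel(), sched, scene, o_r)
        assert np.array_equal(layer1.phases, phases_before)
        assert np.array_equal(layer1.states, states_before)

    def test_hybrid_phase_growth_matches_members(self, recorded_run):
        """The hybrid's phase velocity equals its members' mean velocity."""
        layer1, labels, scene, o_r = recorded_run
        sched = build_schedule([1], t1=0.0, span=10.0)
        res = run_attention(layer1, labels.ravel(), sched, scene, o_r)
        psi_h = res.hybrid_phases[1]
        members = labels.ravel() == 1
        member_mean = layer1.phases[:, members].mean(axis=1)
        i0, i1 = len(res.times) // 2, len(res.times) - 1
        dt = res.times[i1] - res.times[i0]
        v_h = (psi_h[i1] - psi_h[i0]) / dt
        v_m = (member_mean[i1] - member_mean[i0]) / dt
        assert v_h == pytest.approx(v_m, abs=0.05)
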