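"""Reward definition, perturbation sampling, training-set generation and
the greedy registration loop."""

import numpy as np
import pytest

from lvreg import (
    ActionSet,
    CArmGeometry,
    InPlaneTransform,
    MDPConfig,
    PerturbationSpec,
    build_training_set,
    compute_rewards,
    oracle_policy,
    register,
    render_drr,
    sample_perturbation,
    transform_distance,
)


class TestComputeRewards:
    def test_collinear_unit_case(self):
        """From (5,0,0) towards identity: tx- gains +1, tx+ loses 1."""
        r = compute_rewards(
            InPlaneTransform(), InPlaneTransform(5, 0, 0), ActionSet()
        ).rewards
        assert r[1] == pytest.approx(1.0)  # tx-
        assert r[0] == pytest.approx(-1.0)  # tx+

    def test_at_optimum_all_rewards_negative(self):
        t = InPlaneTransform(2, -3, 4)
        r = compute_rewards(t, t, ActionSet()).rewards
        assert np.all(r < 0)
        assert np.allclose(r, -1.0)  # each step costs one D-unit

    def test_three_four_five_hand_case(self):
        """Eq-style hand evaluation: 5 - sqrt(2^2 + 4^2)."""
        r = compute_rewards(
            InPlaneTransform(), InPlaneTransform(3, 4, 0), ActionSet()
        ).rewards
        assert r[1] == pytest.approx(5.0 - np.sqrt(20.0), abs=1e-12)

    def test_reward_bounded_by_step_in_d_units(self):
        """|reward| <= D-size of one action step (triangle inequality)."""
        rng = np.random.default_rng(0)
        actions = ActionSet(step_t_mm=2.0, step_r_deg=1.5)
        for _ in range(200):
            tg = InPlaneTransform(*rng.uniform(-30, 30, 3))
            tt = InPlaneTransform(*rng.uniform(-30, 30, 3))
            r = compute_rewards(tg, tt, actions).rewards
            assert np.all(np.abs(r[:4]) <= actions.step_t_mm + 1e-12)
            assert np.all(np.abs(r[4:]) <= actions.step_r_deg + 1e-12)


class TestSamplePerturbation:
    def test_bounds_respected_and_approached(self):
        spec = PerturbationSpec()
        rng = np.random.default_rng(1)
        t_abs, r_abs, cop, prim, sec = [], [], [], [], []
        for _ in range(10_000):
            t, g = sample_perturbation(spec, rng)
            t_abs += [abs(t.tx_mm), abs(t.ty_mm)]
            r_abs.append(abs(t.rz_deg))
            cop.append(np.linalg.norm(g.cop_offset_mm))
            prim.append(abs(g.primary_angle_deg))
            sec.append(abs(g.secondary_angle_deg))
        for vals, bound in [
            (t_abs, 35.0),
            (r_abs, 15.0),
            (cop, 10.0),
            (prim, 15.0),
            (sec, 5.0),
        ]:
            assert max(vals) <= bound
            assert max(vals) >= 0.98 * bound

    def test_seed_reproducibility(self):
        spec = PerturbationSpec()
        seq1 = [sample_perturbation(spec, np.random.default_rng(4)) for _ in range(5)]
        seq2 = [sample_perturbation(spec, np.random.default_rng(4)) for _ in range(5)]
        for (t1, g1), (t2, g2) in zip(seq1, seq2):
            assert t1 == t2
            assert np.array_equal(g1.cop_offset_mm, g2.cop_offset_mm)

    def test_zero_spec_gives_identity(self):
        spec = PerturbationSpec(0, 0, 0, 0, 0)
        t, g = sample_perturbation(spec, np.random.default_rng(0))
        assert t == InPlaneTransform()
        assert np.allclose(g.cop_offset_mm, 0)


class TestBuildTrainingSet:
    def test_counts_and_label_reverification(self, small_phantom):
        vol, model = small_phantom
        phantoms = [(vol, model, 7)] * 3
        samples = build_training_set(
            phantoms,
            PerturbationSpec(),
            per_volume=4,
            actions=ActionSet(),
            seed=0,
            input_side=32,
            fixed_size=48,
        )
        assert len(samples) == 12
        for s in samples:
            expected = compute_rewards(
                InPlaneTransform(), s.perturbation, ActionSet()
            ).rewards
            assert np.array_equal(s.label.rewards, expected)
            assert s.fixed_roi.shape == (32, 32)
            assert s.moving.shape == (32, 32)

    def test_per_volume_zero_rejected(self, small_phantom):
        vol, model = small_phantom
        with pytest.raises(ValueError):
            build_training_set([(vol, model, 7)], PerturbationSpec(), 0, ActionSet())

    def test_seed_determinism(self, small_phantom):
        vol, model = small_phantom
        kw = dict(
            spec=PerturbationSpec(),
            per_volume=2,
            actions=ActionSet(),
            seed=5,
            input_side=32,
            fixed_size=48,
        )
        a = build_training_set([(vol, model, 7)], **kw)
        b = build_training_set([(vol, model, 7)], **kw)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.fixed_roi, s2.fixed_roi)
            assert np.array_equal(s1.label.rewards, s2.label.rewards)
            assert s1.perturbation == s2.perturbation


@pytest.fixture(scope="module")
def setup(small_phantom):
    vol, model = small_phantom
    geo = CArmGeometry().with_center(model.center)
    fixed = render_drr(vol, geo, size=64)
    cfg = MDPConfig(input_side=32)
    return fixed, model, geo, cfg


class TestRegister:
    def test_start_at_ground_truth_stays_within_one_step(self, setup):
        fixed, model, geo, cfg = setup
        t_g = InPlaneTransform()
        traj = register(oracle_policy(t_g, cfg.actions), fixed, model, geo, t_g, cfg)
        assert traj.stop_reason == "oscillation"
        assert len(traj) <= 6
        assert np.all(np.abs(traj.final.as_array()) <= 1.0 + 1e-9)

    def test_out_of_range_start_flags_divergence(self, setup):
        fixed, model, geo, cfg = setup
        traj = register(
            oracle_policy(InPlaneTransform(), cfg.actions),
            fixed,
            model,
            geo,
            InPlaneTransform(200, 0, 0),
            cfg,
        )
        assert traj.diverged
        assert len(traj) == 0

    def test_oracle_policy_converges_with_monotone_descent(self, setup):
        """Greedy descent on the exact rewards reaches one step per DOF."""
        fixed, model, geo, cfg = setup
        t_g = InPlaneTransform()
        rng = np.random.default_rng(11)
        for _ in range(10):
            t0 = InPlaneTransform(*rng.uniform([-35, -35, -15], [35, 35, 15]))
            traj = register(
                oracle_policy(t_g, cfg.actions), fixed, model, geo, t0, cfg
            )
            assert not traj.diverged
            err = np.abs(traj.final.as_array() - t_g.as_array())
            assert np.all(err <= [1.0 + 1e-9, 1.0 + 1e-9, 1.0 + 1e-9])
            d = [transform_distance(t, t_g) for t in traj.transforms()]
            body = d[: max(len(d) - 4, 1)]
            assert all(b2 <= b1 + 1e-9 for b1, b2 in zip(body, body[1:]))

    def test_telescoping_identity(self, setup):
        """Sum of realised rewards equals the total distance improvement."""
        fixed, model, geo, cfg = setup
        t_g = InPlaneTransform(2, -1, 3)
        rng = np.random.default_rng(3)
        for _ in range(5):
            t0 = InPlaneTransform(*rng.uniform([-30, -30, -10], [30, 30, 10]))
            traj = register(
                oracle_policy(t_g, cfg.actions), fixed, model, geo, t0, cfg
            )
            realized = sum(
                s.rewards[s.action] for s in traj.steps if s.action is not None
            )
            t_last = traj.steps[-1].transform
            expected = transform_distance(t_g, t0) - transform_distance(t_g, t_last)
            assert realized == pytest.approx(expected, abs=1e-9)

    def test_consecutive_transforms_differ_by_one_action(self, setup):
        fixed, model, geo, cfg = setup
        traj = register(
            oracle_policy(InPlaneTransform(), cfg.actions),
            fixed,
            model,
            geo,
            InPlaneTransform(6, -4, 2),
            cfg,
        )
        for s1, s2 in zip(traj.steps, traj.steps[1:]):
            diff = np.abs(s2.transform.as_array() - s1.transform.as_array())
            assert np.count_nonzero(diff) == 1
            assert diff.max() in (cfg.actions.step_t_mm, cfg.actions.step_r_deg)


def test_action_set_structure():
    a = ActionSet(step_t_mm=2.0, step_r_deg=0.5)
    assert len(a) == 6
    dofs = [d for d, _ in a.deltas]
    assert dofs == [0, 0, 1, 1, 2, 2]
    for i in range(6):
        assert a.inverse_action(a.inverse_action(i)) == i
        d1, s1 = a.deltas[i]
        d2, s2 = a.deltas[a.inverse_action(i)]
        assert d1 == d2 and s1 == -s2
    with pytest.raises(ValueError):
        ActionSet(step_t_mm=0)


def test_gamma_stored_but_loop_is_greedy():
    cfg = MDPConfig(gamma=0.5)
    assert cfg.gamma == 0.5
    with pytest.raises(ValueError):
        MDPConfig(gamma=1.5)
    with pytest.raises(ValueError):
        MDPConfig(max_iterations=0)
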