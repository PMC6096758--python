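"""Network layers (gradient checks), the dual-encoder agent and training."""

import numpy as np
import pytest

from lvreg import nn as N
from lvreg.agent import AgentConfig, RewardAgent, TrainConfig, build_agent, train_agent
from lvreg.geometry import InPlaneTransform
from lvreg.imitation import GeometryPerturbation, RewardVector, TrainingSample

RNG = np.random.default_rng(0)
GP0 = GeometryPerturbation(np.zeros(3), 0.0, 0.0)


def _sample(side=32, seed=0):
    r = np.random.default_rng(seed)
    return TrainingSample(
        fixed_roi=r.normal(size=(side, side)).astype(np.float32),
        moving=r.normal(size=(side, side)).astype(np.float32),
        label=RewardVector(r.normal(size=6)),
        phantom_seed=0,
        perturbation=InPlaneTransform(),
        geometry_perturbation=GP0,
    )


class TestLayerGradients:
    """Backprop checked against central finite differences."""

    def _check(self, layer, x, n_probe=6, eps=1e-2, tol=0.08):
        rng = np.random.default_rng(1)
        y = layer.forward(x.copy(), True)
        g = np.ones_like(y)
        dx = layer.backward(g)
        # input gradient
        for _ in range(n_probe):
            idx = tuple(rng.integers(0, s) for s in x.shape)
            xp = x.copy()
            xp[idx] += eps
            xm = x.copy()
            xm[idx] -= eps
            num = (layer.forward(xp, True).sum() - layer.forward(xm, True).sum()) / (
                2 * eps
            )
            if abs(num) > 1e-3 or abs(dx[idx]) > 1e-3:
                assert dx[idx] == pytest.approx(num, rel=tol, abs=5e-3)
        # parameter gradients
        layer.forward(x.copy(), True)
        layer.backward(g)
        for p, gp in zip(layer.params(), layer.grads()):
            for _ in range(n_probe):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                fp = layer.forward(x.copy(), True).sum()
                p[idx] = orig - eps
                fm = layer.forward(x.copy(), True).sum()
                p[idx] = orig
                num = (fp - fm) / (2 * eps)
                if abs(num) > 1e-3 or abs(gp[idx]) > 1e-3:
                    assert gp[idx] == pytest.approx(num, rel=tol, abs=5e-3)

    def test_conv3x3(self):
        x = RNG.normal(size=(3, 2, 8, 8)).astype(np.float32)
        self._check(N.Conv3x3(2, 4, np.random.default_rng(2)), x)

    def test_dense(self):
        x = RNG.normal(size=(5, 7)).astype(np.float32)
        self._check(N.Dense(7, 4, np.random.default_rng(3)), x)

    def test_batchnorm_2d(self):
        x = RNG.normal(size=(6, 5)).astype(np.float32)
        self._check(N.BatchNorm(5, ndim=2), x)

    def test_batchnorm_4d(self):
        x = RNG.normal(size=(4, 3, 4, 4)).astype(np.float32)
        self._check(N.BatchNorm(3, ndim=4), x)

    def test_maxpool(self):
        x = RNG.normal(size=(2, 3, 6, 6)).astype(np.float32)
        pool = N.MaxPool2()
        y = pool.forward(x, True)
        assert y.shape == (2, 3, 3, 3)
        # gradient routes to the argmax element only
        g = np.ones_like(y)
        dx = pool.backward(g)
        assert dx.sum() == pytest.approx(y.size)
        assert ((dx != 0) <= (x == np.repeat(np.repeat(y, 2, 2), 2, 3))).all()


class TestAgentNetwork:
    CFG = AgentConfig(input_side=32, conv_channels=(4, 8), fc_widths=(32, 16), seed=0)

    def test_output_is_six_rewards(self):
        agent = build_agent(self.CFG)
        r = agent.predict_rewards(np.zeros((32, 32)), np.zeros((32, 32)))
        assert r.rewards.shape == (6,)
        assert np.all(np.isfinite(r.rewards))

    def test_seed_determinism_of_initialization(self):
        a = build_agent(self.CFG)
        b = build_agent(self.CFG)
        x = RNG.normal(size=(32, 32))
        assert np.array_equal(
            a.predict_rewards(x, x).rewards, b.predict_rewards(x, x).rewards
        )

    def test_inference_is_repeatable(self):
        agent = build_agent(self.CFG)
        x = RNG.normal(size=(32, 32))
        r1 = agent.predict_rewards(x, x).rewards
        r2 = agent.predict_rewards(x, x).rewards
        assert np.array_equal(r1, r2)

    def test_encoders_are_not_weight_shared(self):
        agent = build_agent(self.CFG)
        w_f = agent.enc_fixed.params()[0]
        w_m = agent.enc_moving.params()[0]
        assert w_f is not w_m
        x, y = RNG.normal(size=(32, 32)), RNG.normal(size=(32, 32))
        assert not np.array_equal(
            agent.predict_rewards(x, y).rewards, agent.predict_rewards(y, x).rewards
        )

    def test_full_scale_config_instantiates(self):
        cfg = AgentConfig.paper_scale()
        assert cfg.input_side == 128
        assert len(cfg.conv_channels) == 4 and len(cfg.fc_widths) == 3
        agent = build_agent(cfg)
        r = agent.predict_rewards(np.zeros((128, 128)), np.zeros((128, 128)))
        assert r.rewards.shape == (6,)

    def test_incompatible_pooling_depth_rejected(self):
        with pytest.raises(ValueError, match="pooling"):
            AgentConfig(input_side=36, conv_channels=(4, 4, 4))

    def test_shape_mismatch_rejected(self):
        agent = build_agent(self.CFG)
        with pytest.raises(ValueError, match="inputs must be"):
            agent.predict_rewards(np.zeros((16, 16)), np.zeros((32, 32)))

    def test_save_load_roundtrip(self, tmp_path):
        agent = build_agent(self.CFG)
        train_agent(agent, [_sample()], TrainConfig(iterations=20, minibatch=1))
        agent.save(tmp_path / "a.npz")
        back = RewardAgent.load(tmp_path / "a.npz")
        x, y = RNG.normal(size=(32, 32)), RNG.normal(size=(32, 32))
        assert np.array_equal(
            agent.predict_rewards(x, y).rewards, back.predict_rewards(x, y).rewards
        )


class TestTraining:
    def test_overfits_a_single_sample(self):
        """Capacity sanity check: loss collapses on one memorised pair.

        Batch norm is disabled here: with a one-sample batch its running
        variance degenerates, which is a property of batch statistics,
        not of network capacity.
        """
        agent = build_agent(
            AgentConfig(
                input_side=32,
                conv_channels=(4, 8),
                fc_widths=(32, 16),
                batch_norm=False,
                seed=0,
            )
        )
        s = _sample(seed=5)
        hist = train_agent(
            agent, [s], TrainConfig(iterations=500, minibatch=1, seed=0)
        )
        assert hist.loss[-1] < 1e-3
        pred = agent.predict_rewards(s.fixed_roi, s.moving).rewards
        assert np.allclose(pred, s.label.rewards, atol=0.05)

    def test_learning_rate_schedule_exact_decay(self):
        """0.01 with ratio 0.8 per 10,000 iterations."""
        cfg = TrainConfig()
        assert cfg.lr_at(0) == 0.01
        assert cfg.lr_at(9_999) == 0.01
        assert cfg.lr_at(10_000) == pytest.approx(0.008, rel=1e-12)
        assert cfg.lr_at(20_000) == pytest.approx(0.0064, rel=1e-12)
        opt = N.RMSProp([np.zeros(1)], lr=0.01, decay_ratio=0.8, decay_interval=10_000)
        assert opt.current_lr(10_000) == pytest.approx(0.008, rel=1e-12)
        assert opt.current_lr(20_000) == pytest.approx(0.0064, rel=1e-12)

    def test_training_is_seed_deterministic(self):
        samples = [_sample(seed=i) for i in range(8)]
        outs = []
        for _ in range(2):
            agent = build_agent(TestAgentNetwork.CFG)
            train_agent(agent, samples, TrainConfig(iterations=30, minibatch=4, seed=2))
            x = samples[0]
            outs.append(agent.predict_rewards(x.fixed_roi, x.moving).rewards)
        assert np.array_equal(outs[0], outs[1])

    def test_loss_history_recorded_per_iteration(self):
        agent = build_agent(TestAgentNetwork.CFG)
        hist = train_agent(
            agent, [_sample(seed=i) for i in range(4)],
            TrainConfig(iterations=25, minibatch=2),
        )
        assert len(hist.loss) == len(hist.lr) == len(hist.iterations) == 25
        assert all(np.isfinite(hist.loss))

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError):
            train_agent(build_agent(TestAgentNetwork.CFG), [], TrainConfig())

    def test_history_csv_export(self, tmp_path):
        agent = build_agent(TestAgentNetwork.CFG)
        hist = train_agent(agent, [_sample()], TrainConfig(iterations=5, minibatch=1))
        hist.to_csv(tmp_path / "curve.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "curve.csv")
        assert list(df.columns) == ["iteration", "lr", "loss"]
        assert len(df) == 5
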