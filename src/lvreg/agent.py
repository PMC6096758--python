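"""The reward-regression agent: dual CNN encoders plus an FC decoder.

Two separate (unshared) convolutional encoders embed the fixed-image ROI
and the moving image; their feature vectors are concatenated and decoded
by a stack of fully connected layers into the six per-action rewards.
Each encoder has four 3x3 convolution layers, each followed by ReLU, 2x2
max pooling and batch normalisation; the decoder has four dense layers
with ReLU + batch normalisation between them.

Training is plain supervised regression: mean-squared error between the
predicted and the exact reward vectors, optimised with RMSProp
(momentum 0.9, learning rate 0.01 decayed by 0.8 every 10,000
iterations, minibatch 80).

The reference configuration takes 128x128 inputs with 32-32-64-64
encoder channels and a 256-128-64-6 decoder.  The default is a CPU-scale
reduction of the same shape: 64x64 inputs, 4-8-16-16 channels,
128-64-32-6 decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .imitation import RewardVector, TrainingSample
from .nn import (
    BatchNorm,
    Conv3x3,
    Dense,
    Flatten,
    MaxPool2,
    ReLU,
    RMSProp,
    Sequential,
)

__all__ = ["AgentConfig", "TrainConfig", "RewardAgent", "build_agent", "train_agent"]


@dataclass(frozen=True)
class AgentConfig:
    """Network shape.  ``paper_scale()`` gives the full-size variant."""

    input_side: int = 64
    conv_channels: tuple[int, ...] = (4, 8, 16, 16)
    fc_widths: tuple[int, ...] = (128, 64, 32)
    n_actions: int = 6
    batch_norm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_actions != 6:
            raise ValueError("the action set has exactly 6 actions")
        if len(self.conv_channels) < 1 or len(self.fc_widths) < 1:
            raise ValueError("need at least one conv and one FC layer")
        if self.input_side % (2 ** len(self.conv_channels)) != 0:
            raise ValueError(
                f"input side {self.input_side} incompatible with "
                f"{len(self.conv_channels)} pooling layers"
            )

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "AgentConfig":
        """Full-size configuration: 128x128 input, 4 conv + 4 FC layers."""
        return cls(
            input_side=128,
            conv_channels=(32, 32, 64, 64),
            fc_widths=(256, 128, 64),
            seed=seed,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser settings (reference values, reduced iteration count)."""

    minibatch: int = 80
    learning_rate: float = 0.01
    momentum: float = 0.9
    decay_ratio: float = 0.8
    decay_interval: int = 10_000
    iterations: int = 3_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")
        if not (0 < self.decay_ratio <= 1):
            raise ValueError("decay_ratio must be in (0, 1]")

    def lr_at(self, iteration: int) -> float:
        """Learning rate in effect at a (0-based) iteration."""
        return self.learning_rate * self.decay_ratio ** (
            iteration // self.decay_interval
        )


def _encoder(cfg: AgentConfig, rng: np.random.Generator) -> Sequential:
    layers: list = []
    c_in = 1
    for c_out in cfg.conv_channels:
        # pool before ReLU: identical to ReLU-then-pool (both monotone),
        # but the activation then runs on the 4x smaller map
        layers += [Conv3x3(c_in, c_out, rng), MaxPool2(), ReLU()]
        if cfg.batch_norm:
            layers.append(BatchNorm(c_out, ndim=4))
        c_in = c_out
    layers.append(Flatten())
    return Sequential(layers)


class RewardAgent:
    """Maps a (fixed ROI, moving) image pair to six action rewards."""

    def __init__(self, cfg: AgentConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.enc_fixed = _encoder(cfg, rng)
        self.enc_moving = _encoder(cfg, rng)
        side_out = cfg.input_side // (2 ** len(cfg.conv_channels))
        feat = side_out * side_out * cfg.conv_channels[-1]
        layers: list = []
        n_in = 2 * feat
        for w in cfg.fc_widths:
            layers.append(Dense(n_in, w, rng))
            layers.append(ReLU())
            if cfg.batch_norm:
                layers.append(BatchNorm(w, ndim=2))
            n_in = w
        layers.append(Dense(n_in, cfg.n_actions, rng))
        self.head = Sequential(layers)

    # -- forward/backward -------------------------------------------------

    def forward(self, fixed: np.ndarray, moving: np.ndarray, train: bool) -> np.ndarray:
        f = self.enc_fixed.forward(fixed, train)
        m = self.enc_moving.forward(moving, train)
        self._feat_split = f.shape[1]
        return self.head.forward(np.concatenate([f, m], axis=1), train)

    def backward(self, grad_out: np.ndarray) -> None:
        g = self.head.backward(grad_out)
        self.enc_fixed.backward(g[:, : self._feat_split])
        self.enc_moving.backward(g[:, self._feat_split :])

    def params(self) -> list[np.ndarray]:
        return (
            self.enc_fixed.params() + self.enc_moving.params() + self.head.params()
        )

    def grads(self) -> list[np.ndarray]:
        return self.enc_fixed.grads() + self.enc_moving.grads() + self.head.grads()

    # -- inference ---------------------------------------------------------

    def predict_rewards(self, fixed: np.ndarray, moving: np.ndarray) -> RewardVector:
        """Deterministic inference (batch norm uses running statistics)."""
        s = self.cfg.input_side
        f = np.asarray(fixed, dtype=np.float32)
        m = np.asarray(moving, dtype=np.float32)
        if f.shape != (s, s) or m.shape != (s, s):
            raise ValueError(
                f"inputs must be {s}x{s}, got {f.shape} and {m.shape}"
            )
        out = self.forward(f[None, None], m[None, None], train=False)
        return RewardVector(rewards=out[0].astype(float))

    def as_policy(self):
        """Adapter to the ``register`` policy signature."""

        def policy(fixed_roi, moving, t):
            return self.predict_rewards(fixed_roi, moving).rewards

        return policy

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint parameters + config to an .npz file."""
        import json

        flat = {}

        def put(prefix, st):
            for k, v in st.items():
                if isinstance(v, dict):
                    put(f"{prefix}{k}/", v)
                else:
                    flat[f"{prefix}{k}"] = v

        put("enc_fixed/", self.enc_fixed.state())
        put("enc_moving/", self.enc_moving.state())
        put("head/", self.head.state())
        cfg = json.dumps(
            {
                "input_side": self.cfg.input_side,
                "conv_channels": list(self.cfg.conv_channels),
                "fc_widths": list(self.cfg.fc_widths),
                "n_actions": self.cfg.n_actions,
                "batch_norm": self.cfg.batch_norm,
                "seed": self.cfg.seed,
            }
        )
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8), **flat)

    @classmethod
    def load(cls, path) -> "RewardAgent":
        import json

        data = np.load(path)
        cfg_d = json.loads(bytes(data["__config__"]).decode())
        cfg = AgentConfig(
            input_side=cfg_d["input_side"],
            conv_channels=tuple(cfg_d["conv_channels"]),
            fc_widths=tuple(cfg_d["fc_widths"]),
            n_actions=cfg_d["n_actions"],
            batch_norm=cfg_d["batch_norm"],
            seed=cfg_d["seed"],
        )
        agent = cls(cfg)

        def take(prefix, seq: Sequential):
            st: dict = {}
            for key in data.files:
                if key.startswith(prefix):
                    parts = key[len(prefix) :].split("/")
                    d = st
                    for p in parts[:-1]:
                        d = d.setdefault(p, {})
                    d[parts[-1]] = data[key]
            seq.load_state(st)

        take("enc_fixed/", agent.enc_fixed)
        take("enc_moving/", agent.enc_moving)
        take("head/", agent.head)
        return agent


def build_agent(cfg: AgentConfig | None = None) -> RewardAgent:
    """Construct a reward agent (seed-deterministic initialisation)."""
    return RewardAgent(cfg if cfg is not None else AgentConfig())


@dataclass
class TrainHistory:
    iterations: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"iteration": self.iterations, "lr": self.lr, "loss": self.loss}
        ).to_csv(path, index=False)


def train_agent(
    agent: RewardAgent,
    samples: Sequence[TrainingSample],
    cfg: TrainConfig | None = None,
) -> TrainHistory:
    """Supervised reward regression (in-place training of ``agent``).

    Minimises the mean-squared error between predicted and exact reward
    vectors over seed-deterministic minibatches.  Returns the loss
    history (one entry per iteration).

    Raises
    ------
    ValueError
        If no samples are given.
    RuntimeError
        If the loss becomes non-finite.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    if len(samples) == 0:
        raise ValueError("no training samples")
    side = agent.cfg.input_side
    xf = np.stack([s.fixed_roi for s in samples]).astype(np.float32)[:, None]
    xm = np.stack([s.moving for s in samples]).astype(np.float32)[:, None]
    y = np.stack([s.label.rewards for s in samples]).astype(np.float32)
    if xf.shape[-1] != side:
        raise ValueError(f"samples are {xf.shape[-1]}px, agent expects {side}px")

    rng = np.random.default_rng(cfg.seed)
    opt = RMSProp(
        agent.params(),
        lr=cfg.learning_rate,
        momentum=cfg.momentum,
        decay_ratio=cfg.decay_ratio,
        decay_interval=cfg.decay_interval,
    )
    n = len(samples)
    history = TrainHistory()
    order = rng.permutation(n)
    cursor = 0
    for it in range(cfg.iterations):
        take = min(cfg.minibatch, n)
        if cursor + take > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor : cursor + take]
        cursor += take
        pred = agent.forward(xf[idx], xm[idx], train=True)
        diff = pred - y[idx]
        loss = float(np.mean(diff**2))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss at iteration {it} "
                f"(lr={opt.current_lr():.4g}); reduce the learning rate"
            )
        agent.backward((2.0 / diff.size) * diff.astype(np.float32))
        opt.step(agent.grads())
        history.iterations.append(it)
        history.lr.append(opt.current_lr(it))
        history.loss.append(loss)
    return history
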