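"""Customized 1-D convolutional GAN for unlabeled sequence corpora.

The generator stacks three stride-2 transpose convolutions (ReLU, ReLU, tanh)
on a learned projection of the noise vector; the discriminator stacks five
stride-1 same-padding convolutions (all ReLU, no batch normalization
anywhere) followed by a single tanh unit.  Because the discriminator output
lives in [-1, 1], training minimizes a least-squares loss against +1 (real)
and -1 (fake) targets.  After adversarial pre-training the discriminator's
fifth convolutional layer is used as a frozen per-position feature extractor.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import Adam, Conv1D, Conv1DTranspose, Dense, Flatten, Layer, Sequential
from .errors import ConfigError, InputError

__all__ = ["GanConfig", "GanCheckpoint", "build_generator", "build_discriminator",
           "train_gan", "extract_features", "generate"]


@dataclass(frozen=True)
class GanConfig:
    seq_len: int
    in_channels: int = 1  # 1 for label-encoded input, 25 for BLOSUM channels
    noise_dim: int = 100
    gen_filters: tuple[int, int, int] = (128, 64, -1)  # -1 -> in_channels
    disc_filters: tuple[int, int, int, int, int] = (4, 8, 16, 32, 64)
    kernel_size: int = 3
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.seq_len % 8 != 0:
            raise ConfigError("seq_len must be divisible by 8 (three stride-2 upsamplings)")
        if len(self.gen_filters) != 3 or len(self.disc_filters) != 5:
            raise ConfigError("expected 3 generator and 5 discriminator filter counts")
        if self.gen_filters[-1] == -1:
            object.__setattr__(self, "gen_filters",
                               (self.gen_filters[0], self.gen_filters[1], self.in_channels))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GanConfig":
        d = dict(d)
        d["gen_filters"] = tuple(d["gen_filters"])
        d["disc_filters"] = tuple(d["disc_filters"])
        return cls(**d)


class _Reshape(Layer):
    trainable = False

    def __init__(self, target_shape):
        super().__init__()
        self.target_shape = tuple(target_shape)

    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.target_shape)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


def _spec(model: Sequential) -> list[dict]:
    out = []
    for layer in model.layers:
        entry = {"kind": type(layer).__name__.lstrip("_")}
        for attr in ("filters", "kernel", "stride", "activation", "units", "in_dim"):
            if hasattr(layer, attr):
                entry[attr] = getattr(layer, attr)
        out.append(entry)
    return out


def build_generator(config: GanConfig, rng: np.random.Generator | None = None) -> Sequential:
    """Noise vector -> dense projection -> (seq_len/8, C) -> three stride-2
    transpose convolutions -> (seq_len, in_channels) in [-1, 1]."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    base_len = config.seq_len // 8
    f1, f2, f3 = config.gen_filters
    k = config.kernel_size
    model = Sequential([
        Dense(config.noise_dim, base_len * f1, rng=rng),
        _Reshape((base_len, f1)),
        Conv1DTranspose(f1, f1, k, stride=2, activation="relu", rng=rng),
        Conv1DTranspose(f1, f2, k, stride=2, activation="relu", rng=rng),
        Conv1DTranspose(f2, f3, k, stride=2, activation="tanh", rng=rng),
    ])
    model.spec = _spec(model)
    return model


def build_discriminator(config: GanConfig, rng: np.random.Generator | None = None) -> Sequential:
    """(seq_len, in_channels) -> five stride-1 same-padding ReLU convolutions
    with filters (4, 8, 16, 32, 64) -> flatten -> dense(1, tanh)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    k = config.kernel_size
    layers: list[Layer] = []
    in_ch = config.in_channels
    for f in config.disc_filters:
        layers.append(Conv1D(in_ch, f, k, stride=1, padding="same", activation="relu", rng=rng))
        in_ch = f
    layers.append(Flatten())
    layers.append(Dense(config.seq_len * config.disc_filters[-1], 1, activation="tanh", rng=rng))
    model = Sequential(layers)
    model.spec = _spec(model)
    return model


@dataclass
class GanCheckpoint:
    generator: Sequential
    discriminator: Sequential
    config: GanConfig
    corpus_hash: str
    history: list[dict] = field(default_factory=list)

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        arrays = {}
        for prefix, model in (("gen", self.generator), ("disc", self.discriminator)):
            for key, value in model.get_weights().items():
                arrays[f"{prefix}/{key}"] = value
        np.savez(os.path.join(directory, "params.npz"), **arrays)
        sidecar = {"config": self.config.to_dict(), "corpus_hash": self.corpus_hash,
                   "history": self.history}
        with open(os.path.join(directory, "checkpoint.json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, directory: str) -> "GanCheckpoint":
        with open(os.path.join(directory, "checkpoint.json")) as fh:
            sidecar = json.load(fh)
        config = GanConfig.from_dict(sidecar["config"])
        gen = build_generator(config)
        disc = build_discriminator(config)
        with np.load(os.path.join(directory, "params.npz")) as data:
            gen.set_weights({k[len("gen/"):]: data[k] for k in data.files if k.startswith("gen/")})
            disc.set_weights({k[len("disc/"):]: data[k] for k in data.files if k.startswith("disc/")})
        return cls(generator=gen, discriminator=disc, config=config,
                   corpus_hash=sidecar["corpus_hash"], history=sidecar.get("history", []))


def _as_batch(corpus, config: GanConfig) -> np.ndarray:
    x = np.asarray(corpus, dtype=np.float64)
    if x.ndim == 2:  # (N, L) single-channel shorthand
        x = x[:, :, None]
    if x.ndim != 3 or x.shape[1] != config.seq_len or x.shape[2] != config.in_channels:
        raise InputError(
            f"expected sequences of shape ({config.seq_len}, {config.in_channels}), "
            f"got {x.shape[1:] if x.ndim == 3 else x.shape}")
    return x


def corpus_fingerprint(x: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(x).tobytes()).hexdigest()


def train_gan(corpus, config: GanConfig) -> GanCheckpoint:
    """Adversarially train generator and discriminator with alternating 1:1
    updates and a least-squares loss against +/-1 targets.  Deterministic for
    a fixed config (seed included)."""
    if len(corpus) == 0:
        raise InputError("cannot train a GAN on an empty corpus")
    real = _as_batch(corpus, config)
    rng = np.random.default_rng(config.seed)
    gen = build_generator(config, np.random.default_rng(config.seed + 1))
    disc = build_discriminator(config, np.random.default_rng(config.seed + 2))
    opt_g = Adam([gen], lr=config.learning_rate)
    opt_d = Adam([disc], lr=config.learning_rate)

    history = []
    n = real.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for start in range(0, n, config.batch_size):
            batch = real[order[start : start + config.batch_size]]
            b = batch.shape[0]

            # discriminator step on real (+1) and fake (-1) targets
            z = rng.standard_normal((b, config.noise_dim))
            fake = gen(z)
            x = np.concatenate([batch, fake], axis=0)
            t = np.concatenate([np.ones((b, 1)), -np.ones((b, 1))], axis=0)
            d_out = disc.forward(x, train=True)
            d_loss = float(np.mean((d_out - t) ** 2))
            disc.backward(2.0 * (d_out - t) / x.shape[0])
            opt_d.step()

            # generator step: push D(G(z)) toward +1
            z = rng.standard_normal((b, config.noise_dim))
            fake = gen.forward(z, train=True)
            d_fake = disc.forward(fake, train=True)
            g_loss = float(np.mean((d_fake - 1.0) ** 2))
            d_grad = disc.backward(2.0 * (d_fake - 1.0) / b)
            gen.backward(d_grad)
            opt_g.step()

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise InputError("non-finite GAN loss encountered")
            d_losses.append(d_loss)
            g_losses.append(g_loss)
        history.append({"epoch": epoch,
                        "d_loss": float(np.mean(d_losses)),
                        "g_loss": float(np.mean(g_losses))})
    return GanCheckpoint(generator=gen, discriminator=disc, config=config,
                         corpus_hash=corpus_fingerprint(real), history=history)


def generate(checkpoint: GanCheckpoint, n: int, seed: int = 0) -> np.ndarray:
    """Sample n sequences from the trained generator."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, checkpoint.config.noise_dim))
    return checkpoint.generator(z)


def extract_features(checkpoint: GanCheckpoint, batch) -> np.ndarray:
    """Frozen activations of the discriminator's fifth convolutional layer.

    Returns an array of shape (batch, seq_len, 64) under default filters.
    """
    x = _as_batch(batch, checkpoint.config)
    n_convs = len(checkpoint.config.disc_filters)
    return checkpoint.discriminator.forward(x, train=False, upto=n_convs)
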