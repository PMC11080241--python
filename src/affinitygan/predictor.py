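"""Supervised affinity regressor assembled from sequence encoders, frozen GAN
features, two convolutional branches, add/concat fusion, and an FC head.

Three model variants differ only in the protein branch input:

* ``A`` — frozen GAN discriminator features over scaled label encodings for
  both protein and drug;
* ``B`` — raw BLOSUM channels for the protein, GAN features for the drug;
* ``C`` — GAN features computed over min-max-scaled BLOSUM channels for the
  protein, GAN features for the drug.

Each branch is three ReLU convolutions (filters 128/256/384, kernel 8 for
proteins and 4 for drugs) followed by a global max-pool, so both branches
emit equal-width vectors and elementwise add-fusion is well defined.  The
head is three fully-connected ReLU layers (1024/512/512) with dropout 0.25
after each, then a single linear output unit regressing pKd.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.neighbors import KNeighborsRegressor

from ._nn import Adam, Conv1D, Dense, Dropout, Embedding, GlobalMaxPool1D, Sequential
from .datasets import AffinityDataset
from .encoding import (BlosumMatrix, SequenceVocabulary, blosum_encode, build_vocabulary,
                       label_encode, load_blosum, scale_to_gan_range)
from .errors import ConfigError, InputError, StateError
from .gan import GanCheckpoint, extract_features

__all__ = ["PredictorConfig", "ModelVariant", "AffinityModel", "build_cnn_block",
           "fuse_latents", "assemble_model", "train_predictor", "predict_affinity",
           "train_baseline"]

_PROTEIN_MODES = ("dcgan_features_on_label", "blosum", "dcgan_features_on_blosum",
                  "label_embedding")
_DRUG_MODES = ("dcgan_features_on_label", "label_embedding")


@dataclass(frozen=True)
class PredictorConfig:
    protein_len: int = 2000
    smiles_len: int = 200
    cnn_filters: tuple[int, int, int] = (128, 256, 384)
    protein_kernel: int = 8
    drug_kernel: int = 4
    fc_units: tuple[int, int, int] = (1024, 512, 512)
    dropout: float = 0.25
    fusion: str = "add"
    learning_rate: float = 0.001
    batch_size: int = 256
    max_epochs: int = 300
    early_stopping_patience: int = 10
    embedding_dim: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.fusion not in ("add", "concat"):
            raise ConfigError(f"unknown fusion mode {self.fusion!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PredictorConfig":
        d = dict(d)
        for key in ("cnn_filters", "fc_units"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class ModelVariant:
    name: str
    protein_input: str
    drug_input: str = "dcgan_features_on_label"

    _CANONICAL = {
        "A": "dcgan_features_on_label",
        "B": "blosum",
        "C": "dcgan_features_on_blosum",
    }

    def __post_init__(self):
        if self.protein_input not in _PROTEIN_MODES:
            raise ConfigError(f"unknown protein input mode {self.protein_input!r}")
        if self.drug_input not in _DRUG_MODES:
            raise ConfigError(f"unknown drug input mode {self.drug_input!r}")

    @classmethod
    def from_name(cls, name: str) -> "ModelVariant":
        if name not in cls._CANONICAL:
            raise ConfigError(f"unknown variant {name!r}; expected A, B, or C")
        return cls(name=name, protein_input=cls._CANONICAL[name])

    @property
    def needs_protein_gan(self) -> bool:
        return self.protein_input.startswith("dcgan")

    @property
    def needs_drug_gan(self) -> bool:
        return self.drug_input.startswith("dcgan")


def build_cnn_block(branch: str, config: PredictorConfig, in_channels: int, *,
                    embedding_vocab: int | None = None,
                    rng: np.random.Generator) -> Sequential:
    """Three ReLU convolutions plus a global max-pool, yielding a fixed-width
    vector of length ``config.cnn_filters[-1]``.  If ``embedding_vocab`` is
    given the block starts with a trainable embedding over integer codes."""
    if branch not in ("protein", "drug"):
        raise ConfigError(f"unknown branch {branch!r}")
    kernel = config.protein_kernel if branch == "protein" else config.drug_kernel
    layers = []
    if embedding_vocab is not None:
        layers.append(Embedding(embedding_vocab, config.embedding_dim, rng=rng))
        in_channels = config.embedding_dim
    for f in config.cnn_filters:
        layers.append(Conv1D(in_channels, f, kernel, stride=1, padding="valid",
                             activation="relu", rng=rng))
        in_channels = f
    layers.append(GlobalMaxPool1D())
    model = Sequential(layers)
    model.branch = branch
    model.kernel = kernel
    return model


def fuse_latents(protein_vec: np.ndarray, drug_vec: np.ndarray, mode: str) -> np.ndarray:
    """add -> elementwise sum (equal lengths required); concat -> juxtaposition."""
    protein_vec = np.asarray(protein_vec)
    drug_vec = np.asarray(drug_vec)
    if mode == "add":
        if protein_vec.shape[-1] != drug_vec.shape[-1]:
            raise InputError("add fusion requires equal-length latent vectors")
        return protein_vec + drug_vec
    if mode == "concat":
        return np.concatenate([protein_vec, drug_vec], axis=-1)
    raise ConfigError(f"unknown fusion mode {mode!r}")


class AffinityModel:
    """Two-branch convolutional regressor with frozen GAN feature inputs."""

    def __init__(self, variant: ModelVariant, config: PredictorConfig,
                 protein_gan: GanCheckpoint | None, drug_gan: GanCheckpoint | None,
                 protein_vocab: SequenceVocabulary | None,
                 smiles_vocab: SequenceVocabulary | None,
                 blosum: BlosumMatrix | None):
        self.variant = variant
        self.config = config
        self.protein_gan = protein_gan
        self.drug_gan = drug_gan
        self.protein_vocab = protein_vocab
        self.smiles_vocab = smiles_vocab
        self.blosum = blosum
        self.trained = False
        self.history: list[dict] = []

        rng = np.random.default_rng(config.seed)
        p_channels, p_embed = self._branch_input_shape("protein")
        d_channels, d_embed = self._branch_input_shape("drug")
        self.protein_branch = build_cnn_block("protein", config, p_channels,
                                              embedding_vocab=p_embed, rng=rng)
        self.drug_branch = build_cnn_block("drug", config, d_channels,
                                           embedding_vocab=d_embed, rng=rng)
        width = config.cnn_filters[-1]
        fused = width if config.fusion == "add" else 2 * width
        head_layers = []
        in_dim = fused
        for units in config.fc_units:
            head_layers.append(Dense(in_dim, units, activation="relu", rng=rng))
            head_layers.append(Dropout(config.dropout))
            in_dim = units
        head_layers.append(Dense(in_dim, 1, activation="linear", rng=rng))
        self.head = Sequential(head_layers)

    # -- construction helpers -------------------------------------------------

    def _branch_input_shape(self, branch: str):
        """(in_channels, embedding_vocab_or_None) for a branch's CNN block."""
        mode = self.variant.protein_input if branch == "protein" else self.variant.drug_input
        if mode == "blosum":
            return 25, None
        if mode == "label_embedding":
            vocab = self.protein_vocab if branch == "protein" else self.smiles_vocab
            return 0, vocab.unknown_index + 1
        gan = self.protein_gan if branch == "protein" else self.drug_gan
        return gan.config.disc_filters[-1], None

    # -- input pipelines ------------------------------------------------------

    def encode_proteins(self, seqs: list[str]) -> np.ndarray:
        mode = self.variant.protein_input
        L = self.config.protein_len
        if mode == "blosum":
            return np.stack([blosum_encode(s, self.blosum, L).matrix.T for s in seqs])
        if mode == "label_embedding":
            return np.stack([label_encode(s, self.protein_vocab, L).values for s in seqs])
        if mode == "dcgan_features_on_label":
            x = np.stack([scale_to_gan_range(label_encode(s, self.protein_vocab, L),
                                             self.protein_vocab) for s in seqs])[:, :, None]
        else:  # dcgan_features_on_blosum: min-max scale scores to [-1, 1]
            lo, hi = self.blosum.scores.min(), self.blosum.scores.max()
            mats = np.stack([blosum_encode(s, self.blosum, L).matrix.T for s in seqs])
            x = 2.0 * (mats - lo) / (hi - lo) - 1.0
        return self._gan_features(self.protein_gan, x)

    def encode_drugs(self, seqs: list[str]) -> np.ndarray:
        L = self.config.smiles_len
        if self.variant.drug_input == "label_embedding":
            return np.stack([label_encode(s, self.smiles_vocab, L).values for s in seqs])
        x = np.stack([scale_to_gan_range(label_encode(s, self.smiles_vocab, L),
                                         self.smiles_vocab) for s in seqs])[:, :, None]
        return self._gan_features(self.drug_gan, x)

    @staticmethod
    def _gan_features(checkpoint: GanCheckpoint, x: np.ndarray, chunk: int = 64) -> np.ndarray:
        return np.concatenate([extract_features(checkpoint, x[i : i + chunk])
                               for i in range(0, len(x), chunk)])

    def dataset_inputs(self, dataset: AffinityDataset):
        """Encode each unique entity once and gather per record."""
        pids = sorted({r.protein_id for r in dataset.records})
        dids = sorted({r.drug_id for r in dataset.records})
        p_feat = self.encode_proteins([dataset.protein_seqs[p] for p in pids])
        d_feat = self.encode_drugs([dataset.drug_seqs[d] for d in dids])
        p_pos = {p: i for i, p in enumerate(pids)}
        d_pos = {d: i for i, d in enumerate(dids)}
        Xp = p_feat[[p_pos[r.protein_id] for r in dataset.records]]
        Xd = d_feat[[d_pos[r.drug_id] for r in dataset.records]]
        return Xp, Xd

    # -- forward / backward ---------------------------------------------------

    def forward(self, Xp, Xd, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        hp = self.protein_branch.forward(Xp, train=train, rng=rng)
        hd = self.drug_branch.forward(Xd, train=train, rng=rng)
        fused = fuse_latents(hp, hd, self.config.fusion)
        return self.head.forward(fused, train=train, rng=rng)[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        dfused = self.head.backward(dpred[:, None])
        if self.config.fusion == "add":
            dhp, dhd = dfused, dfused
        else:
            width = self.config.cnn_filters[-1]
            dhp, dhd = dfused[:, :width], dfused[:, width:]
        self.protein_branch.backward(dhp)
        self.drug_branch.backward(dhd)

    # -- bookkeeping ----------------------------------------------------------

    @property
    def submodels(self) -> list[Sequential]:
        return [self.protein_branch, self.drug_branch, self.head]

    def num_params(self) -> int:
        """Trainable parameter count (frozen GAN weights excluded)."""
        return sum(m.num_params() for m in self.submodels)

    def get_weights(self) -> dict[str, np.ndarray]:
        return {f"{name}/{k}": v
                for name, m in zip(("protein", "drug", "head"), self.submodels)
                for k, v in m.get_weights().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, m in zip(("protein", "drug", "head"), self.submodels):
            prefix = name + "/"
            m.set_weights({k[len(prefix):]: v for k, v in weights.items()
                           if k.startswith(prefix)})

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        np.savez(os.path.join(directory, "params.npz"), **self.get_weights())
        provenance = {
            "variant": asdict(self.variant),
            "config": self.config.to_dict(),
            "trained": self.trained,
            "protein_vocab": self.protein_vocab.to_dict() if self.protein_vocab else None,
            "smiles_vocab": self.smiles_vocab.to_dict() if self.smiles_vocab else None,
            "history": self.history,
        }
        with open(os.path.join(directory, "model.json"), "w") as fh:
            json.dump(provenance, fh, indent=2)


def load_model(directory: str, protein_gan: GanCheckpoint | None = None,
               drug_gan: GanCheckpoint | None = None) -> AffinityModel:
    """Rebuild a saved model; GAN checkpoints must be supplied separately for
    variants that need them (they are stored in their own directories)."""
    with open(os.path.join(directory, "model.json")) as fh:
        prov = json.load(fh)
    variant = ModelVariant(**prov["variant"])
    config = PredictorConfig.from_dict(prov["config"])
    pv = SequenceVocabulary.from_dict(prov["protein_vocab"]) if prov["protein_vocab"] else None
    sv = SequenceVocabulary.from_dict(prov["smiles_vocab"]) if prov["smiles_vocab"] else None
    model = assemble_model(variant, config, protein_gan=protein_gan, drug_gan=drug_gan,
                           protein_vocab=pv, smiles_vocab=sv)
    with np.load(os.path.join(directory, "params.npz")) as data:
        model.set_weights({k: data[k] for k in data.files})
    model.trained = bool(prov.get("trained", False))
    model.history = prov.get("history", [])
    return model


def assemble_model(variant: ModelVariant, config: PredictorConfig,
                   protein_gan: GanCheckpoint | None = None,
                   drug_gan: GanCheckpoint | None = None,
                   protein_vocab: SequenceVocabulary | None = None,
                   smiles_vocab: SequenceVocabulary | None = None,
                   blosum: BlosumMatrix | None = None) -> AffinityModel:
    """Wire encoders, frozen GAN checkpoints, CNN branches and the FC head."""
    if variant.needs_protein_gan:
        if protein_gan is None:
            raise ConfigError(f"variant {variant.name} requires a protein GAN checkpoint")
        if protein_gan.config.seq_len != config.protein_len:
            raise ConfigError("protein GAN seq_len does not match protein_len")
    if variant.needs_drug_gan:
        if drug_gan is None:
            raise ConfigError(f"variant {variant.name} requires a drug GAN checkpoint")
        if drug_gan.config.seq_len != config.smiles_len:
            raise ConfigError("drug GAN seq_len does not match smiles_len")
    needs_blosum = "blosum" in variant.protein_input
    if needs_blosum and blosum is None:
        blosum = load_blosum()
    needs_protein_vocab = variant.protein_input in ("dcgan_features_on_label", "label_embedding")
    if needs_protein_vocab and protein_vocab is None:
        raise ConfigError("protein vocabulary required for label-encoded protein input")
    if smiles_vocab is None:
        raise ConfigError("smiles vocabulary required")
    return AffinityModel(variant, config, protein_gan, drug_gan,
                         protein_vocab, smiles_vocab, blosum)


def train_predictor(model: AffinityModel, train: AffinityDataset, val: AffinityDataset,
                    config: PredictorConfig | None = None):
    """Minimize MSE with Adam; early-stop on validation MSE and restore the
    best-validation weights.  Deterministic given the config seed."""
    config = config if config is not None else model.config
    if len(train) == 0 or len(val) == 0:
        raise InputError("train and validation sets must be non-empty")
    y_tr, y_val = train.affinities, val.affinities
    if not (np.isfinite(y_tr).all() and np.isfinite(y_val).all()):
        raise InputError("affinity labels must be finite")

    Xp_tr, Xd_tr = model.dataset_inputs(train)
    Xp_val, Xd_val = model.dataset_inputs(val)

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.submodels, lr=config.learning_rate)
    best_mse, best_weights, stall = np.inf, model.get_weights(), 0
    history = []
    n = len(y_tr)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        train_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            pred = model.forward(Xp_tr[idx], Xd_tr[idx], train=True, rng=rng)
            err = pred - y_tr[idx]
            train_losses.append(float(np.mean(err ** 2)))
            model.backward(2.0 * err / idx.size)
            opt.step()
        val_pred = _predict_batched(model, Xp_val, Xd_val, config.batch_size)
        val_mse = float(np.mean((val_pred - y_val) ** 2))
        history.append({"epoch": epoch, "train_mse": float(np.mean(train_losses)),
                        "val_mse": val_mse})
        if val_mse < best_mse:
            best_mse, best_weights, stall = val_mse, model.get_weights(), 0
        else:
            stall += 1
            if stall >= config.early_stopping_patience:
                break
    model.set_weights(best_weights)
    model.trained = True
    model.history = history
    return model, history


def _predict_batched(model: AffinityModel, Xp, Xd, batch_size: int) -> np.ndarray:
    return np.concatenate([model.forward(Xp[i : i + batch_size], Xd[i : i + batch_size])
                           for i in range(0, len(Xp), batch_size)])


def predict_affinity(model: AffinityModel, pairs: list[tuple[str, str]]) -> np.ndarray:
    """Predict pKd for raw (protein sequence, SMILES) pairs."""
    if not model.trained:
        raise StateError("model has not been trained")
    proteins = [p for p, _ in pairs]
    drugs = [d for _, d in pairs]
    Xp = model.encode_proteins(proteins)
    Xd = model.encode_drugs(drugs)
    return _predict_batched(model, Xp, Xd, model.config.batch_size)


# -- straw-model baselines ----------------------------------------------------


def _label_features(dataset: AffinityDataset, protein_vocab, smiles_vocab,
                    protein_len: int, smiles_len: int) -> np.ndarray:
    rows = []
    for r in dataset.records:
        p = label_encode(dataset.protein_seqs[r.protein_id], protein_vocab, protein_len).values
        d = label_encode(dataset.drug_seqs[r.drug_id], smiles_vocab, smiles_len).values
        rows.append(np.concatenate([p, d]))
    return np.asarray(rows, dtype=np.float64)


def train_baseline(kind: str, train: AffinityDataset, test: AffinityDataset,
                   params: dict | None = None) -> np.ndarray:
    """Control baselines on label-encoded inputs: 'fc' trains the FC head
    alone; 'knn' predicts the mean affinity of the k nearest training pairs
    under Euclidean distance over concatenated encodings."""
    params = dict(params or {})
    protein_len = params.pop("protein_len", 2000)
    smiles_len = params.pop("smiles_len", 200)
    pv = params.pop("protein_vocab", None) or build_vocabulary(
        sorted(train.protein_seqs.values()), "protein")
    sv = params.pop("smiles_vocab", None) or build_vocabulary(
        sorted(train.drug_seqs.values()), "smiles")
    X_tr = _label_features(train, pv, sv, protein_len, smiles_len)
    X_te = _label_features(test, pv, sv, protein_len, smiles_len)
    y_tr = train.affinities

    if kind == "knn":
        k = int(params.pop("k", 5))
        if k > len(train):
            raise ConfigError(f"k={k} exceeds training-set size {len(train)}")
        knn = KNeighborsRegressor(n_neighbors=k, metric="euclidean")
        knn.fit(X_tr, y_tr)
        return knn.predict(X_te)

    if kind == "fc":
        fc_units = tuple(params.pop("fc_units", (1024, 512, 512)))
        dropout = float(params.pop("dropout", 0.25))
        lr = float(params.pop("learning_rate", 0.001))
        epochs = int(params.pop("epochs", 30))
        batch_size = int(params.pop("batch_size", 256))
        seed = int(params.pop("seed", 0))
        rng = np.random.default_rng(seed)
        layers, in_dim = [], X_tr.shape[1]
        for units in fc_units:
            layers.append(Dense(in_dim, units, activation="relu", rng=rng))
            layers.append(Dropout(dropout))
            in_dim = units
        layers.append(Dense(in_dim, 1, activation="linear", rng=rng))
        net = Sequential(layers)
        opt = Adam([net], lr=lr)
        n = len(y_tr)
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                pred = net.forward(X_tr[idx], train=True, rng=rng)[:, 0]
                net.backward((2.0 * (pred - y_tr[idx]) / idx.size)[:, None])
                opt.step()
        return net.forward(X_te)[:, 0]

    raise ConfigError(f"unknown baseline kind {kind!r}")
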