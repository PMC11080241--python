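import numpy as np
import pytest

import affinitygan as ag

GAN_SEQ_LEN = 32
SMILES_LEN = 40
PROTEIN_LEN = 64


@pytest.fixture(scope="session")
def tiny_corpus():
    """64 scaled label-encoded protein sequences of length 32 (1 channel)."""
    seqs = ag.generate_corpus("protein", 64, (28, GAN_SEQ_LEN), seed=7)
    vocab = ag.build_vocabulary(seqs, "protein")
    x = np.stack([ag.scale_to_gan_range(ag.label_encode(s, vocab, GAN_SEQ_LEN), vocab)
                  for s in seqs])[:, :, None]
    return x


@pytest.fixture(scope="session")
def tiny_gan_config():
    return ag.GanConfig(seq_len=GAN_SEQ_LEN, in_channels=1, epochs=5, batch_size=16, seed=0)


@pytest.fixture(scope="session")
def trained_gan(tiny_corpus, tiny_gan_config):
    return ag.train_gan(tiny_corpus, tiny_gan_config)


@pytest.fixture(scope="session")
def small_dataset():
    """400-pair planted-signal dataset for fast predictor tests."""
    return ag.generate_dataset(ag.SyntheticConfig(n_proteins=20, n_drugs=30,
                                                  n_pairs=400, seed=5))


def desk_predictor_config(**overrides) -> ag.PredictorConfig:
    """Reduced-width configuration for desk-scale training runs."""
    base = dict(protein_len=PROTEIN_LEN, smiles_len=SMILES_LEN,
                cnn_filters=(16, 32, 48), fc_units=(64, 32, 32), batch_size=128,
                max_epochs=32, early_stopping_patience=8, learning_rate=0.001, seed=0)
    base.update(overrides)
    return ag.PredictorConfig(**base)


def train_drug_gan(dataset: ag.AffinityDataset, seed: int,
                   epochs: int = 8) -> tuple[ag.GanCheckpoint, ag.SequenceVocabulary]:
    smiles = sorted(dataset.drug_seqs.values())
    vocab = ag.build_vocabulary(smiles, "smiles")
    x = np.stack([ag.scale_to_gan_range(ag.label_encode(s, vocab, SMILES_LEN), vocab)
                  for s in smiles])[:, :, None]
    ck = ag.train_gan(x, ag.GanConfig(seq_len=SMILES_LEN, epochs=epochs,
                                      batch_size=16, seed=seed))
    return ck, vocab


def train_protein_gan(dataset: ag.AffinityDataset, seed: int, in_channels: int = 1,
                      epochs: int = 8) -> tuple[ag.GanCheckpoint, ag.SequenceVocabulary]:
    proteins = sorted(dataset.protein_seqs.values())
    vocab = ag.build_vocabulary(proteins, "protein")
    if in_channels == 25:
        matrix = ag.load_blosum()
        lo, hi = matrix.scores.min(), matrix.scores.max()
        mats = np.stack([ag.blosum_encode(s, matrix, PROTEIN_LEN).matrix.T
                         for s in proteins])
        x = 2.0 * (mats - lo) / (hi - lo) - 1.0
    else:
        x = np.stack([ag.scale_to_gan_range(ag.label_encode(s, vocab, PROTEIN_LEN), vocab)
                      for s in proteins])[:, :, None]
    ck = ag.train_gan(x, ag.GanConfig(seq_len=PROTEIN_LEN, in_channels=in_channels,
                                      epochs=epochs, batch_size=16, seed=seed + 50))
    return ck, vocab


def run_variant(variant_name: str, seed: int, straw_mode: str | None = None,
                n_pairs: int = 2000, dataset_seed_base: int = 100) -> float:
    """Train one variant on the planted-signal dataset and return the test CI.

    Mirrors the adversarial-control protocol: an optional straw shuffle of
    train/test/both affinities before training.
    """
    ds = ag.generate_dataset(ag.SyntheticConfig(n_pairs=n_pairs,
                                                seed=dataset_seed_base + seed))
    drug_gan, smiles_vocab = train_drug_gan(ds, seed)
    variant = ag.ModelVariant.from_name(variant_name)
    protein_gan = protein_vocab = None
    if variant.needs_protein_gan:
        channels = 25 if "blosum" in variant.protein_input else 1
        protein_gan, protein_vocab = train_protein_gan(ds, seed, in_channels=channels)
    elif variant.protein_input == "label_embedding":
        protein_vocab = ag.build_vocabulary(sorted(ds.protein_seqs.values()), "protein")

    split = ag.kfold_split(ds, k=5, seed=seed)[0]
    if straw_mode:
        ds = ag.shuffle_straw(ds, split, straw_mode, seed=seed)
    cfg = desk_predictor_config(seed=seed)
    model = ag.assemble_model(variant, cfg, protein_gan=protein_gan, drug_gan=drug_gan,
                              protein_vocab=protein_vocab, smiles_vocab=smiles_vocab)
    train_ds, test_ds = ds.subset(split.train), ds.subset(split.test)
    model, _ = ag.train_predictor(model, train_ds, test_ds, cfg)
    Xp, Xd = model.dataset_inputs(test_ds)
    preds = model.forward(Xp, Xd)
    return ag.concordance_index(test_ds.affinities, preds)
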