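"""Desk-scale synthetic corpora and labeled datasets with a planted,
recoverable drug x protein interaction signal.

The affinity of a (drug, protein) pair is

    pKd = mu + beta * count(motif in protein) * [pharmacophore in drug] + noise

clipped to a pKd-like range, so the signal is learnable by short-kernel
convolutions, invisible to a mean predictor, and destroyed by label
shuffling.  A deterministic per-drug logP surrogate supports cold-start
splitting without a chemistry engine.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np

from .datasets import AffinityDataset, AffinityRecord
from .encoding import PROTEIN_ALPHABET
from .errors import ConfigError, InputError

__all__ = ["SyntheticConfig", "generate_corpus", "generate_dataset",
           "compute_logp_surrogate", "write_bundle"]

_ATOMS = "CNOcno"


@dataclass(frozen=True)
class SyntheticConfig:
    n_proteins: int = 40
    n_drugs: int = 60
    n_pairs: int = 2000
    protein_len_range: tuple[int, int] = (40, 60)
    smiles_len_range: tuple[int, int] = (24, 40)
    motif: str = "HQWFY"
    pharmacophore: str = "NC=O"
    effect_size: float = 2.0     # beta
    baseline: float = 6.0        # mu
    noise_sd: float = 0.3        # sigma
    affinity_clip: tuple[float, float] = (4.0, 11.0)
    seed: int = 0

    def __post_init__(self):
        if self.protein_len_range[0] > self.protein_len_range[1] or \
           self.smiles_len_range[0] > self.smiles_len_range[1]:
            raise ConfigError("length ranges must be non-empty")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_pairs > self.n_proteins * self.n_drugs:
            raise ConfigError("n_pairs exceeds the number of distinct (drug, protein) pairs")

    def to_dict(self) -> dict:
        return asdict(self)


def _random_smiles(rng: np.random.Generator, length: int) -> str:
    """Syntactically tidy SMILES-like string: balanced parentheses, matched
    ring digits, '=' always followed by an atom."""
    out: list[str] = []
    while len(out) < length:
        budget = length - len(out)
        choices = ["atom"]
        if budget >= 2:
            choices.append("double")
        if budget >= 3:
            choices.append("branch")
        if budget >= 4:
            choices.append("ring")
        pick = choices[rng.integers(len(choices))]
        if pick == "atom":
            out.append(_ATOMS[rng.integers(6)])
        elif pick == "double":
            out += ["=", _ATOMS[rng.integers(6)]]
        elif pick == "branch":
            inner = int(min(budget - 2, 1 + rng.integers(3)))
            out.append("(")
            out += [_ATOMS[rng.integers(6)] for _ in range(inner)]
            out.append(")")
        else:
            digit = "12"[int(rng.integers(2))]
            inner = int(min(budget - 4, rng.integers(3)))
            out += [_ATOMS[rng.integers(6)], digit]
            out += [_ATOMS[rng.integers(6)] for _ in range(inner)]
            out += [_ATOMS[rng.integers(6)], digit]
    return "".join(out)


def generate_corpus(kind: str, n: int, len_range: tuple[int, int], seed: int = 0) -> list[str]:
    """Random unlabeled sequences: uniform 25-letter proteins, or SMILES-like
    strings over {C, N, O, c, n, o, =, (, ), 1, 2}."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    if kind not in ("protein", "smiles"):
        raise ConfigError(f"unknown corpus kind {kind!r}")
    lo, hi = len_range
    if lo > hi or lo < 1:
        raise ConfigError("invalid length range")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        if kind == "protein":
            out.append("".join(rng.choice(list(PROTEIN_ALPHABET), size=length)))
        else:
            out.append(_random_smiles(rng, length))
    return out


def compute_logp_surrogate(smiles: str) -> float:
    """Deterministic lipophilicity stand-in:
    0.5*#{C,c} - 0.3*#{O,o} - 0.3*#{N,n}."""
    if not smiles:
        raise InputError("empty SMILES string")
    carbons = smiles.count("C") + smiles.count("c")
    oxygens = smiles.count("O") + smiles.count("o")
    nitrogens = smiles.count("N") + smiles.count("n")
    return round(0.5 * carbons - 0.3 * oxygens - 0.3 * nitrogens, 10)


def _plant_protein(rng: np.random.Generator, seq: str, motif: str, copies: int) -> str:
    chars = list(seq)
    m = len(motif)
    if copies * m > len(chars):
        copies = len(chars) // m
    # non-overlapping slots
    slots = np.arange(0, len(chars) - m + 1)
    placed = 0
    taken: list[int] = []
    for _ in range(100):
        if placed == copies:
            break
        pos = int(rng.choice(slots))
        if all(abs(pos - t) >= m for t in taken):
            chars[pos : pos + m] = list(motif)
            taken.append(pos)
            placed += 1
    return "".join(chars)


def generate_dataset(config: SyntheticConfig) -> AffinityDataset:
    """Sample proteins with 0-2 planted motif copies, drugs with/without the
    pharmacophore, then label random distinct pairs with the planted
    interaction signal plus Gaussian noise."""
    rng = np.random.default_rng(config.seed)
    motif, pharm = config.motif, config.pharmacophore

    proteins = {}
    base = generate_corpus("protein", config.n_proteins, config.protein_len_range,
                           seed=config.seed + 1)
    for i, seq in enumerate(base):
        copies = int(rng.integers(0, 3))  # 0, 1 or 2 motif copies
        proteins[f"P{i:04d}"] = _plant_protein(rng, seq, motif, copies)

    drugs = {}
    base = generate_corpus("smiles", config.n_drugs, config.smiles_len_range,
                           seed=config.seed + 2)
    for i, seq in enumerate(base):
        if rng.random() < 0.5 and len(seq) >= len(pharm):
            # prepend the pharmacophore, trimming to keep the length
            seq = pharm + seq[: len(seq) - len(pharm)]
        drugs[f"D{i:04d}"] = seq

    pids, dids = list(proteins), list(drugs)
    total = len(pids) * len(dids)
    flat = rng.choice(total, size=config.n_pairs, replace=False)
    lo, hi = config.affinity_clip
    records = []
    for f in flat:
        di, pi = divmod(int(f), len(pids))
        d_id, p_id = dids[di], pids[pi]
        # recompute the signal from the emitted sequences, so the formula is exact
        signal = config.effect_size * proteins[p_id].count(motif) * \
            (1.0 if pharm in drugs[d_id] else 0.0)
        y = config.baseline + signal + rng.normal(0.0, config.noise_sd)
        records.append(AffinityRecord(d_id, p_id, float(np.clip(y, lo, hi))))

    logp = {d: compute_logp_surrogate(s) for d, s in drugs.items()}
    return AffinityDataset(records=records, drug_seqs=drugs, protein_seqs=proteins,
                           logp=logp)


def write_bundle(dataset: AffinityDataset, directory: str,
                 config: SyntheticConfig | None = None) -> None:
    """Write FASTA proteins, one-per-line SMILES, affinity and logP TSVs, and
    a JSON manifest of the generating parameters."""
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "proteins.fasta"), "w") as fh:
        for pid, seq in dataset.protein_seqs.items():
            fh.write(f">{pid}\n{seq}\n")
    with open(os.path.join(directory, "drugs.smi"), "w") as fh:
        for did, seq in dataset.drug_seqs.items():
            fh.write(f"{seq}\t{did}\n")
    with open(os.path.join(directory, "affinities.tsv"), "w") as fh:
        fh.write("drug_id\tprotein_id\taffinity\n")
        for r in dataset.records:
            fh.write(f"{r.drug_id}\t{r.protein_id}\t{r.affinity:.6f}\n")
    if dataset.logp is not None:
        with open(os.path.join(directory, "logp.tsv"), "w") as fh:
            fh.write("drug_id\tlogp\n")
            for did, v in dataset.logp.items():
                fh.write(f"{did}\t{v:.6f}\n")
    manifest = {"n_records": len(dataset), "n_proteins": len(dataset.protein_seqs),
                "n_drugs": len(dataset.drug_seqs)}
    if config is not None:
        manifest["config"] = config.to_dict()
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
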