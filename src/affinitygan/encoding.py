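"""Sequence encoders: label encoding, GAN input scaling, and BLOSUM encoding.

Proteins and drug SMILES are both treated as plain character strings.  Label
encoding maps each character to a small integer (0 reserved for padding, one
extra index for unseen characters); BLOSUM encoding maps each protein residue
to its 25-dimensional substitution-matrix row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ConfigError, InputError

__all__ = [
    "SequenceVocabulary",
    "LabelEncodedSequence",
    "BlosumMatrix",
    "BlosumEncodedProtein",
    "build_vocabulary",
    "label_encode",
    "label_decode",
    "scale_to_gan_range",
    "load_blosum",
    "blosum_encode",
    "PROTEIN_ALPHABET",
    "SMILES_TOKENS",
]

#: Canonical 25-letter residue alphabet (order fixed by the bundled matrix).
PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZXUO"

#: Character set used for synthetic SMILES-like strings.
SMILES_TOKENS = "CNOcno=()12"

PAD_INDEX = 0


@dataclass(frozen=True)
class SequenceVocabulary:
    """Character-to-index map with pad index 0 and a trailing unknown index."""

    kind: str  # 'protein' | 'smiles'
    symbol_to_index: dict[str, int]

    def __post_init__(self):
        indices = sorted(self.symbol_to_index.values())
        if indices != list(range(1, len(indices) + 1)):
            raise ConfigError("vocabulary indices must be contiguous 1..|symbols|")

    @property
    def unknown_index(self) -> int:
        return len(self.symbol_to_index) + 1

    @property
    def pad_index(self) -> int:
        return PAD_INDEX

    def index_of(self, ch: str) -> int:
        return self.symbol_to_index.get(ch, self.unknown_index)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "symbol_to_index": dict(self.symbol_to_index)}

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceVocabulary":
        return cls(kind=d["kind"], symbol_to_index={k: int(v) for k, v in d["symbol_to_index"].items()})


@dataclass(frozen=True)
class LabelEncodedSequence:
    values: np.ndarray  # int vector of length max_len
    original_length: int


@dataclass(frozen=True)
class BlosumMatrix:
    alphabet: str            # 25 distinct characters, ordered
    scores: np.ndarray       # 25 x 25 integer matrix, symmetric
    _row_of: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if len(self.alphabet) != 25 or len(set(self.alphabet)) != 25:
            raise ConfigError("BLOSUM alphabet must have 25 distinct characters")
        if self.scores.shape != (25, 25):
            raise ConfigError("BLOSUM score matrix must be 25x25")
        if not np.array_equal(self.scores, self.scores.T):
            raise ConfigError("BLOSUM score matrix must be symmetric")
        object.__setattr__(self, "_row_of", {c: i for i, c in enumerate(self.alphabet)})

    def row(self, residue: str) -> np.ndarray:
        """Substitution row for a residue; unlisted characters fall back to 'X'."""
        i = self._row_of.get(residue, self._row_of["X"])
        return self.scores[i]


@dataclass(frozen=True)
class BlosumEncodedProtein:
    matrix: np.ndarray  # 25 x max_len
    original_length: int


def build_vocabulary(corpus: list[str], kind: str) -> SequenceVocabulary:
    """Build a vocabulary from the sorted set of characters observed in ``corpus``.

    Indices are assigned in sorted character order starting at 1; index 0 is
    reserved for padding and index ``|symbols| + 1`` for unseen characters.
    """
    if kind not in ("protein", "smiles"):
        raise ConfigError(f"unknown vocabulary kind {kind!r}")
    if not corpus:
        raise InputError("cannot build a vocabulary from an empty corpus")
    if any(not s for s in corpus):
        raise InputError("corpus contains an empty string")
    symbols = sorted({ch for s in corpus for ch in s})
    return SequenceVocabulary(kind=kind, symbol_to_index={c: i + 1 for i, c in enumerate(symbols)})


def label_encode(seq: str, vocab: SequenceVocabulary, max_len: int) -> LabelEncodedSequence:
    """Integer-encode ``seq``, right-truncated at ``max_len``, right-padded with 0."""
    if max_len < 1:
        raise ConfigError("max_len must be >= 1")
    values = np.zeros(max_len, dtype=np.int64)
    for j, ch in enumerate(seq[:max_len]):
        values[j] = vocab.index_of(ch)
    return LabelEncodedSequence(values=values, original_length=len(seq))


def label_decode(encoded: LabelEncodedSequence, vocab: SequenceVocabulary) -> str:
    """Inverse of :func:`label_encode` for in-vocabulary, non-truncated input."""
    index_to_symbol = {i: c for c, i in vocab.symbol_to_index.items()}
    out = []
    for v in encoded.values:
        if v == vocab.pad_index:
            break
        out.append(index_to_symbol.get(int(v), "?"))
    return "".join(out)


def scale_to_gan_range(encoded: LabelEncodedSequence, vocab: SequenceVocabulary) -> np.ndarray:
    """Affinely map integer codes from [0, unknown_index] to [-1, 1]."""
    values = encoded.values
    if values.min() < 0 or values.max() > vocab.unknown_index:
        raise InputError("encoded values outside [0, unknown_index]")
    return 2.0 * values / vocab.unknown_index - 1.0


def load_blosum(path=None) -> BlosumMatrix:
    """Load a plain-text square substitution matrix (bundled 25-letter BLOSUM62
    extension by default: standard 20 residues plus B, Z, X, U, O)."""
    if path is None:
        text = resources.files("affinitygan.data").joinpath("blosum62x25.txt").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    alphabet = "".join(lines[0].split())
    rows = []
    for ln in lines[1:]:
        parts = ln.split()
        if parts[0] != alphabet[len(rows)]:
            raise ConfigError("matrix row labels do not match the header alphabet")
        rows.append([int(v) for v in parts[1:]])
    return BlosumMatrix(alphabet=alphabet, scores=np.asarray(rows, dtype=np.int64))


def blosum_encode(protein: str, matrix: BlosumMatrix, max_len: int) -> BlosumEncodedProtein:
    """Encode a protein as a 25 x max_len matrix of substitution rows.

    Column j holds the matrix row of residue j (characters outside the
    25-letter alphabet use the 'X' row); columns past the sequence are zero.
    """
    if max_len < 1:
        raise ConfigError("max_len must be >= 1")
    out = np.zeros((25, max_len), dtype=np.float64)
    for j, ch in enumerate(protein[:max_len]):
        out[:, j] = matrix.row(ch)
    return BlosumEncodedProtein(matrix=out, original_length=len(protein))
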