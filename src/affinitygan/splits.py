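"""Warm-start folds, logP-based cold-start splits, and straw-model shuffles."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .datasets import AffinityDataset
from .errors import ConfigError, InputError

__all__ = ["SplitResult", "kfold_split", "cold_start_logp_split", "shuffle_straw",
           "quantile_interval"]


@dataclass(frozen=True)
class SplitResult:
    train: tuple[int, ...]
    test: tuple[int, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.train) & set(self.test):
            raise ConfigError("train and test indices overlap")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SplitResult":
        d = json.loads(text)
        return cls(train=tuple(d["train"]), test=tuple(d["test"]),
                   provenance=d.get("provenance", {}))


def kfold_split(dataset: AffinityDataset, k: int = 5, seed: int = 0) -> list[SplitResult]:
    """Record-level random partition into k folds of near-equal size.

    Fold i's test set is fold i, its train set is everything else.  Drugs and
    proteins may recur across folds (warm start).
    """
    n = len(dataset)
    if k < 2:
        raise ConfigError("k must be >= 2")
    if k > n:
        raise ConfigError(f"k={k} exceeds the number of records ({n})")
    order = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(order, k)
    results = []
    for i, fold in enumerate(folds):
        test = np.sort(fold)
        train = np.sort(np.concatenate([f for j, f in enumerate(folds) if j != i]))
        results.append(SplitResult(
            train=tuple(int(x) for x in train),
            test=tuple(int(x) for x in test),
            provenance={"rule": "kfold", "k": k, "fold": i, "seed": seed}))
    return results


def cold_start_logp_split(dataset: AffinityDataset, logp: dict[str, float] | None = None,
                          test_interval: tuple[float, float] = (0.0, np.inf)) -> SplitResult:
    """Hold out every record whose drug's logP falls in [lo, hi).

    All records of a held-out drug go to test, so the train and test drug
    sets are disjoint by construction.
    """
    logp = logp if logp is not None else dataset.logp
    if logp is None:
        raise InputError("no logP table available")
    lo, hi = test_interval
    if not lo < hi:
        raise ConfigError("test interval must satisfy lo < hi")
    train, test = [], []
    for i, rec in enumerate(dataset.records):
        if rec.drug_id not in logp:
            raise InputError(f"missing logP for drug {rec.drug_id!r}")
        (test if lo <= logp[rec.drug_id] < hi else train).append(i)
    if not test or not train:
        raise ConfigError(
            f"degenerate cold-start split: {len(train)} train / {len(test)} test records")
    return SplitResult(train=tuple(train), test=tuple(test),
                       provenance={"rule": "cold_logp", "lo": float(lo),
                                   "hi": float(hi) if np.isfinite(hi) else "inf"})


def quantile_interval(logp: dict[str, float], top_fraction: float) -> tuple[float, float]:
    """[q, inf) interval holding out the drugs with the highest logP values."""
    if not 0.0 < top_fraction < 1.0:
        raise ConfigError("top_fraction must be in (0, 1)")
    values = np.asarray(sorted(logp.values()))
    q = float(np.quantile(values, 1.0 - top_fraction))
    return (q, np.inf)


def shuffle_straw(dataset: AffinityDataset, split: SplitResult, mode: str,
                  seed: int = 0) -> AffinityDataset:
    """Permute affinity values within the selected partition(s) of a split.

    mode 'train' shuffles labels among train records, 'test' among test
    records, 'both' applies independent permutations to each.  Drug/protein
    assignments are untouched and the per-partition multiset of affinities is
    preserved exactly.
    """
    if mode not in ("train", "test", "both"):
        raise ConfigError(f"invalid straw mode {mode!r}")
    rng = np.random.default_rng(seed)
    y = dataset.affinities.copy()
    partitions = []
    if mode in ("train", "both"):
        partitions.append(np.asarray(split.train, dtype=np.intp))
    if mode in ("test", "both"):
        partitions.append(np.asarray(split.test, dtype=np.intp))
    for idx in partitions:
        if idx.size == 0:
            raise InputError("cannot shuffle an empty partition")
        y[idx] = y[idx][rng.permutation(idx.size)]
    return dataset.with_affinities(y)
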