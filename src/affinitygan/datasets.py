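"""Labeled affinity dataset container shared by the splitters and the predictor."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = ["AffinityRecord", "AffinityDataset"]


@dataclass(frozen=True)
class AffinityRecord:
    drug_id: str
    protein_id: str
    affinity: float  # pKd


@dataclass
class AffinityDataset:
    """(drug, protein, pKd) records plus sequence lookup tables and optional logP."""

    records: list[AffinityRecord]
    drug_seqs: dict[str, str]
    protein_seqs: dict[str, str]
    logp: dict[str, float] | None = field(default=None)

    def __post_init__(self):
        for r in self.records:
            if r.drug_id not in self.drug_seqs:
                raise InputError(f"record references unknown drug_id {r.drug_id!r}")
            if r.protein_id not in self.protein_seqs:
                raise InputError(f"record references unknown protein_id {r.protein_id!r}")
            if not np.isfinite(r.affinity):
                raise InputError(f"non-finite affinity for pair ({r.drug_id}, {r.protein_id})")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def affinities(self) -> np.ndarray:
        return np.asarray([r.affinity for r in self.records], dtype=np.float64)

    def subset(self, indices) -> "AffinityDataset":
        recs = [self.records[i] for i in indices]
        return AffinityDataset(records=recs, drug_seqs=self.drug_seqs,
                               protein_seqs=self.protein_seqs, logp=self.logp)

    def with_affinities(self, values) -> "AffinityDataset":
        values = np.asarray(values, dtype=np.float64)
        if len(values) != len(self.records):
            raise InputError("affinity vector length mismatch")
        recs = [AffinityRecord(r.drug_id, r.protein_id, float(v))
                for r, v in zip(self.records, values)]
        return AffinityDataset(records=recs, drug_seqs=self.drug_seqs,
                               protein_seqs=self.protein_seqs, logp=self.logp)
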