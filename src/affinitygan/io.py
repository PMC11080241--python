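"""Strict readers and writers for the plain-text formats the pipeline uses.

TSV is the canonical tabular dialect (UTF-8, '#' comment lines ignored).
Readers reject malformed input instead of coercing it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import AffinityDataset, AffinityRecord
from .errors import FormatError

__all__ = ["read_fasta", "read_smiles", "read_affinity_table", "read_logp_table",
           "load_affinity_dataset", "write_history_tsv"]


def read_fasta(path: str) -> list[tuple[str, str]]:
    """Parse FASTA records, concatenating wrapped sequence lines.

    The first non-blank line must be a '>' header; every record must carry a
    non-empty sequence.
    """
    records: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                header = line[1:].strip()
                ident = header.split()[0] if header else ""
                if not ident:
                    raise FormatError(f"{path}: FASTA header with no identifier")
                records.append((ident, []))
            else:
                if not records:
                    raise FormatError(f"{path}: sequence data before the first FASTA header")
                records[-1][1].append(line.strip())
    out = []
    for ident, chunks in records:
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: record {ident!r} has an empty sequence")
        out.append((ident, seq))
    return out


def read_smiles(path: str) -> list[tuple[str, str]]:
    """One SMILES per line, optionally followed by a tab and an identifier.
    Missing identifiers become positional ids D0000, D0001, ..."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            if not smiles:
                raise FormatError(f"{path}: empty SMILES on line {i + 1}")
            ident = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"D{i:04d}"
            out.append((ident, smiles))
    return out


def _read_tsv(path: str, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def _parse_float_column(df: pd.DataFrame, column: str, path: str) -> np.ndarray:
    values = pd.to_numeric(df[column], errors="coerce").to_numpy(dtype=np.float64)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        row = int(bad[0]) + 2  # 1-based, counting the header line
        raise FormatError(f"{path}: non-numeric {column} {df[column].iloc[bad[0]]!r} "
                          f"on row {row}")
    return values


def read_affinity_table(path: str) -> list[AffinityRecord]:
    """TSV with header columns drug_id, protein_id, affinity (pKd)."""
    df = _read_tsv(path, ["drug_id", "protein_id", "affinity"])
    affinities = _parse_float_column(df, "affinity", path)
    return [AffinityRecord(str(d), str(p), float(a))
            for d, p, a in zip(df["drug_id"], df["protein_id"], affinities)]


def read_logp_table(path: str) -> dict[str, float]:
    """TSV with header columns drug_id, logp; duplicate ids are rejected."""
    df = _read_tsv(path, ["drug_id", "logp"])
    dupes = df["drug_id"][df["drug_id"].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate drug_id(s) {sorted(set(dupes))}")
    values = _parse_float_column(df, "logp", path)
    return {str(d): float(v) for d, v in zip(df["drug_id"], values)}


def load_affinity_dataset(affinity_path: str, fasta_path: str, smiles_path: str,
                          logp_path: str | None = None) -> AffinityDataset:
    records = read_affinity_table(affinity_path)
    proteins = dict(read_fasta(fasta_path))
    drugs = dict(read_smiles(smiles_path))
    logp = read_logp_table(logp_path) if logp_path else None
    return AffinityDataset(records=records, drug_seqs=drugs, protein_seqs=proteins,
                           logp=logp)


def write_history_tsv(history: list[dict], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\ttrain_mse\tval_mse\n")
        for row in history:
            fh.write(f"{row['epoch']}\t{row['train_mse']:.8f}\t{row['val_mse']:.8f}\n")
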