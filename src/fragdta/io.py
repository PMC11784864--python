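"""Readers and writers for the field's plain-text formats.

SMILES come from one-per-line ``.smi`` files (optional identifier after
whitespace) or CSV columns; protein sequences from FASTA (via Biopython) or
CSV columns; labelled pairs from CSV/TSV tables with columns
``drug_id, target_id, smiles, sequence, label``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .model import PairRecord
from .sequences import Alphabet, BioSequence

__all__ = ["read_smi", "read_fasta", "read_pairs", "write_pairs"]


def read_smi(path) -> list[BioSequence]:
    """Read a one-SMILES-per-line file; a second whitespace-separated field
    is taken as the identifier."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            ident = parts[1] if len(parts) > 1 else f"D{i}"
            out.append(BioSequence(text=parts[0], kind=Alphabet.DRUG_SMILES, ident=ident))
    return out


def read_fasta(path) -> list[BioSequence]:
    """Read protein sequences from a FASTA file."""
    return [
        BioSequence(text=str(rec.seq), kind=Alphabet.PROTEIN_SEQ, ident=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_pairs(path) -> list[PairRecord]:
    """Read a labelled pair table (CSV, or TSV for .tsv/.tab suffixes)."""
    sep = "\t" if Path(path).suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    required = {"smiles", "sequence", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"pair table needs columns {sorted(required)}, has {list(df.columns)}")
    pairs = []
    for row in df.itertuples(index=False):
        drug = BioSequence(
            text=row.smiles, kind=Alphabet.DRUG_SMILES,
            ident=str(getattr(row, "drug_id", "")),
        )
        target = BioSequence(
            text=row.sequence, kind=Alphabet.PROTEIN_SEQ,
            ident=str(getattr(row, "target_id", "")),
        )
        pairs.append(PairRecord(drug=drug, target=target, label=float(row.label)))
    return pairs


def write_pairs(pairs: list[PairRecord], path) -> None:
    pd.DataFrame(
        {
            "drug_id": [p.drug.ident for p in pairs],
            "target_id": [p.target.ident for p in pairs],
            "smiles": [p.drug.text for p in pairs],
            "sequence": [p.target.text for p in pairs],
            "label": [p.label for p in pairs],
        }
    ).to_csv(path, index=False)
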