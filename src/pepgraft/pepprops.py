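"""Sequence-level peptide utilities: molecular weight, alanine scans, tables.

Molecular weight is the average (isotope-abundance weighted) mass of the
free, unmodified peptide: the sum of average residue masses plus one water
(18.0153 g/mol).  The residue-mass table is the standard average-mass table
(g/mol); it can be overridden per call for non-standard conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import pandas as pd

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "PeptideRecord",
    "peptide_mw",
    "alanine_mutant",
    "read_peptide_table",
    "write_peptide_table",
    "read_fasta",
    "write_fasta",
    "bundled_peptide_table",
]

#: Average residue (amino-acid minus water) masses, g/mol.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MASS = 18.0153


def peptide_mw(sequence: str, mass_table: dict[str, float] | None = None) -> float:
    """Average molecular weight (g/mol) of a free, unmodified peptide."""
    table = AVERAGE_RESIDUE_MASS if mass_table is None else mass_table
    if not sequence:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for i, letter in enumerate(sequence.upper()):
        try:
            total += table[letter]
        except KeyError:
            raise ValueError(
                f"non-standard residue {letter!r} at position {i + 1}") from None
    return total


@dataclass
class PeptideRecord:
    name: str
    sequence: str
    mw: float = 0.0
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.name!r}: empty sequence")
        if not self.sequence.isupper():
            warnings.warn(f"record {self.name!r}: sequence uppercased")
            self.sequence = self.sequence.upper()
        if self.mw <= 0.0:
            self.mw = peptide_mw(self.sequence)


def alanine_mutant(record: PeptideRecord, position: int) -> PeptideRecord:
    """Point mutant with 1-based ``position`` set to alanine.

    The mutant is named wild-type letter + position + 'A' (e.g. ``W3A``).
    Mutating a position that is already alanine returns the record unchanged
    with a warning.
    """
    seq = record.sequence
    if not 1 <= position <= len(seq):
        raise IndexError(f"position {position} outside 1..{len(seq)}")
    wt = seq[position - 1]
    if wt == "A":
        warnings.warn(f"{record.name}: position {position} is already alanine; no-op")
        return replace(record)
    new_seq = seq[: position - 1] + "A" + seq[position:]
    return PeptideRecord(name=f"{wt}{position}A", sequence=new_seq,
                         annotations={**record.annotations, "parent": record.name})


# ---------------------------------------------------------------------------
# Tables

_TSV_COLS = ["name", "sequence", "mw"]


def write_peptide_table(records: list[PeptideRecord], path) -> None:
    rows = []
    for r in records:
        row = {"name": r.name, "sequence": r.sequence, "mw": round(r.mw, 4)}
        row.update(r.annotations)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _records_from_frame(df: pd.DataFrame) -> list[PeptideRecord]:
    if df["name"].duplicated().any():
        dups = df["name"][df["name"].duplicated()].tolist()
        raise ValueError(f"duplicate peptide names: {dups}")
    extra = [c for c in df.columns if c not in _TSV_COLS]
    out = []
    for _, row in df.iterrows():
        ann = {c: row[c] for c in extra if pd.notna(row[c])}
        if "mw" in df.columns and pd.notna(row["mw"]):
            ann["printed_mw"] = float(row["mw"])  # as-published, never trusted
        out.append(PeptideRecord(name=str(row["name"]), sequence=str(row["sequence"]),
                                 annotations=ann))
    return out


def read_peptide_table(path) -> list[PeptideRecord]:
    """Read a TSV of peptides (columns: name, sequence, mw, extras → annotations).

    The mw column is recomputed from the sequence, never trusted."""
    return _records_from_frame(pd.read_csv(path, sep="\t", dtype=str))


def write_fasta(records: list[PeptideRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.name}\n{r.sequence}\n")


def read_fasta(path) -> list[PeptideRecord]:
    records: list[PeptideRecord] = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(PeptideRecord(name=name, sequence="".join(chunks)))
                name, chunks = line[1:].split()[0], []
            else:
                chunks.append(line)
    if name is not None:
        records.append(PeptideRecord(name=name, sequence="".join(chunks)))
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate names in FASTA")
    return records


def bundled_peptide_table() -> list[PeptideRecord]:
    """The PD-1-binder peptide panel shipped with the package (15 records:
    four five-anchor designs, five alanine mutants of the best binder, and
    six alternative-anchor designs).  KD and purity annotations are
    experimental values carried as metadata, never computed."""
    with resources.as_file(resources.files("pepgraft") / "data" / "paper_peptides.tsv") as p:
        return read_peptide_table(p)
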