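"""FASTA input/output and integer encoding of protein sequences.

Two alphabets are managed here:

* the 23-symbol encoding alphabet ``X,A,C,...,W,Y`` mapped to the integer
  codes 0..22 used to build the 2-D grid for moment computation, and
* the 20 standard amino acids, alphabetically ordered, which index every
  20-length vector (frequency, AAPIV, RAAPIV) and 20x20 matrix (PRIM,
  RPRIM) downstream.

Ambiguity codes (B, J, Z) and any other letter outside the 23-symbol table
are treated as the unknown symbol X (code 0).
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: 23-symbol encoding alphabet; the code of a symbol is its index here.
ENCODING_ALPHABET = "XACDEFGHIKLMNOPQRSTUVWY"

#: code lookup for the 23 symbols
ENCODING_TABLE: dict[str, int] = {aa: i for i, aa in enumerate(ENCODING_ALPHABET)}

#: the 20 standard amino acids, alphabetically ordered ("from A to Y");
#: indexes all 20-length vectors and 20x20 matrices.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

STANDARD_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(STANDARD_AMINO_ACIDS)}


@dataclass(frozen=True)
class ProteinSequence:
    """A single protein record: identifier plus upper-case residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if not all(c in string.ascii_uppercase for c in self.residues):
            bad = sorted({c for c in self.residues if c not in string.ascii_uppercase})
            raise ValueError(
                f"record {self.id!r} contains non-letter characters: {bad}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reversed(self) -> "ProteinSequence":
        return ProteinSequence(self.id, self.residues[::-1])


def encode_sequence(seq: ProteinSequence) -> list[int]:
    """Map residues to the 0..22 integer codes.

    Letters outside the 23-symbol table (B, J, Z, ...) map to 0, the code
    of the unknown symbol X. Length is preserved.
    """
    return [ENCODING_TABLE.get(c, 0) for c in seq.residues]


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a (possibly line-wrapped, multi-record) FASTA file.

    Sequence lines are concatenated, whitespace stripped, and letters
    upper-cased. Raises on a missing file, an empty sequence, or a
    duplicated record identifier.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id: {rec.id!r}")
        seen.add(rec.id)
        residues = "".join(str(rec.seq).split()).upper()
        if not residues:
            raise ValueError(f"empty sequence for record {rec.id!r}")
        out.append(ProteinSequence(rec.id, residues))
    return out


def write_fasta(sequences: list[ProteinSequence], path: str | Path) -> None:
    """Write records to FASTA, preserving order."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV ``sequence_id<TAB>label`` with labels in {0,1}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sid, lab = parts
            if lab not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {lab!r}")
            if sid in labels:
                raise ValueError(f"{path}:{lineno}: duplicate id {sid!r}")
            labels[sid] = int(lab)
    return labels


def write_labels(labels: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")
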