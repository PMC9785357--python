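"""Protein records and FASTA input.

Sequences are uppercased on load and a single trailing stop symbol ``*`` is
stripped. The 20 standard one-letter residue codes plus ``X`` (unknown) are
accepted; anything else is rejected with the offending position so malformed
proteomes fail loudly rather than silently dropping hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_RESIDUES = STANDARD_RESIDUES | {"X"}


class SequenceError(ValueError):
    """Raised when a sequence contains a character outside the residue alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: FASTA id, free-text description, residue string."""

    id: str
    description: str
    sequence: str
    length: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "length", len(self.sequence))

    @classmethod
    def from_raw(cls, id: str, sequence: str, description: str = "") -> "ProteinRecord":
        seq = sequence.upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        validate_sequence(seq)
        return cls(id=id, description=description, sequence=seq)


def validate_sequence(seq: str) -> None:
    """Check every character is a standard residue or X (1-based position in errors)."""
    for i, ch in enumerate(seq):
        if ch not in ALLOWED_RESIDUES:
            raise SequenceError(
                f"invalid residue {ch!r} at position {i + 1} (1-based)"
            )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Load a multi-record protein FASTA (wrapped or unwrapped)."""
    records = []
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        try:
            records.append(
                ProteinRecord.from_raw(rec.id, str(rec.seq), rec.description)
            )
        except SequenceError as exc:
            raise SequenceError(f"record {idx} ({rec.id}): {exc}") from exc
    return records


def write_fasta(records: Iterator[ProteinRecord] | list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
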