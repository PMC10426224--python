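"""FASTA input/output with strict per-alphabet validation.

Records are plain dataclasses; residues are stored uppercase with no gaps or
whitespace.  Three alphabets are supported:

``protein``
    The 20 standard amino acids plus ``B``, ``Z``, ``U``, ``X``.  A ``*``
    (stop) is tolerated on input but stripped with a warning.
``dna``
    ``ACGT`` plus the IUPAC ambiguity codes and ``N``.  A ``U`` in the input
    is normalized to ``T`` and the record is flagged.
``rna``
    ``ACGU`` plus ``T`` (tolerated, since guide RNAs are routinely written
    with DNA letters) and the IUPAC ambiguity codes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "ALPHABETS",
    "SequenceRecord",
    "FastaError",
    "read_fasta",
    "write_fasta",
]

_IUPAC_AMBIG = "RYSWKMBDHVN"

ALPHABETS: dict[str, frozenset[str]] = {
    "protein": frozenset("ACDEFGHIKLMNPQRSTVWY" + "BZUX"),
    "dna": frozenset("ACGT" + _IUPAC_AMBIG),
    "rna": frozenset("ACGUT" + _IUPAC_AMBIG),
}


class FastaError(ValueError):
    """Raised for malformed FASTA input or invalid records."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry: identifier, free-text description, residues."""

    id: str
    description: str
    alphabet: str
    residues: str
    u_normalized: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.alphabet not in ALPHABETS:
            raise FastaError(f"unknown alphabet {self.alphabet!r}")
        if not self.residues:
            raise FastaError(f"record {self.id!r} has no residues")
        _validate(self.id, self.residues, self.alphabet)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_protein(self) -> bool:
        return self.alphabet == "protein"

    @property
    def is_nucleotide(self) -> bool:
        return self.alphabet in ("dna", "rna")


def _validate(record_id: str, residues: str, alphabet: str) -> None:
    allowed = ALPHABETS[alphabet]
    for pos, char in enumerate(residues):
        if char not in allowed:
            raise FastaError(
                f"record {record_id!r}: illegal character {char!r} at "
                f"position {pos} for alphabet {alphabet!r}"
            )


def _normalize(record_id: str, raw: str, alphabet: str) -> tuple[str, bool]:
    seq = "".join(raw.split()).upper()
    if "*" in seq:
        warnings.warn(
            f"record {record_id!r}: stripped {seq.count('*')} '*' character(s)",
            stacklevel=3,
        )
        seq = seq.replace("*", "")
    u_normalized = False
    if alphabet == "dna" and "U" in seq:
        seq = seq.replace("U", "T")
        u_normalized = True
    return seq, u_normalized


def read_fasta(path: str | Path, alphabet: str) -> list[SequenceRecord]:
    """Read all records from a FASTA file, validating against *alphabet*.

    Records are returned in file order.  Raises :class:`FastaError` for an
    empty file, an empty sequence, a duplicate identifier, or any character
    outside the declared alphabet (the error names the record, position and
    character).
    """
    if alphabet not in ALPHABETS:
        raise FastaError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, raw in SimpleFastaParser(handle):
            parts = header.split(None, 1)
            rid = parts[0] if parts else ""
            if not rid:
                raise FastaError(f"{path}: record with empty header")
            if rid in seen:
                raise FastaError(f"{path}: duplicate record id {rid!r}")
            seen.add(rid)
            desc = parts[1] if len(parts) > 1 else ""
            seq, u_norm = _normalize(rid, raw, alphabet)
            if not seq:
                raise FastaError(f"{path}: record {rid!r} has no residues")
            records.append(
                SequenceRecord(
                    id=rid,
                    description=desc,
                    alphabet=alphabet,
                    residues=seq,
                    u_normalized=u_norm,
                )
            )
    if not records:
        raise FastaError(f"{path}: no records found")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write records to *path*; round-trip stable with :func:`read_fasta`."""
    records = list(records)
    if not records:
        raise FastaError("refusing to write an empty FASTA file")
    if line_width < 1:
        raise ValueError("line_width must be positive")
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(rec.residues), line_width):
                handle.write(rec.residues[i : i + line_width] + "\n")
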