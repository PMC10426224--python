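"""Guide-RNA vs microRNA similarity screen with an E < 0.01 gate.

Both query and database sequences are T-normalized; each database entry is
aligned on the given strand and its reverse complement and the better of the
two alignments is reported.  Scoring uses the nucleotide scheme
(match +5 / mismatch -4, gaps 10/6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .align import (
    EValueContext,
    KarlinAltschulParams,
    LocalAlignment,
    ScoringScheme,
    evalue,
    smith_waterman,
)
from .hits import ScreenRule, parse_subject_metadata
from .seqio import SequenceRecord

__all__ = ["RnaHit", "rna_screen", "reverse_complement", "spacer"]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(residues: str) -> str:
    """Reverse complement of a T-normalized nucleotide string."""
    return residues.replace("U", "T").translate(_COMPLEMENT)[::-1]


def spacer(grna: SequenceRecord, length: int = 20) -> SequenceRecord:
    """The 5' target-recognition portion of a guide RNA."""
    if len(grna) < length:
        raise ValueError(f"guide {grna.id!r} shorter than spacer ({length})")
    return SequenceRecord(id=f"{grna.id}_spacer", description=grna.description,
                          alphabet=grna.alphabet,
                          residues=grna.residues[:length])


def _t_normalized(record: SequenceRecord) -> SequenceRecord:
    if not record.is_nucleotide:
        raise ValueError(f"record {record.id!r} is not a nucleotide sequence")
    if "U" not in record.residues:
        return record
    return SequenceRecord(id=record.id, description=record.description,
                          alphabet="dna",
                          residues=record.residues.replace("U", "T"),
                          u_normalized=True)


@dataclass(frozen=True)
class RnaHit:
    """Best alignment of the guide against one microRNA (either strand)."""

    mirna_id: str
    species: str
    strand: str  # "+" or "-"
    alignment: LocalAlignment
    evalue: float
    significant: bool


def rna_screen(
    grna: SequenceRecord,
    mirna_db: list[SequenceRecord],
    rule: ScreenRule,
    ctx: EValueContext | None = None,
    scheme: ScoringScheme | None = None,
) -> list[RnaHit]:
    """Screen a guide RNA against a microRNA set; E < ``rule.evalue_max_rna``
    marks significance.  Returns one hit per microRNA, sorted by E."""
    if not mirna_db:
        warnings.warn(f"empty microRNA database for {grna.id!r}", stacklevel=2)
        return []
    if scheme is None:
        scheme = ScoringScheme.nuc()
    params = KarlinAltschulParams.for_scheme(scheme)
    query = _t_normalized(grna)
    if ctx is None:
        ctx = EValueContext.from_db(len(query), mirna_db)

    hits: list[RnaHit] = []
    for mirna in mirna_db:
        fwd_rec = _t_normalized(mirna)
        rev_rec = SequenceRecord(id=mirna.id, description=mirna.description,
                                 alphabet="dna",
                                 residues=reverse_complement(mirna.residues))
        fwd = smith_waterman(query, fwd_rec, scheme)
        rev = smith_waterman(query, rev_rec, scheme)
        aln, strand = (fwd, "+") if fwd.score >= rev.score else (rev, "-")
        e = evalue(aln.score, params, ctx)
        _, species, _ = parse_subject_metadata(mirna)
        hits.append(RnaHit(mirna_id=mirna.id, species=species, strand=strand,
                           alignment=aln, evalue=e,
                           significant=e < rule.evalue_max_rna))
    hits.sort(key=lambda h: (h.evalue, h.mirna_id))
    return hits
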