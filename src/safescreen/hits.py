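"""Shared report-row types and the full-length screening engine."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .align import (
    EValueContext,
    KarlinAltschulParams,
    LocalAlignment,
    ScoringScheme,
    evalue,
    percent_identity,
    smith_waterman,
)
from .seqio import SequenceRecord

__all__ = ["ScreenRule", "ScreenHit", "parse_subject_metadata",
           "full_length_screen"]


@dataclass(frozen=True)
class ScreenRule:
    """Significance thresholds for the tiered screens.

    Defaults: >=35% identity over >=80 alignment columns, 80-residue sliding
    window, 8-mer epitopes, E <= 10 for protein candidate hits and E < 0.01
    for RNA hits.
    """

    identity_threshold: float = 35.0
    min_segment: int = 80
    window: int = 80
    kmer: int = 8
    evalue_max_protein: float = 10.0
    evalue_max_rna: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 100:
            raise ValueError("identity_threshold must be in (0, 100]")
        if self.min_segment < 1 or self.kmer < 1 or self.window < 1:
            raise ValueError("min_segment, window and kmer must be >= 1")
        if self.evalue_max_protein <= 0 or self.evalue_max_rna <= 0:
            raise ValueError("E-value ceilings must be positive")


def parse_subject_metadata(record: SequenceRecord) -> tuple[str, str, str]:
    """Split a database record into (accession, organism, description).

    Supports the ``id|organism|description`` header convention, either in
    the id token itself or as ``organism|description`` in the free-text
    description; absent fields become empty strings.
    """
    if "|" in record.id:
        parts = record.id.split("|", 2)
        acc = parts[0]
        organism = parts[1] if len(parts) > 1 else ""
        desc = parts[2] if len(parts) > 2 else record.description
        return acc, organism, desc
    if "|" in record.description:
        organism, desc = record.description.split("|", 1)
        return record.id, organism.strip(), desc.strip()
    return record.id, "", record.description


@dataclass(frozen=True)
class ScreenHit:
    """One database match with Table-style statistics and a verdict flag."""

    accession: str
    organism: str
    description: str
    subject_length: int
    evalue: float
    percent_identity: float
    alignment_length: int
    significant: bool
    comment: str = ""
    alignment: LocalAlignment | None = field(default=None, compare=False,
                                             repr=False)

    def with_comment(self, comment: str) -> "ScreenHit":
        return replace(self, comment=comment)


def full_length_screen(
    query: SequenceRecord,
    db: list[SequenceRecord],
    scheme: ScoringScheme,
    rule: ScreenRule,
    ctx: EValueContext | None = None,
    params: KarlinAltschulParams | None = None,
) -> list[ScreenHit]:
    """Best full-length local alignment per subject, E-gated and flagged.

    One hit per subject with ``E <= rule.evalue_max_protein``, sorted by E
    ascending; ``significant`` follows the identity/segment-length rule.
    """
    if not db:
        warnings.warn(f"empty database for query {query.id!r}", stacklevel=2)
        return []
    if ctx is None:
        ctx = EValueContext.from_db(len(query), db)
    if params is None:
        params = KarlinAltschulParams.for_scheme(scheme)

    hits: list[ScreenHit] = []
    for subject in db:
        aln = smith_waterman(query, subject, scheme)
        e = evalue(aln.score, params, ctx)
        if e > rule.evalue_max_protein:
            continue
        pid = percent_identity(aln) if not aln.is_empty else 0.0
        acc, organism, desc = parse_subject_metadata(subject)
        hits.append(ScreenHit(
            accession=acc, organism=organism, description=desc,
            subject_length=len(subject), evalue=e, percent_identity=pid,
            alignment_length=aln.columns,
            significant=(pid >= rule.identity_threshold
                         and aln.columns >= rule.min_segment),
            alignment=aln,
        ))
    hits.sort(key=lambda h: (h.evalue, h.accession))
    return hits
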