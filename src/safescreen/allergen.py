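"""Three-tier allergenicity screen.

Tier 1 -- full-length local alignment against every database entry, with the
35%-identity-over->=80-columns significance rule.
Tier 2 -- stride-1 sliding windows (default 80 residues) of the query, each
aligned against every database entry and flagged under the same rule (the
segment requirement degrades to the window length for short queries).
Tier 3 -- exact contiguous k-mer scan (default 8-mers) of the query against
every database entry; k-mer matches are reported unconditionally, with no
E-value gate.
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
    percent_identity,
    smith_waterman,
)
from .hits import ScreenHit, ScreenRule, full_length_screen
from .seqio import SequenceRecord

__all__ = [
    "ScreenRule",
    "EpitopeMatch",
    "WindowHit",
    "count_kmer_windows",
    "kmer_epitope_scan",
    "sliding_window_screen",
    "full_length_allergen_screen",
]


@dataclass(frozen=True)
class EpitopeMatch:
    """One shared k-mer between the query and one database subject.

    Positions are 0-based starts of every occurrence, sorted ascending.
    """

    kmer_string: str
    subject_id: str
    query_positions: tuple[int, ...]
    subject_positions: tuple[int, ...]


@dataclass(frozen=True)
class WindowHit:
    """Best alignment of one query window against one subject."""

    window_start: int
    window_length: int
    alignment: LocalAlignment
    evalue: float
    flagged: bool


def count_kmer_windows(seq: SequenceRecord, k: int) -> int:
    """Number of stride-1 length-*k* windows: ``max(len - k + 1, 0)``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(seq) - k + 1
    if n < 1:
        warnings.warn(
            f"record {seq.id!r} shorter than k={k}; no windows", stacklevel=2)
        return 0
    return n


def _kmer_positions(residues: str, k: int) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i in range(len(residues) - k + 1):
        kmer = residues[i:i + k]
        if "X" in kmer:
            continue
        out.setdefault(kmer, []).append(i)
    return out


def kmer_epitope_scan(query: SequenceRecord, db: list[SequenceRecord],
                      k: int) -> list[EpitopeMatch]:
    """Exact matches of every length-*k* query substring against *db*.

    Returns one :class:`EpitopeMatch` per distinct (k-mer, subject) pair
    carrying all occurrence positions, ordered by subject then k-mer.
    K-mers containing ``X`` never match.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if query.alphabet != "protein":
        raise ValueError("epitope scan expects a protein query")
    if not db:
        warnings.warn(f"empty database for query {query.id!r}", stacklevel=2)
        return []

    query_kmers = _kmer_positions(query.residues, k)
    matches: list[EpitopeMatch] = []
    for subject in db:
        subject_kmers = _kmer_positions(subject.residues, k)
        shared = sorted(query_kmers.keys() & subject_kmers.keys())
        for kmer in shared:
            matches.append(EpitopeMatch(
                kmer_string=kmer,
                subject_id=subject.id,
                query_positions=tuple(query_kmers[kmer]),
                subject_positions=tuple(subject_kmers[kmer]),
            ))
    matches.sort(key=lambda m: (m.subject_id, m.kmer_string))
    return matches


def sliding_window_screen(
    query: SequenceRecord,
    db: list[SequenceRecord],
    scheme: ScoringScheme,
    rule: ScreenRule,
    params: KarlinAltschulParams | None = None,
) -> list[WindowHit]:
    """Align every stride-1 window of the query to every subject.

    A query shorter than ``rule.window`` yields one full-length window.  A
    window is flagged when its best alignment to a subject reaches the
    identity threshold over at least ``min(rule.min_segment, window_length)``
    columns.  Only hits with ``E <= rule.evalue_max_protein`` are returned
    (E computed with the window length as query size).
    """
    if not db:
        warnings.warn(f"empty database for query {query.id!r}", stacklevel=2)
        return []
    if params is None:
        params = KarlinAltschulParams.for_scheme(scheme)

    wlen = min(rule.window, len(query))
    starts = range(len(query) - wlen + 1)
    ctx = EValueContext.from_db(wlen, db)
    needed_columns = min(rule.min_segment, wlen)

    hits: list[WindowHit] = []
    for start in starts:
        window = SequenceRecord(
            id=f"{query.id}[{start}:{start + wlen}]",
            description="", alphabet=query.alphabet,
            residues=query.residues[start:start + wlen])
        for subject in db:
            aln = smith_waterman(window, subject, scheme)
            e = evalue(aln.score, params, ctx)
            if e > rule.evalue_max_protein:
                continue
            pid = percent_identity(aln) if not aln.is_empty else 0.0
            hits.append(WindowHit(
                window_start=start, window_length=wlen, alignment=aln,
                evalue=e,
                flagged=(pid >= rule.identity_threshold
                         and aln.columns >= needed_columns),
            ))
    return hits


def full_length_allergen_screen(
    query: SequenceRecord,
    db: list[SequenceRecord],
    scheme: ScoringScheme,
    rule: ScreenRule,
    ctx: EValueContext | None = None,
) -> list[ScreenHit]:
    """Tier-1 screen: one best alignment per allergen subject, E-gated."""
    return full_length_screen(query, db, scheme, rule, ctx)
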