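"""Full-length toxin homology screen and the combined rule-outcome verdict."""

from __future__ import annotations

from dataclasses import dataclass

from .align import EValueContext, ScoringScheme
from .allergen import EpitopeMatch, WindowHit
from .hits import ScreenHit, ScreenRule, full_length_screen
from .seqio import SequenceRecord

__all__ = ["ScreenHit", "ScreenRule", "Verdict", "toxin_screen", "verdict"]


def toxin_screen(
    query: SequenceRecord,
    db: list[SequenceRecord],
    scheme: ScoringScheme,
    rule: ScreenRule,
    ctx: EValueContext | None = None,
) -> list[ScreenHit]:
    """One report row per toxin subject with E <= ceiling, sorted by E.

    Significance is the 35%-identity-over->=80-columns call; the free-text
    comment column is left empty for manual curation.
    """
    return full_length_screen(query, db, scheme, rule, ctx)


@dataclass(frozen=True)
class Verdict:
    """Structured summary of rule outcomes; never a safety claim."""

    any_significant_alignment: bool
    any_flagged_window: bool
    epitope_count: int
    items_for_manual_review: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "any_significant_alignment": self.any_significant_alignment,
            "any_flagged_window": self.any_flagged_window,
            "epitope_count": self.epitope_count,
            "items_for_manual_review": list(self.items_for_manual_review),
        }


def verdict(hits: list[ScreenHit], epitopes: list[EpitopeMatch],
            windows: list[WindowHit]) -> Verdict:
    """Summarize rule outcomes across the screening tiers.

    ``epitope_count`` counts distinct shared k-mer strings.  Items for
    manual review are the distinct epitope strings, the accessions of
    significant full-length hits, and flagged window descriptors.
    """
    distinct_kmers = sorted({m.kmer_string for m in epitopes})
    significant = [h for h in hits if h.significant]
    flagged = [w for w in windows if w.flagged]
    items = list(distinct_kmers)
    items += [h.accession for h in significant]
    items += [f"window@{w.window_start}~{w.alignment.subject_id}"
              for w in flagged]
    return Verdict(
        any_significant_alignment=bool(significant),
        any_flagged_window=bool(flagged),
        epitope_count=len(distinct_kmers),
        items_for_manual_review=tuple(items),
    )
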