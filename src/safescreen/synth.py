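"""Decoy reference databases with controlled, fully seeded structure.

Generates i.i.d. background sequences from a residue composition model and
plants three kinds of signal for closed-loop validation of the screens:

* homologous segments -- a donor segment substitution-mutated to an exact
  ungapped target identity, spliced into a decoy record;
* exact k-mer epitopes -- inserted verbatim;
* shuffled short RNAs -- mononucleotide (count-preserving) or dinucleotide
  (Altschul-Erickson Eulerian-path, dinucleotide-count-preserving) shuffles.

Every planted item is recorded in a manifest; identical spec + seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "PROTEIN_BACKGROUND",
    "DecoySpec",
    "PlantedHomolog",
    "make_decoy_db",
    "mutate_to_identity",
    "shuffle_rna",
]

# Robinson & Robinson amino-acid background frequencies (the composition
# underlying the shipped BLOSUM matrices' statistics); renormalized on use.
PROTEIN_BACKGROUND: dict[str, float] = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

_NUC_LETTERS = {"dna": "ACGT", "rna": "ACGU"}


def _composition(alphabet: str,
                 frequencies: dict[str, float] | None) -> tuple[list[str], np.ndarray]:
    if frequencies is None:
        if alphabet == "protein":
            frequencies = PROTEIN_BACKGROUND
        else:
            frequencies = {c: 0.25 for c in _NUC_LETTERS[alphabet]}
    letters = sorted(frequencies)
    probs = np.array([frequencies[c] for c in letters], dtype=float)
    if (probs <= 0).any():
        raise ValueError("residue frequencies must be positive")
    return letters, probs / probs.sum()


@dataclass(frozen=True)
class PlantedHomolog:
    """Recipe for one homologous segment planted into a decoy record."""

    donor: SequenceRecord
    target_identity: float
    segment_length: int

    def __post_init__(self) -> None:
        if not 0 < self.target_identity <= 1:
            raise ValueError("target_identity must be in (0, 1]")
        if not 1 <= self.segment_length <= len(self.donor):
            raise ValueError("segment_length must be within the donor length")


@dataclass(frozen=True)
class DecoySpec:
    """Recipe for a synthetic reference database."""

    n_records: int
    length_range: tuple[int, int] = (80, 600)
    alphabet: str = "protein"
    residue_frequencies: dict[str, float] | None = None
    planted_homologs: tuple[PlantedHomolog, ...] = ()
    planted_epitopes: tuple[tuple[str, int], ...] = ()  # (kmer, record index)
    seed: int = 0
    id_prefix: str = "decoy"

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be positive")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid length_range")


def mutate_to_identity(donor_segment: str, target_identity: float, seed: int,
                       alphabet: str = "protein",
                       frequencies: dict[str, float] | None = None) -> str:
    """Substitute exactly ``round((1 - target_identity) * L)`` positions.

    Positions are chosen without replacement by the seeded generator; each
    substituted residue is drawn from the composition model conditioned on
    differing from the original, so the realized ungapped identity is exact
    by construction.
    """
    L = len(donor_segment)
    if L == 0:
        raise ValueError("donor segment is empty")
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_sub = round((1 - target_identity) * L)
    if n_sub == 0:
        return donor_segment
    letters, probs = _composition(alphabet, frequencies)
    positions = rng.choice(L, size=n_sub, replace=False)
    out = list(donor_segment)
    for pos in sorted(int(p) for p in positions):
        original = out[pos]
        keep = [i for i, c in enumerate(letters) if c != original]
        if not keep:
            raise ValueError("composition model has a single residue; "
                             "cannot substitute")
        p = probs[keep] / probs[keep].sum()
        out[pos] = letters[keep[int(rng.choice(len(keep), p=p))]]
    return "".join(out)


def _random_sequence(rng: np.random.Generator, length: int,
                     letters: Sequence[str], probs: np.ndarray) -> str:
    idx = rng.choice(len(letters), size=length, p=probs)
    return "".join(letters[i] for i in idx)


def make_decoy_db(spec: DecoySpec) -> tuple[list[SequenceRecord], list[dict]]:
    """Generate the decoy database and its planted-signal manifest."""
    rng = np.random.default_rng(spec.seed)
    letters, probs = _composition(spec.alphabet, spec.residue_frequencies)
    lo, hi = spec.length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_records)
    width = max(4, len(str(spec.n_records)))
    seqs = [_random_sequence(rng, int(n), letters, probs) for n in lengths]
    ids = [f"{spec.id_prefix}_{i:0{width}d}" for i in range(spec.n_records)]

    manifest: list[dict] = []
    for homolog in spec.planted_homologs:
        seg_len = homolog.segment_length
        donor_start = int(rng.integers(0, len(homolog.donor) - seg_len + 1))
        segment = homolog.donor.residues[donor_start:donor_start + seg_len]
        mutated = mutate_to_identity(
            segment, homolog.target_identity, seed=int(rng.integers(2 ** 31)),
            alphabet=spec.alphabet, frequencies=spec.residue_frequencies)
        eligible = [i for i, s in enumerate(seqs) if len(s) >= seg_len]
        if not eligible:
            raise ValueError(
                f"no decoy record long enough for a {seg_len}-residue segment")
        host = eligible[int(rng.integers(0, len(eligible)))]
        offset = int(rng.integers(0, len(seqs[host]) - seg_len + 1))
        seqs[host] = (seqs[host][:offset] + mutated
                      + seqs[host][offset + seg_len:])
        realized = sum(a == b for a, b in zip(segment, mutated)) / seg_len
        manifest.append({
            "record_id": ids[host], "kind": "homolog", "offset": offset,
            "length": seg_len, "target_identity": homolog.target_identity,
            "realized_identity": realized, "donor": homolog.donor.id,
            "donor_start": donor_start,
        })

    for kmer, host in spec.planted_epitopes:
        if not 0 <= host < spec.n_records:
            raise ValueError(f"epitope host index {host} out of range")
        if len(kmer) > len(seqs[host]):
            raise ValueError(
                f"epitope {kmer!r} longer than host record {ids[host]!r}")
        offset = int(rng.integers(0, len(seqs[host]) - len(kmer) + 1))
        seqs[host] = (seqs[host][:offset] + kmer.upper()
                      + seqs[host][offset + len(kmer):])
        manifest.append({
            "record_id": ids[host], "kind": "epitope", "offset": offset,
            "length": len(kmer), "kmer": kmer.upper(),
        })

    records = [SequenceRecord(id=rid, description="synthetic decoy",
                              alphabet=spec.alphabet, residues=s)
               for rid, s in zip(ids, seqs)]
    return records, manifest


# ---------------------------------------------------------------------------
# RNA shuffles
# ---------------------------------------------------------------------------

def _dinucleotide_shuffle(s: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson Eulerian shuffle preserving dinucleotide counts."""
    if len(set(s)) == 1:
        return s
    # out-edge multiset per vertex, in order of appearance
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = [v for v in edges if v != last]

    for _ in range(10_000):
        # choose one out-edge per non-terminal vertex as its final edge and
        # check the chosen edges form an arborescence toward the terminal
        chosen = {v: edges[v][int(rng.integers(0, len(edges[v])))]
                  for v in vertices}
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last:
                cur = chosen.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - practically unreachable
        raise RuntimeError("dinucleotide shuffle failed to converge")

    order: dict[str, list[str]] = {}
    for v, outs in edges.items():
        outs = outs.copy()
        if v in chosen:
            outs.remove(chosen[v])
        perm = [outs[i] for i in rng.permutation(len(outs))]
        if v in chosen:
            perm.append(chosen[v])
        order[v] = perm

    walk = [s[0]]
    pos = {v: 0 for v in order}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = order[cur][pos[cur]]
        pos[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


def shuffle_rna(record: SequenceRecord, mode: str,
                seed: int) -> SequenceRecord:
    """Seeded shuffle of a nucleotide record.

    ``mononucleotide`` preserves base counts exactly; ``dinucleotide``
    preserves the dinucleotide count table exactly.
    """
    if not record.is_nucleotide:
        raise ValueError(f"record {record.id!r} is not a nucleotide sequence")
    rng = np.random.default_rng(seed)
    if mode == "mononucleotide":
        chars = list(record.residues)
        shuffled = "".join(chars[i] for i in rng.permutation(len(chars)))
    elif mode == "dinucleotide":
        if len(record) < 2:
            raise ValueError("dinucleotide shuffle needs length >= 2")
        shuffled = _dinucleotide_shuffle(record.residues, rng)
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    return SequenceRecord(id=f"{record.id}_shuf", description=record.description,
                          alphabet=record.alphabet, residues=shuffled)
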