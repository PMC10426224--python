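"""Report serialization: TSV tables with provenance headers, JSON summaries.

Every TSV starts with ``#``-prefixed comment lines recording the tool
version, the fully resolved configuration and the SHA-256 of each input
file; JSON outputs carry the same information under ``_provenance``.
E-values are printed in scientific notation with two significant digits and
identities to one decimal, matching the report tables' print style.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

from . import __version__
from .allergen import EpitopeMatch, WindowHit
from .align import percent_identity
from .hits import ScreenHit
from .rna import RnaHit

__all__ = [
    "SCREEN_HIT_COLUMNS",
    "provenance",
    "write_tsv",
    "read_tsv",
    "write_json",
    "screen_hit_rows",
    "window_hit_rows",
    "epitope_rows",
    "rna_hit_rows",
]

SCREEN_HIT_COLUMNS = [
    "Database", "Program", "Keyword", "Accession", "Organism", "Description",
    "Length(aa)", "Evalue", "PercentIdentity", "AlignmentLength(aa)",
    "Significant", "Comment",
]
WINDOW_COLUMNS = [
    "WindowStart", "WindowLength", "SubjectId", "Score", "Evalue",
    "PercentIdentity", "AlignmentLength", "Flagged",
]
EPITOPE_COLUMNS = ["Kmer", "SubjectId", "QueryPositions", "SubjectPositions"]
RNA_COLUMNS = [
    "MirnaId", "Species", "Strand", "Score", "Identities", "AlignmentLength",
    "Evalue", "Significant",
]


def _fmt_evalue(e: float) -> str:
    return f"{e:.1e}"


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def provenance(config: Mapping[str, object],
               inputs: Iterable[str | Path] = ()) -> dict[str, str]:
    out = {"tool": f"safescreen {__version__}"}
    for key in sorted(config):
        out[f"config.{key}"] = str(config[key])
    for path in inputs:
        out[f"sha256.{Path(path).name}"] = sha256_file(path)
    return out


def write_tsv(path: str | Path, columns: list[str],
              rows: Iterable[Mapping[str, object]],
              header: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")


def read_tsv(path: str | Path) -> tuple[list[str], list[dict[str, str]]]:
    """Read a report TSV back; comment lines are skipped."""
    columns: list[str] = []
    rows: list[dict[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not columns:
                columns = line.split("\t")
                continue
            rows.append(dict(zip(columns, line.split("\t"))))
    return columns, rows


def write_json(path: str | Path, payload: dict,
               header: Mapping[str, str] | None = None) -> None:
    doc = dict(payload)
    if header:
        doc["_provenance"] = dict(header)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


# -- row builders -----------------------------------------------------------

def screen_hit_rows(hits: Iterable[ScreenHit], database: str = "",
                    program: str = "safescreen-sw",
                    keyword: str = "") -> list[dict[str, object]]:
    rows = []
    for h in hits:
        rows.append({
            "Database": database, "Program": program, "Keyword": keyword,
            "Accession": h.accession, "Organism": h.organism,
            "Description": h.description, "Length(aa)": h.subject_length,
            "Evalue": _fmt_evalue(h.evalue),
            "PercentIdentity": f"{h.percent_identity:.1f}",
            "AlignmentLength(aa)": h.alignment_length,
            "Significant": h.significant, "Comment": h.comment,
        })
    return rows


def window_hit_rows(windows: Iterable[WindowHit]) -> list[dict[str, object]]:
    rows = []
    for w in windows:
        aln = w.alignment
        pid = percent_identity(aln) if not aln.is_empty else 0.0
        rows.append({
            "WindowStart": w.window_start, "WindowLength": w.window_length,
            "SubjectId": aln.subject_id, "Score": aln.score,
            "Evalue": _fmt_evalue(w.evalue),
            "PercentIdentity": f"{pid:.1f}",
            "AlignmentLength": aln.columns, "Flagged": w.flagged,
        })
    return rows


def epitope_rows(matches: Iterable[EpitopeMatch]) -> list[dict[str, object]]:
    return [{
        "Kmer": m.kmer_string, "SubjectId": m.subject_id,
        "QueryPositions": ",".join(map(str, m.query_positions)),
        "SubjectPositions": ",".join(map(str, m.subject_positions)),
    } for m in matches]


def rna_hit_rows(hits: Iterable[RnaHit]) -> list[dict[str, object]]:
    return [{
        "MirnaId": h.mirna_id, "Species": h.species, "Strand": h.strand,
        "Score": h.alignment.score, "Identities": h.alignment.identities,
        "AlignmentLength": h.alignment.columns,
        "Evalue": _fmt_evalue(h.evalue), "Significant": h.significant,
    } for h in hits]
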