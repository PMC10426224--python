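"""Bundled query/subject sequences used throughout the test suite and docs."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .seqio import SequenceRecord, read_fasta

#: fixture name -> (data file, alphabet)
FIXTURES: dict[str, tuple[str, str]] = {
    "hcas9": ("hcas9.faa", "protein"),
    "dsred": ("dsred.faa", "protein"),
    "hevb9": ("hevb9.faa", "protein"),
    "t1_grna": ("t1_grna.fna", "rna"),
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture FASTA file."""
    try:
        fname, _ = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    return Path(str(resources.files("safescreen").joinpath("data", fname)))


def load_fixture(name: str) -> SequenceRecord:
    """Load a bundled single-record fixture by short name."""
    _, alphabet = FIXTURES[name]
    return read_fasta(fixture_path(name), alphabet)[0]
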