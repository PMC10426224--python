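import pytest

from safescreen import ScoringScheme, ScreenRule, SequenceRecord, load_fixture


@pytest.fixture(scope="session")
def hcas9():
    return load_fixture("hcas9")


@pytest.fixture(scope="session")
def dsred():
    return load_fixture("dsred")


@pytest.fixture(scope="session")
def hevb9():
    return load_fixture("hevb9")


@pytest.fixture(scope="session")
def t1_grna():
    return load_fixture("t1_grna")


@pytest.fixture(scope="session")
def blosum62():
    return ScoringScheme.blosum62()


@pytest.fixture(scope="session")
def nuc_scheme():
    return ScoringScheme.nuc()


@pytest.fixture
def default_rule():
    return ScreenRule()


def protein(seq: str, rid: str = "p") -> SequenceRecord:
    return SequenceRecord(id=rid, description="", alphabet="protein",
                          residues=seq)


def rna_rec(seq: str, rid: str = "r") -> SequenceRecord:
    return SequenceRecord(id=rid, description="", alphabet="rna",
                          residues=seq)


@pytest.fixture
def make_protein():
    return protein


@pytest.fixture
def make_rna():
    return rna_rec
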