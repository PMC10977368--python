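import pytest

from skipdesign.synthetic_data import (
    FixtureSpec,
    make_paperlike_fixture,
    make_toy_gene,
)


@pytest.fixture(scope="session")
def igfbp1_fixture():
    return make_paperlike_fixture("igfbp1-like", seed=7)


@pytest.fixture(scope="session")
def igfbp3_fixture():
    return make_paperlike_fixture("igfbp3-like", seed=7)


@pytest.fixture(scope="session")
def toy_gene():
    return make_toy_gene(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def toy_gene_185():
    """Three-exon toy with the 185-nt out-of-frame target exon."""
    return make_toy_gene(FixtureSpec(seed=3, exon_lengths=(100, 185, 120)))


SIMPLE_FASTA = ">chr1\n" + "ACGTACGTAA" * 6 + "\n"

SIMPLE_GFF3 = """##gff-version 3
chr1\ttest\tgene\t11\t40\t.\t+\t.\tID=g1
chr1\ttest\tmRNA\t11\t40\t.\t+\t.\tID=tx1;Parent=g1
chr1\ttest\texon\t11\t20\t.\t+\t.\tID=tx1.e1;Parent=tx1
chr1\ttest\texon\t31\t40\t.\t+\t.\tID=tx1.e2;Parent=tx1
"""

SIMPLE_GFF3_MINUS = SIMPLE_GFF3.replace("\t+\t", "\t-\t")

SIMPLE_GTF = """chr1\ttest\ttranscript\t11\t40\t.\t+\t.\tgene_id "g1"; transcript_id "tx1";
chr1\ttest\texon\t11\t20\t.\t+\t.\tgene_id "g1"; transcript_id "tx1";
chr1\ttest\texon\t31\t40\t.\t+\t.\tgene_id "g1"; transcript_id "tx1";
"""


@pytest.fixture
def simple_fasta():
    return SIMPLE_FASTA


@pytest.fixture
def simple_gff3():
    return SIMPLE_GFF3


@pytest.fixture
def simple_gff3_minus():
    return SIMPLE_GFF3_MINUS


@pytest.fixture
def simple_gtf():
    return SIMPLE_GTF
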