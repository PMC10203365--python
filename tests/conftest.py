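import pytest

from panelsmith.genomic_io import GenomicInterval, TranscriptModel
from panelsmith.synth_data import SimSpec, simulate_gene_models


GFF_TWO_EXON = """\
##gff-version 3
chr1\tsrc\tgene\t50\t500\t.\t+\t.\tID=G1
chr1\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=G1.T1;Parent=G1
chr1\tsrc\tCDS\t101\t200\t.\t+\t0\tID=c1;Parent=G1.T1
chr1\tsrc\tCDS\t301\t400\t.\t+\t0\tID=c2;Parent=G1.T1
"""

GFF_MINUS = """\
##gff-version 3
chr1\tsrc\tgene\t50\t500\t.\t-\t.\tID=G2
chr1\tsrc\tmRNA\t101\t400\t.\t-\t.\tID=G2.T1;Parent=G2
chr1\tsrc\tCDS\t101\t200\t.\t-\t0\tID=c1;Parent=G2.T1
chr1\tsrc\tCDS\t301\t400\t.\t-\t0\tID=c2;Parent=G2.T1
"""


@pytest.fixture
def gff_two_exon():
    return GFF_TWO_EXON


@pytest.fixture
def gff_minus():
    return GFF_MINUS


@pytest.fixture
def plus_transcript():
    return TranscriptModel(
        gene_id="G1", transcript_id="G1.T1", chrom="chr1", strand="+",
        cds=[GenomicInterval("chr1", 100, 200),
             GenomicInterval("chr1", 300, 400)],
    )


@pytest.fixture(scope="session")
def sim_models():
    """A modest simulated gene set shared across tests."""
    spec = SimSpec(seed=11, n_genes=20)
    return simulate_gene_models(spec)
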