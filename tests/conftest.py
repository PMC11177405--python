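import numpy as np
import pytest

from tubkit.core import GenomeBundle, GeneRecord, GenomicInterval
from tubkit.pipeline import run_recovery
from tubkit.simulate import SimulationConfig, simulate_dataset


def make_gene(gene_id, chrom, exon_spans, strand="+", **kw):
    exons = [GenomicInterval(chrom, a, b, strand) for a, b in exon_spans]
    locus = GenomicInterval(
        chrom, min(a for a, _ in exon_spans), max(b for _, b in exon_spans), strand
    )
    return GeneRecord(gene_id=gene_id, locus=locus, exons=exons, **kw)


@pytest.fixture
def tiny_bundle():
    # one chromosome, a plus- and a minus-strand gene whose CDS is ATGGCTTAA
    chrom_seq = "TTTT" + "ATGGCT" + "GGGG" + "TAA" + "TTTTTTTT"
    # gene1: exons (4,10) + (14,17) -> ATGGCT + TAA
    g1 = make_gene("g1", "chr1", [(4, 10), (14, 17)], "+")
    # gene2 on minus strand at 20..29: place revcomp(ATGGCTTAA)
    seq2 = chrom_seq[:20] + "TTAAGCCAT" + chrom_seq[29:]
    g2 = make_gene("g2", "chr1", [(20, 29)], "-")
    bundle = GenomeBundle(
        sequences={"chr1": seq2}, genes=[g1, g2], subgenome_map={"chr1": "G1"}
    )
    return bundle


@pytest.fixture(scope="session")
def sim_default():
    """Default-config synthetic dataset, seed 1."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def recovery_one():
    """Full pipeline recovery on one default seed."""
    return run_recovery(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def recovery_batch():
    """Full pipeline recovery across 20 default seeds (shared by the
    acceptance tests; computed once per session)."""
    return [run_recovery(SimulationConfig(seed=s)) for s in range(1, 21)]


@pytest.fixture(scope="session")
def rates_zero_dataset():
    cfg = SimulationConfig(
        seed=5,
        loss_rate=0.0,
        pseudogenize_rate=0.0,
        tandem_dup_rate=0.0,
        transpose_rate=0.0,
    )
    return simulate_dataset(cfg)
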