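import pytest

from snpburden.models import GeneModel, GenomeSequence
from snpburden.simulate import PlantedCounts, SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition synthetic dataset shared across tests."""
    return simulate_dataset(SimulationSpec(seed=11))


@pytest.fixture(scope="session")
def sim_clean():
    """Dataset with no forced low-depth or near-INDEL variants: every
    planted coding SNP survives filtering."""
    spec = SimulationSpec(
        seed=5,
        planted=PlantedCounts(synonymous=50, nonsynonymous=50,
                              noncoding=20, indels=10),
        low_depth_fraction=0.0,
        near_indel_fraction=0.0,
    )
    return simulate_dataset(spec)


@pytest.fixture()
def toy_genome():
    # contig1: one + strand gene (two exons), one - strand gene (one exon)
    #   geneA: CDS 11-19 + 30-32 (+)   spliced = seq[10:19] + seq[29:32]
    #   geneB: CDS 41-49 (-)           spliced = revcomp(seq[40:49])
    seq = (
        "AAAAATTTTT"      # 1-10   intergenic
        "ATGGCTCAT"       # 11-19  geneA exon1: ATG GCT CAT -> M A H
        "GGGGGGGGGG"      # 20-29  intron (geneA span 11..32)
        "TAA"             # 30-32  geneA exon2: stop
        "CCCCCCCC"        # 33-40  intergenic
        "TTACAGCGC"       # 41-49  geneB (-): revcomp = GCGCTGTAA -> A L *
        "ACGTACGTACG"     # 50-60  intergenic
    )
    return GenomeSequence("contig1", seq)


@pytest.fixture()
def toy_models():
    gene_a = GeneModel(
        gene_id="geneA", contig_id="contig1", strand="+",
        cds_segments=((11, 19), (30, 32)),
    )
    gene_b = GeneModel(
        gene_id="geneB", contig_id="contig1", strand="-",
        cds_segments=((41, 49),),
    )
    return [gene_a, gene_b]
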