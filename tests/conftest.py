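import pytest

from kissmine import data_path
from kissmine.io import read_fasta, read_newick
from kissmine.synthetic import (
    GenomeConfig,
    KissImplant,
    KissRImplant,
    degrade_gene,
    make_genome,
)


@pytest.fixture(scope="session")
def kp10():
    """Bundled reference decapeptides (label -> 10-mer)."""
    return read_fasta(data_path("kp10_reference.fa"))


@pytest.fixture(scope="session")
def amniote_tree():
    """Rooted sarcopterygian species tree with named internal nodes."""
    return read_newick(data_path("sarcopterygian_tree.nwk"))


@pytest.fixture(scope="session")
def intact_genome():
    """Synthetic genome with intact Kiss implants on both strands plus a
    five-exon receptor gene; truth recorded."""
    config = GenomeConfig(
        n_segments=4,
        segment_length=2500,
        implants=[
            KissImplant(gene_type="Kiss2", decapeptide="FNFNPFGLRF", strand="+"),
            KissImplant(gene_type="Kiss1", decapeptide="YNWNSFGLRY", strand="-"),
            KissImplant(
                gene_type="Kiss2",
                decapeptide="FNFNSFGLRF",
                strand="+",
                extra_dibasic_offset_aa=2,  # long (53) + short (12) variants
            ),
            KissRImplant(gene_type="KissR1", strand="-"),
        ],
    )
    return make_genome(config, seed=2014)


@pytest.fixture(scope="session")
def degraded_genome():
    """Synthetic genome carrying one implant per degradation mode."""
    implants = [
        degrade_gene(
            KissImplant(decapeptide="FIFNPFGLGF", premature_stop_offset_nt=36),
            "premature_stop",
        ),
        degrade_gene(KissImplant(decapeptide="FNFNPFGLRF"), "motif_substitution"),
        degrade_gene(KissImplant(decapeptide="FNFNPFGLRF"), "cleavage_loss"),
        degrade_gene(
            KissImplant(decapeptide="FKVNLLGLGF"), "amidation_degeneration", seed=3
        ),
    ]
    config = GenomeConfig(n_segments=4, segment_length=2000, implants=implants)
    return make_genome(config, seed=2015)
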