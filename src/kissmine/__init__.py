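"""kissmine: kisspeptin (Kiss) and kisspeptin-receptor (KissR) gene mining,
classification and evolutionary-scenario reconstruction.

The package mines decapeptide-coding precursor ORFs in genomic DNA,
diagnoses pseudogenization, validates multi-exon receptor models, compares
and aligns mature peptides, infers neighbor-joining phylogenies with
bootstrap supports, classifies loci into paralogon types by shared
syntenic markers, and counts minimal gene-loss events under Dollo
parsimony on a species tree.  A synthetic-data generator provides genomes,
neighborhoods and presence/absence data with known ground truth.
"""

from importlib import resources

__version__ = "0.1.0"

from .mining import (  # noqa: F401
    GenomeSegment,
    OrfHit,
    DecapeptideHit,
    PrecursorCandidate,
    classify_amidation,
    diagnose_pseudogene,
    find_orfs,
    mine_genome,
    mine_segment,
    predict_cleavage_sites,
    scan_decapeptides,
    score_splice_acceptors,
)
from .peptides import (  # noqa: F401
    MultipleAlignment,
    global_align,
    identity_matrix,
    pairwise_identity,
    progressive_align,
)
from .phylo import (  # noqa: F401
    bootstrap_supports,
    distances,
    majority_consensus,
    nj_tree,
    root_tree,
)
from .receptor import count_tm_domains, validate_gene_model  # noqa: F401
from .scenario import (  # noqa: F401
    ScenarioResult,
    build_scenario_table,
    compare_hypotheses,
    dollo_losses,
)
from .synteny import (  # noqa: F401
    Neighborhood,
    ReferenceParalogon,
    assess_region_presence,
    classify_locus,
)
from .synthetic import (  # noqa: F401
    GenomeConfig,
    KissImplant,
    KissRImplant,
    SyntheticTruth,
    degrade_gene,
    make_genome,
    make_neighborhood_tables,
    make_scenario_dataset,
)


def data_path(name: str):
    """Path to a bundled data file (reference decapeptides, marker sets,
    species tree)."""
    return resources.files("kissmine") / "data" / name
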