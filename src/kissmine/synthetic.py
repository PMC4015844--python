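"""Synthetic genomes, neighborhoods and presence/absence data with truth.

Every downstream stage of the pipeline is exercised on data generated
here: two-exon Kiss-like genes whose second exon carries the stop-bounded
precursor ORF (spacer, dibasic cleavage site, Kp(10) decapeptide,
amidation motif), five-exon KissR-like genes with GT–AG introns encoding a
seven-helix membrane protein, controlled degradations of each, marker-gene
neighborhood tables with tunable marker drop-out, and Dollo scenario state
vectors implied by a known set of loss edges.  All generators are pure
functions of (config, seed), and the ground truth is recorded alongside
the outputs so tests never re-derive it.

The background sequence model is i.i.d. nucleotides at a configurable GC
fraction; mining does not depend on background realism, only on the
implanted signal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .mining import GenomeSegment

_BLOSUM62_SCRUB = substitution_matrices.load("BLOSUM62")

__all__ = [
    "KissImplant",
    "KissRImplant",
    "ImplantedGene",
    "SyntheticTruth",
    "GenomeConfig",
    "degrade_gene",
    "make_genome",
    "make_neighborhood_tables",
    "make_scenario_dataset",
]

DEGRADATION_MODES = (
    "none",
    "premature_stop",
    "motif_substitution",
    "cleavage_loss",
    "amidation_degeneration",
)

# one fixed codon per residue keeps cassettes deterministic given the spec
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGA", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "AGA",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "*": "TAA",
}
# spacer residues: no K/R (would create spurious cleavage sites), no C/M/W
_SPACER_RESIDUES = "ADEFGHILNPQSTVY"
_LOOP_RESIDUES = "DENQSTGH"  # strongly hydrophilic loops
_TM_RESIDUES = "ILVF"  # strongly hydrophobic helices


def _codons(aa: str) -> str:
    return "".join(_CODON[c] for c in aa)


@dataclass
class KissImplant:
    """Specification of a two-exon Kiss-like gene to implant.

    The precursor ORF (second exon) reads: spacer1, a KR dibasic cleavage
    site, spacer2, the decapeptide, the amidation motif, then the
    delimiting stop; the implied mature peptide is ``spacer2_aa + 10``
    residues long.
    """

    gene_type: str = "Kiss2"
    strand: str = "+"
    decapeptide: str = "FNFNPFGLRF"
    amidation_motif: str = "GKR"
    spacer1_aa: int = 10
    spacer2_aa: int = 43
    degradation: str = "none"
    premature_stop_offset_nt: int = 36
    motif_substitutions: dict[int, str] = field(
        default_factory=lambda: {2: "I", 9: "G"}
    )
    # optional second dibasic pair inside spacer2, this many residues 5' of
    # the decapeptide: yields an extra mature-peptide variant of that
    # length + 10 (e.g. 2 -> a 12-residue short form beside the long one)
    extra_dibasic_offset_aa: int | None = None
    segment_index: int | None = None

    def __post_init__(self) -> None:
        if len(self.decapeptide) != 10:
            raise ValueError("decapeptide must be 10 residues")
        if self.degradation not in DEGRADATION_MODES:
            raise ValueError(f"unknown degradation mode {self.degradation!r}")

    @property
    def mature_length(self) -> int:
        return self.spacer2_aa + 10


@dataclass
class KissRImplant:
    """Specification of a five-exon KissR-like receptor gene to implant."""

    gene_type: str = "KissR1"
    strand: str = "+"
    n_tm: int = 7
    tm_aa: int = 23
    loop_aa: int = 15
    tail_aa: int = 20
    n_exons: int = 5
    intron_nt: int = 40
    degradation: str = "none"
    segment_index: int | None = None

    def __post_init__(self) -> None:
        if self.degradation not in ("none", "premature_stop"):
            if self.degradation in DEGRADATION_MODES:
                raise ValueError(
                    f"degradation {self.degradation!r} is incompatible with a "
                    "receptor gene structure"
                )
            raise ValueError(f"unknown degradation mode {self.degradation!r}")


@dataclass
class ImplantedGene:
    """Ground-truth record of one implanted gene."""

    segment_id: str
    gene_type: str
    strand: str
    exons: list[tuple[int, int]]  # forward strand, 0-based half-open
    degradation: str = "none"
    decapeptide: str | None = None
    decapeptide_interval: tuple[int, int] | None = None
    amidation_motif: str | None = None
    mature_length: int | None = None
    upstream_stop_distance_nt: int | None = None
    orf_interval: tuple[int, int] | None = None
    protein: str | None = None


@dataclass
class SyntheticTruth:
    implanted_genes: list[ImplantedGene] = field(default_factory=list)
    neighborhood_assignments: dict[str, str] = field(default_factory=dict)
    dropped_markers: dict[str, list[str]] = field(default_factory=dict)
    scenario_truth: dict[str, list[list[str]]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)
        genes = [
            ImplantedGene(
                **{
                    **g,
                    "exons": [tuple(x) for x in g["exons"]],
                    "decapeptide_interval": (
                        tuple(g["decapeptide_interval"])
                        if g["decapeptide_interval"]
                        else None
                    ),
                    "orf_interval": (
                        tuple(g["orf_interval"]) if g["orf_interval"] else None
                    ),
                }
            )
            for g in raw["implanted_genes"]
        ]
        return cls(
            implanted_genes=genes,
            neighborhood_assignments=raw.get("neighborhood_assignments", {}),
            dropped_markers=raw.get("dropped_markers", {}),
            scenario_truth=raw.get("scenario_truth", {}),
        )


@dataclass
class GenomeConfig:
    """Generator settings.

    ``scrub_background`` enforces the noise-free contract: segments are
    rejection-sampled until the only six-frame 10-residue windows similar
    to the scrub panel (score ratio >= ``scrub_threshold``) are the
    implanted decapeptides themselves, so ground truth is exact.  The
    default panel is the bundled reference Kp(10) set plus the implant
    decapeptides.
    """

    n_segments: int = 3
    segment_length: int = 3000
    gc_fraction: float = 0.45
    implants: list = field(default_factory=list)
    species: str = "synthetic"
    scrub_background: bool = True
    scrub_threshold: float = 0.4
    scrub_queries: list[str] | None = None


def degrade_gene(gene, mode: str, seed: int = 0):
    """Return a copy of an implant spec with one degradation mode applied.

    Modes: ``premature_stop`` (in-frame stop a configurable distance 5' of
    the decapeptide codons), ``motif_substitution`` (mutates the stated
    conserved decapeptide positions), ``cleavage_loss`` (removes the
    upstream dibasic pair), ``amidation_degeneration`` (G-Basic-Basic ->
    G-Basic-nonbasic), ``none`` (identity).
    """
    if mode not in DEGRADATION_MODES:
        raise ValueError(f"unknown degradation mode {mode!r}")
    if mode == "none":
        return dataclasses.replace(gene)
    if isinstance(gene, KissRImplant):
        raise ValueError(
            f"degradation {mode!r} is incompatible with a receptor gene structure"
        )
    spec = dataclasses.replace(gene, degradation=mode)
    if mode == "motif_substitution":
        decap = list(spec.decapeptide)
        for pos, res in spec.motif_substitutions.items():
            decap[pos - 1] = res
        spec.decapeptide = "".join(decap)
    elif mode == "amidation_degeneration":
        motif = spec.amidation_motif
        if len(motif) != 3 or motif[0] != "G" or motif[1] not in "KR":
            raise ValueError(
                f"amidation_degeneration needs a G-Basic-Basic motif, got {motif!r}"
            )
        rng = np.random.default_rng(seed)
        nonbasic = rng.choice(list("LGAQ"))
        spec.amidation_motif = motif[:2] + str(nonbasic)
    # premature_stop and cleavage_loss act at cassette-assembly time
    return spec


def _kiss_cassette(spec: KissImplant, rng: np.random.Generator) -> tuple[str, dict]:
    """Assemble the second-exon cassette: 5' stop, precursor ORF, 3' stop.

    Returns the cassette (on the coding strand) and relative coordinates.
    """
    spacer1 = "".join(rng.choice(list(_SPACER_RESIDUES), size=spec.spacer1_aa))
    spacer2 = list(rng.choice(list(_SPACER_RESIDUES), size=spec.spacer2_aa))
    if spec.extra_dibasic_offset_aa is not None:
        pos = spec.spacer2_aa - spec.extra_dibasic_offset_aa - 2
        if not 0 <= pos <= spec.spacer2_aa - 2:
            raise ValueError("extra_dibasic_offset_aa does not fit in spacer2")
        spacer2[pos : pos + 2] = ["K", "K"]
    spacer2 = "".join(spacer2)
    dibasic = "QT" if spec.degradation == "cleavage_loss" else "KR"
    orf_aa = spacer1 + dibasic + spacer2 + spec.decapeptide + spec.amidation_motif
    codons = [_CODON[a] for a in orf_aa]
    decap_start_aa = spec.spacer1_aa + 2 + spec.spacer2_aa
    if spec.degradation == "premature_stop":
        dist = spec.premature_stop_offset_nt
        if dist % 3:
            raise ValueError("premature_stop offset must be a codon multiple")
        idx = decap_start_aa - dist // 3 - 1
        if idx < 0:
            raise ValueError("premature_stop offset exceeds upstream spacer")
        codons[idx] = _CODON["*"]
    body = "".join(codons)
    cassette = _CODON["*"] + body + _CODON["*"]
    orf_start = 3
    upstream_nt = 3 * decap_start_aa
    if spec.degradation == "premature_stop":
        # the inserted stop re-delimits the ORF
        idx = decap_start_aa - spec.premature_stop_offset_nt // 3 - 1
        orf_start = 3 + 3 * (idx + 1)
        upstream_nt = spec.premature_stop_offset_nt
    rel = {
        "orf": (orf_start, 3 + len(body)),
        "decapeptide": (3 + 3 * decap_start_aa, 3 + 3 * (decap_start_aa + 10)),
        "upstream_stop_nt": upstream_nt,
    }
    return cassette, rel


def _kissr_cassette(spec: KissRImplant, rng: np.random.Generator) -> tuple[str, dict]:
    """Assemble a multi-exon receptor gene with GT..AG introns.

    Returns the gene sequence (coding strand) with relative exon intervals
    and the encoded protein.
    """
    tail_n = "".join(rng.choice(list(_LOOP_RESIDUES), size=spec.tail_aa))
    tail_c = "".join(rng.choice(list(_LOOP_RESIDUES), size=spec.tail_aa))
    parts = [tail_n]
    for k in range(spec.n_tm):
        parts.append("".join(rng.choice(list(_TM_RESIDUES), size=spec.tm_aa)))
        if k < spec.n_tm - 1:
            parts.append("".join(rng.choice(list(_LOOP_RESIDUES), size=spec.loop_aa)))
    parts.append(tail_c)
    protein = "M" + "".join(parts)
    cds = _codons(protein) + _CODON["*"]
    # split CDS into exons at interior points (not codon-aligned on purpose)
    n_ex = spec.n_exons
    cuts = sorted(
        rng.choice(np.arange(10, len(cds) - 10), size=n_ex - 1, replace=False)
    )
    bounds = [0, *cuts, len(cds)]
    exon_seqs = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
    pieces: list[str] = []
    rel_exons: list[tuple[int, int]] = []
    pos = 0
    for k, ex in enumerate(exon_seqs):
        rel_exons.append((pos, pos + len(ex)))
        pieces.append(ex)
        pos += len(ex)
        if k < len(exon_seqs) - 1:
            inner = "".join(
                rng.choice(list("ACGT"), size=max(spec.intron_nt - 4, 1))
            )
            intron = "GT" + inner + "AG"
            pieces.append(intron)
            pos += len(intron)
    return "".join(pieces), {"exons": rel_exons, "protein": protein}


def _background(length: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _default_panel() -> list[str]:
    from importlib import resources

    from Bio import SeqIO

    path = resources.files("kissmine") / "data" / "kp10_reference.fa"
    with path.open() as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, "fasta")]


def _has_spurious_signal(
    seq: str,
    allowed: list[tuple[int, int]],
    panel: list[str],
    threshold: float,
) -> bool:
    """True if any stop-free six-frame 10-residue window outside the
    allowed forward-strand intervals scores >= threshold x self-score
    against any panel peptide."""
    from .mining import _self_score, _translate_frame, _window_score

    selfs = [_self_score(q, _BLOSUM62_SCRUB) for q in panel]
    L = len(seq)
    for strand in "+-":
        scan = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            aa = _translate_frame(scan, frame)
            for off in range(len(aa) - 9):
                window = aa[off : off + 10]
                if "*" in window:
                    continue
                ok = False
                for q, s in zip(panel, selfs):
                    if s > 0 and _window_score(window, q, _BLOSUM62_SCRUB) >= threshold * s:
                        ok = True
                        break
                if not ok:
                    continue
                s_nt = frame + 3 * off
                e_nt = s_nt + 30
                if strand == "-":
                    s_nt, e_nt = L - e_nt, L - s_nt
                if not any(a <= s_nt and e_nt <= b for a, b in allowed):
                    return True
    return False


def make_genome(
    config: GenomeConfig, seed: int
) -> tuple[list[GenomeSegment], SyntheticTruth]:
    """Generate a synthetic genome with implanted genes and its truth.

    Implants are placed at non-overlapping random positions (on the
    recorded strand) within their assigned segment; identical
    (config, seed) reproduces byte-identical sequences.  With
    ``scrub_background`` (default) each segment is resampled until it
    carries no decapeptide-like signal beyond the implanted ones.
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    segments: list[GenomeSegment] = []
    if config.n_segments == 0:
        return segments, truth
    per_segment: dict[int, list] = {i: [] for i in range(config.n_segments)}
    for k, implant in enumerate(config.implants):
        idx = implant.segment_index
        if idx is None:
            idx = k % config.n_segments
        if idx >= config.n_segments:
            raise ValueError(f"implant assigned to missing segment {idx}")
        per_segment[idx].append(implant)

    panel: list[str] | None = None
    if config.scrub_background:
        panel = list(
            config.scrub_queries
            if config.scrub_queries is not None
            else _default_panel()
        )
        for implant in config.implants:
            if isinstance(implant, KissImplant):
                panel.append(implant.decapeptide)

    for i in range(config.n_segments):
        seg_id = f"seg{i + 1}"
        for _attempt in range(60):
            seq, genes = _build_segment(
                seg_id, per_segment[i], config, rng
            )
            if panel is None:
                break
            allowed = [
                g.decapeptide_interval
                for g in genes
                if g.decapeptide_interval is not None
            ]
            if not _has_spurious_signal(
                seq, allowed, panel, config.scrub_threshold
            ):
                break
        else:
            raise RuntimeError(
                f"segment {seg_id}: could not sample a clean background"
            )
        truth.implanted_genes.extend(genes)
        segments.append(
            GenomeSegment(id=seg_id, species=config.species, sequence=seq)
        )
    return segments, truth


def _build_segment(
    seg_id: str,
    implants: list,
    config: GenomeConfig,
    rng: np.random.Generator,
) -> tuple[str, list[ImplantedGene]]:
    genes: list[ImplantedGene] = []
    seq = list(_background(config.segment_length, config.gc_fraction, rng))
    cursor = 50
    for implant in implants:
        if isinstance(implant, KissImplant):
            cassette, rel = _kiss_cassette(implant, rng)
            # exon 1: a short coding stub 5' of the ORF-bearing exon,
            # separated by a GT..AG intron with a polypyrimidine tract
            stub = _codons(
                "M" + "".join(rng.choice(list(_SPACER_RESIDUES), size=9))
            )
            intron = (
                "GT"
                + "".join(rng.choice(list("ACGT"), size=30))
                + "TTCTTCCTTTCC"
                + "AG"
            )
            gene = stub + intron + cassette
            exon1_rel = (0, len(stub))
            exon2_off = len(stub) + len(intron)
            exon2_rel = (
                exon2_off + rel["orf"][0],
                exon2_off + rel["orf"][1],
            )
            decap_rel = (
                exon2_off + rel["decapeptide"][0],
                exon2_off + rel["decapeptide"][1],
            )
            meta = {
                "exons_rel": [exon1_rel, exon2_rel],
                "decap_rel": decap_rel,
                "orf_rel": exon2_rel,
                "upstream_stop_nt": rel["upstream_stop_nt"],
            }
        else:
            gene, info = _kissr_cassette(implant, rng)
            meta = {"exons_rel": info["exons"], "protein": info["protein"]}
        if len(gene) > config.segment_length:
            raise ValueError(
                f"implant of {len(gene)} nt exceeds segment length "
                f"{config.segment_length}"
            )
        if cursor + len(gene) + 50 > config.segment_length:
            raise ValueError(
                f"segment {seg_id} too short for its implants"
            )
        start = int(
            rng.integers(
                cursor,
                config.segment_length - len(gene) - 50 + 1,
            )
        ) if cursor < config.segment_length - len(gene) - 50 else cursor
        placed = gene if implant.strand == "+" else str(
            Seq(gene).reverse_complement()
        )
        seq[start : start + len(gene)] = list(placed)
        cursor = start + len(gene) + 10

        def fwd(rel_iv: tuple[int, int]) -> tuple[int, int]:
            if implant.strand == "+":
                return (start + rel_iv[0], start + rel_iv[1])
            g = len(gene)
            return (start + g - rel_iv[1], start + g - rel_iv[0])

        if isinstance(implant, KissImplant):
            genes.append(
                ImplantedGene(
                    segment_id=seg_id,
                    gene_type=implant.gene_type,
                    strand=implant.strand,
                    exons=[fwd(iv) for iv in meta["exons_rel"]],
                    degradation=implant.degradation,
                    decapeptide=implant.decapeptide,
                    decapeptide_interval=fwd(meta["decap_rel"]),
                    amidation_motif=implant.amidation_motif,
                    mature_length=implant.mature_length,
                    upstream_stop_distance_nt=meta["upstream_stop_nt"],
                    orf_interval=fwd(meta["orf_rel"]),
                )
            )
        else:
            genes.append(
                ImplantedGene(
                    segment_id=seg_id,
                    gene_type=implant.gene_type,
                    strand=implant.strand,
                    exons=[fwd(iv) for iv in meta["exons_rel"]],
                    degradation=implant.degradation,
                    protein=meta["protein"],
                )
            )

    return "".join(seq), genes


def make_neighborhood_tables(
    assignments: dict[str, str],
    marker_sets: dict[str, set[str]],
    drop_rate: float = 0.0,
    n_decoys: int = 5,
    seed: int = 0,
):
    """Neighborhood tables for assigned loci, with marker drop-out.

    For each locus -> paralogon assignment, emits a gene table containing
    the paralogon's markers minus ``round(drop_rate * n_markers)`` randomly
    dropped ones, plus ``n_decoys`` decoy genes, at random sorted positions
    around a focal locus.  Returns (DataFrame, dropped) where ``dropped``
    maps locus -> the dropped marker symbols.
    """
    import pandas as pd

    if not 0 <= drop_rate <= 1:
        raise ValueError("drop_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    dropped: dict[str, list[str]] = {}
    for locus, label in sorted(assignments.items()):
        if label not in marker_sets:
            raise ValueError(f"locus {locus!r} assigned to unknown paralogon {label!r}")
        markers = sorted(marker_sets[label])
        n_drop = round(drop_rate * len(markers))
        drop_idx = set(
            rng.choice(len(markers), size=n_drop, replace=False).tolist()
        )
        kept = [m for k, m in enumerate(markers) if k not in drop_idx]
        dropped[locus] = sorted(m for k, m in enumerate(markers) if k in drop_idx)
        symbols = kept + [f"DECOY{rng.integers(0, 10**6):06d}" for _ in range(n_decoys)]
        rng.shuffle(symbols)
        pos = np.sort(rng.choice(np.arange(1, 10**6), size=len(symbols) + 1, replace=False))
        focal_at = len(symbols) // 2
        focal_position = int(pos[focal_at])
        gene_pos = [int(p) for k, p in enumerate(pos) if k != focal_at]
        for sym, p in zip(symbols, gene_pos):
            rows.append(
                {
                    "locus": locus,
                    "species": "synthetic",
                    "segment": f"nbh_{locus}",
                    "symbol": sym,
                    "start": p,
                    "end": p + 1000,
                    "strand": rng.choice(["+", "-"]),
                    "focal_position": focal_position,
                }
            )
    return pd.DataFrame(rows), dropped


def make_scenario_dataset(
    tree,
    origin,
    losses: list[list[str] | tuple[str, ...]],
    gene_type: str = "gene",
) -> dict[str, str]:
    """Tip states implied by a gain at ``origin`` and losses on ``losses``.

    Each loss edge is identified by the tip set below it.  Loss edges must
    lie below the origin and no loss edge may be ancestral to another.
    Tips below any loss edge are absent; other tips below the origin are
    present; tips outside the origin clade are absent.
    """
    from .scenario import _clade_tips, _resolve_origin

    onode = _resolve_origin(tree, origin)
    clade = set(_clade_tips(onode))
    all_tips = set(_clade_tips(tree))
    loss_sets = [frozenset(e) for e in losses]
    valid_edges = set()
    for node in onode.traverse(include_self=False):
        valid_edges.add(frozenset(_clade_tips(node)))
    for ls in loss_sets:
        if ls not in valid_edges:
            raise ValueError(f"loss edge {sorted(ls)} is not an edge below origin")
    for a in loss_sets:
        for b in loss_sets:
            if a != b and a < b:
                raise ValueError(
                    f"nested loss edges: {sorted(a)} inside {sorted(b)}"
                )
    absent = set().union(*loss_sets) if loss_sets else set()
    states = {}
    for tip in all_tips:
        if tip not in clade or tip in absent:
            states[tip] = "absent"
        else:
            states[tip] = "present"
    return states
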