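"""File formats, configuration and the end-to-end pipeline driver.

Community-standard formats throughout: FASTA for sequences, aligned FASTA
for MSAs, Newick for trees, TSV for tables, YAML for configuration.  All
coordinates are 0-based half-open on the forward strand.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from . import mining, peptides, phylo, synteny
from .mining import GenomeSegment
from .synteny import GeneRecord, Neighborhood, ReferenceParalogon

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "newick_string",
    "read_neighborhoods",
    "read_paralogons",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("kissmine")

IUPAC_CHARS = set("ACGTUNRYSWKMBDHV*-") | set("EFILPQXZJ")  # DNA + protein


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping.

    Sequences are upper-cased (lowercase input is accepted and logged);
    duplicate ids and non-IUPAC characters are errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        raw = str(rec.seq)
        if raw != raw.upper():
            log.info("record %s: lowercase bases upper-cased", rec.id)
        seq = raw.upper()
        for k, c in enumerate(seq):
            if c not in IUPAC_CHARS:
                raise ValueError(
                    f"record {rec.id!r}: non-IUPAC character {c!r} at position {k}"
                )
        records[rec.id] = seq
    return records


def write_fasta(records: dict[str, str], path) -> None:
    """Write sequences as FASTA wrapped at 60 columns."""
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(recs)


def _to_number(text: str):
    try:
        f = float(text)
    except ValueError:
        return None
    return f


def read_newick(path_or_str) -> TreeNode:
    """Parse Newick; numeric internal-node labels become ``support``."""
    p = Path(str(path_or_str))
    if p.exists():
        text = p.read_text()
    else:
        text = str(path_or_str)
    if text.count("(") != text.count(")"):
        offset = min(text.rfind("("), len(text))
        raise ValueError(f"unbalanced parentheses in newick (near offset {offset})")
    import io as _io

    tree = TreeNode.read(_io.StringIO(text))
    for node in tree.non_tips(include_self=True):
        if node.name is not None:
            val = _to_number(node.name)
            if val is not None:
                node.support = val
                node.name = None
    return tree


def _fmt(x: float) -> str:
    return f"{x:g}"


def _newick_node(node: TreeNode) -> str:
    if node.is_tip():
        body = node.name or ""
    else:
        inner = ",".join(_newick_node(c) for c in node.children)
        support = getattr(node, "support", None)
        label = _fmt(support) if support is not None else (node.name or "")
        body = f"({inner}){label}"
    if node.length is not None:
        body += f":{_fmt(node.length)}"
    return body


def newick_string(tree: TreeNode) -> str:
    """Serialize a tree to Newick with %g number formatting.

    Supports (internal node values) are written as internal labels; the
    write -> read -> write round trip is byte-stable.
    """
    return _newick_node(tree) + ";"


def write_newick(tree: TreeNode, path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


def read_neighborhoods(path) -> dict[str, Neighborhood]:
    """Read a neighborhood gene table (TSV) into per-locus Neighborhoods.

    Expected columns: locus, species, segment, symbol, start, end, strand,
    focal_position.
    """
    df = pd.read_csv(path, sep="\t")
    out: dict[str, Neighborhood] = {}
    for locus, grp in df.groupby("locus", sort=True):
        first = grp.iloc[0]
        out[str(locus)] = Neighborhood(
            species=str(first["species"]),
            segment_id=str(first["segment"]),
            focal_position=int(first["focal_position"]),
            records=[
                GeneRecord(
                    symbol=str(r["symbol"]),
                    start=int(r["start"]),
                    end=int(r["end"]),
                    strand=str(r["strand"]),
                )
                for _, r in grp.iterrows()
            ],
        )
    return out


def read_paralogons(path) -> list[ReferenceParalogon]:
    """Load reference paralogon marker sets from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    refs = []
    for label, spec in raw["paralogons"].items():
        refs.append(
            ReferenceParalogon(
                label=label,
                markers=set(spec["markers"]),
                total_considered=spec.get("total_considered"),
            )
        )
    return refs


@dataclass
class PipelineConfig:
    """Paths and thresholds for an end-to-end run."""

    genome: str | None = None
    queries: str | None = None
    neighborhoods: str | None = None
    tree: str | None = None
    marker_sets: str | None = None
    states: str | None = None  # presence/absence TSV: taxon x gene type
    outdir: str = "kissmine_out"
    species: str = "unknown"
    rel_threshold: float = 0.4
    min_orf_nt: int = 60
    min_cv: float = 80.0
    short_orf_nt: int = 150
    close_stop_nt: int = 60
    max_conserved_subs: int = 1
    min_fraction: float = 0.25
    synteny_window: int = 15
    bootstrap: int = 100
    distance_method: str = "p"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _candidates_frame(cands) -> pd.DataFrame:
    rows = []
    for c in cands:
        h = c.hit
        rows.append(
            {
                "segment": h.orf.segment_id,
                "strand": h.orf.strand,
                "orf_start": h.orf.start,
                "orf_end": h.orf.end,
                "window_start": h.window_start_nt,
                "window_end": h.window_end_nt,
                "decapeptide": h.window,
                "best_query": h.best_query,
                "score": h.score,
                "amidation_class": h.amidation_class,
                "n_cleavage_sites": len(c.cleavage_sites),
                "mature_lengths": ",".join(
                    str(p.length) for p in c.mature_peptides
                ),
                "upstream_stop_nt": c.upstream_stop_distance_nt,
                "flags": ",".join(sorted(c.pseudogene_flags)),
                "verdict": c.verdict,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage: mine -> diagnose -> identity -> align ->
    tree -> classify -> scenario; outputs are written under ``outdir`` and
    summarised in the returned report.  Reproducible for fixed config+seed.
    """
    if config.genome is None:
        raise ValueError("config is missing the genome path")
    if config.queries is None:
        raise ValueError("config is missing the queries path")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.digest(), "stages": {}}

    def stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {}
        return report["stages"][name]

    try:
        s = stage("mine")
        genome = read_fasta(config.genome)
        queries = read_fasta(config.queries)
        segments = [
            GenomeSegment(id=k, species=config.species, sequence=v)
            for k, v in genome.items()
        ]
        cands = mining.mine_genome(
            segments,
            queries,
            rel_threshold=config.rel_threshold,
            min_len_nt=config.min_orf_nt,
            min_cv=config.min_cv,
            short_orf_nt=config.short_orf_nt,
            close_stop_nt=config.close_stop_nt,
            max_conserved_subs=config.max_conserved_subs,
        )
        table = _candidates_frame(cands)
        table.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        mature = {
            f"{c.hit.orf.segment_id}_{c.hit.window_start_nt}": c.mature_peptides[0].sequence
            for c in cands
            if c.mature_peptides
        }
        if mature:
            write_fasta(mature, outdir / "mature_peptides.fa")
        s["n_segments"] = len(segments)
        s["n_candidates"] = len(cands)
        s["n_intact"] = sum(1 for c in cands if c.verdict == "intact")

        s = stage("identity")
        decaps = {
            f"{c.hit.orf.segment_id}_{c.hit.window_start_nt}": c.hit.window
            for c in cands
        }
        decaps.update(queries)
        if len(decaps) >= 2:
            im = peptides.identity_matrix(decaps)
            im.to_frame().to_csv(outdir / "identity.tsv", sep="\t")
            s["n_peptides"] = len(decaps)

        s = stage("tree")
        phylo_input = {
            lab: seq + ""  # mature peptides plus amidation context are comparable
            for lab, seq in mature.items()
        }
        phylo_input.update(queries)
        if len(phylo_input) >= 3:
            msa = peptides.progressive_align(phylo_input)
            tree = phylo.bootstrap_supports(
                msa,
                n_replicates=config.bootstrap,
                seed=config.seed,
                method=config.distance_method,
            )
            write_newick(tree, outdir / "tree.nwk")
            s["n_taxa"] = len(phylo_input)
            s["n_bootstrap"] = config.bootstrap

        if config.neighborhoods and config.marker_sets:
            s = stage("classify")
            nbhs = read_neighborhoods(config.neighborhoods)
            refs = read_paralogons(config.marker_sets)
            rows = []
            for locus, nbh in sorted(nbhs.items()):
                assigned, scores = synteny.classify_locus(
                    nbh, refs, window=config.synteny_window
                )
                rows.append({"locus": locus, "assigned": assigned, **scores})
            cls_table = pd.DataFrame(rows)
            cls_table.to_csv(outdir / "classification.tsv", sep="\t", index=False)
            s["n_loci"] = len(rows)

        if config.tree and config.states:
            s = stage("scenario")
            from .scenario import build_scenario_table

            sp_tree = read_newick(config.tree)
            states = pd.read_csv(config.states, sep="\t", index_col=0)
            results = build_scenario_table(sp_tree, states)
            payload = {
                g: {
                    "origin": r.origin,
                    "event_count": r.event_count,
                    "loss_events": [list(e) for e in r.loss_events],
                    "uncertain": r.uncertain,
                }
                for g, r in results.items()
            }
            (outdir / "scenarios.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True)
            )
            s["n_gene_types"] = len(results)
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        failed = list(report["stages"])[-1] if report["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
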