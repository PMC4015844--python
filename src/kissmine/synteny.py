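"""Synteny-based classification of Kiss/KissR loci into paralogon types.

Kisspeptin genes diverge too fast for sequence alone to settle orthology,
but the four Kiss (and four KissR) paralogons — chromosomal regions
descended from one pre-duplication region via the 1R/2R whole-genome
duplications — retain characteristic neighbouring marker genes.  A
candidate locus is classified by counting, within a gene-rank window
around it, how many markers of each reference paralogon it shares.

A second concern is assembly incompleteness: when almost none of a
region's markers can be found anywhere in an assembly, the gene's absence
cannot be asserted.  ``assess_region_presence`` issues a ``region_missing``
verdict in that case, which downstream downgrades "absent" to "unknown".
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Neighborhood",
    "ReferenceParalogon",
    "classify_locus",
    "assess_region_presence",
]


@dataclass
class GeneRecord:
    symbol: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class Neighborhood:
    """Ordered gene records around a focal locus on one genomic segment."""

    species: str
    segment_id: str
    focal_position: int
    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.start, r.end))
        for r in self.records:
            r.symbol = r.symbol.upper()


@dataclass
class ReferenceParalogon:
    """Marker genes characterising one paralogon region.

    ``total_considered`` is the number of markers tracked for the
    region-presence assessment; it may exceed ``len(markers)`` when the
    reference region is characterised by more genes than are listed by
    symbol.
    """

    label: str
    markers: set[str]
    total_considered: int | None = None

    def __post_init__(self) -> None:
        self.markers = {m.upper() for m in self.markers}
        if self.total_considered is None:
            self.total_considered = len(self.markers)
        if self.total_considered < 1:
            raise ValueError("total_considered must be >= 1")


def classify_locus(
    nbh: Neighborhood,
    refs: list[ReferenceParalogon],
    window: int = 15,
) -> tuple[str, dict[str, int]]:
    """Assign a locus to a paralogon type by shared neighbouring markers.

    ``score(type)`` counts that type's markers among the ``window`` genes on
    each side of the focal locus (gene rank, not base pairs — assemblies of
    very different contiguity are compared).  The unique argmax wins;
    a tied positive maximum is ``ambiguous``; all-zero is ``unclassified``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    labels = [r.label for r in refs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate paralogon labels")
    scores = {r.label: 0 for r in refs}
    if nbh.records:
        # rank of the first gene at/after the focal position
        rank = 0
        for k, rec in enumerate(nbh.records):
            if rec.start >= nbh.focal_position:
                rank = k
                break
        else:
            rank = len(nbh.records)
        lo, hi = max(0, rank - window), min(len(nbh.records), rank + window)
        nearby = {rec.symbol for rec in nbh.records[lo:hi]}
        for ref in refs:
            scores[ref.label] = len(ref.markers & nearby)
    best = max(scores.values()) if scores else 0
    if best == 0:
        return "unclassified", scores
    winners = [lab for lab, s in scores.items() if s == best]
    if len(winners) > 1:
        return "ambiguous", scores
    return winners[0], scores


def assess_region_presence(
    assembly_symbols: set[str],
    ref: ReferenceParalogon,
    min_fraction: float = 0.25,
) -> tuple[int, float, str]:
    """Decide whether a paralogon region is represented in an assembly.

    Returns (number of the region's markers found anywhere in the assembly,
    the fraction of ``total_considered`` they represent, and the verdict
    ``region_present`` or ``region_missing``).  A ``region_missing`` verdict
    means a gene-absent call for this region is unsupported and should be
    reported as unknown.
    """
    symbols = {s.upper() for s in assembly_symbols}
    present = len(ref.markers & symbols)
    fraction = present / ref.total_considered
    verdict = "region_missing" if fraction < min_fraction else "region_present"
    return present, fraction, verdict
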