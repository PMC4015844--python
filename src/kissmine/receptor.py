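"""Validation of multi-exon kisspeptin-receptor (KissR) gene models.

KissR genes keep a conserved five-exon / four-intron architecture across
vertebrates, and KissR proteins are class-A GPCRs with seven transmembrane
helices.  This module does not discover exons — junctions come from
annotation or the synthetic-truth files — it validates them (every intron
must begin GT and end AG), splices and translates the CDS, and counts
transmembrane segments from Kyte–Doolittle windowed hydropathy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .mining import GenomeSegment

__all__ = [
    "ReceptorGeneModel",
    "GeneModelError",
    "validate_gene_model",
    "count_tm_domains",
    "KYTE_DOOLITTLE",
]

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


class GeneModelError(ValueError):
    """A gene model violating the splicing or framing rules."""

    def __init__(self, message: str, intron_index: int | None = None):
        super().__init__(message)
        self.intron_index = intron_index


@dataclass
class ReceptorGeneModel:
    segment_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: str
    protein: str
    tm_segments: list[tuple[int, int]] = field(default_factory=list)
    partial: bool = False

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


def validate_gene_model(
    segment: GenomeSegment,
    exons: list[tuple[int, int]],
    strand: str = "+",
    expected_exons: int = 5,
    tm_window: int = 19,
    tm_threshold: float = 1.6,
) -> ReceptorGeneModel:
    """Validate exon intervals against the GT–AG rule and assemble the CDS.

    Exon intervals are 0-based half-open forward-strand coordinates, given
    in 5'->3' transcript order (for the minus strand: descending forward
    coordinates).  Every intron must begin with GT and end with AG on the
    transcribed strand; the spliced CDS must translate without internal
    stop and end at a single terminal stop codon.  A model with fewer than
    ``expected_exons`` exons is flagged partial (e.g. exon-1 missing from
    an incomplete assembly).
    """
    if not exons:
        raise GeneModelError("no exons given")
    if strand not in "+-":
        raise GeneModelError(f"invalid strand {strand!r}")
    L = len(segment)
    for s, e in exons:
        if not (0 <= s < e <= L):
            raise GeneModelError(f"exon ({s}, {e}) outside segment")
    fwd_sorted = sorted(exons)
    for (s1, e1), (s2, e2) in zip(fwd_sorted, fwd_sorted[1:]):
        if e1 > s2:
            raise GeneModelError("overlapping exons")
    if strand == "+":
        if exons != fwd_sorted:
            raise GeneModelError("plus-strand exons must ascend 5'->3'")
    else:
        if exons != sorted(exons, reverse=True):
            raise GeneModelError("minus-strand exons must descend 5'->3'")

    total = sum(e - s for s, e in exons)
    if total % 3:
        raise GeneModelError("total exon length not divisible by 3")

    seq = segment.sequence

    def transcribed(s: int, e: int) -> str:
        raw = seq[s:e]
        return raw if strand == "+" else str(Seq(raw).reverse_complement())

    # intron k lies between exon k and exon k+1 in transcript order
    for k in range(len(exons) - 1):
        (s1, e1), (s2, e2) = exons[k], exons[k + 1]
        if strand == "+":
            intron = seq[e1:s2]
        else:
            intron = str(Seq(seq[e2:s1]).reverse_complement())
        if len(intron) < 4:
            raise GeneModelError(f"intron {k} too short", intron_index=k)
        if not intron.startswith("GT"):
            raise GeneModelError(
                f"intron {k} does not begin with GT (found {intron[:2]})",
                intron_index=k,
            )
        if not intron.endswith("AG"):
            raise GeneModelError(
                f"intron {k} does not end with AG (found {intron[-2:]})",
                intron_index=k,
            )

    cds = "".join(transcribed(s, e) for s, e in exons)
    aa = str(Seq(cds).translate())
    partial = len(exons) < expected_exons
    if aa.endswith("*"):
        protein = aa[:-1]
    elif partial:
        protein = aa  # terminal exon may be missing
    else:
        raise GeneModelError("spliced CDS lacks a terminal stop codon")
    if "*" in protein:
        raise GeneModelError(
            f"internal stop codon at residue {protein.index('*')}"
        )
    model = ReceptorGeneModel(
        segment_id=segment.id,
        strand=strand,
        exons=list(exons),
        cds=cds,
        protein=protein,
        partial=partial,
    )
    model.tm_segments = count_tm_domains(
        protein, window=tm_window, threshold=tm_threshold
    )
    return model


def count_tm_domains(
    protein: str,
    window: int = 19,
    threshold: float = 1.6,
    min_separation: int = 5,
) -> list[tuple[int, int]]:
    """Transmembrane segments from windowed Kyte–Doolittle hydropathy.

    A residue position belongs to a TM segment when the mean hydropathy of
    the ``window`` residues centred on it exceeds ``threshold``; maximal
    runs of such positions are reported as (start, end) half-open residue
    intervals, with runs separated by fewer than ``min_separation``
    residues merged.  Proteins shorter than the window yield no segments.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd number")
    n = len(protein)
    if n < window:
        return []
    values = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in protein])
    kernel = np.ones(window) / window
    means = np.convolve(values, kernel, mode="valid")  # centre positions
    half = window // 2
    above = means > threshold
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(above):
        if not above[i]:
            i += 1
            continue
        j = i
        while j < len(above) and above[j]:
            j += 1
        runs.append((i + half, j + half))  # centre index -> residue index
        i = j
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < min_separation:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return merged
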