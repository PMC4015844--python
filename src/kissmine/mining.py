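"""Mining of kisspeptin-like decapeptide (Kp(10)) coding ORFs in genomic DNA.

The core of a kisspeptin precursor gene is a short, highly conserved
10-residue peptide (Kp(10)) followed immediately by a proteolytic
cleavage / alpha-amidation signal of the form ``G-Basic-Basic`` or
``G-Basic-Stop``.  Because the rest of the precursor is poorly conserved,
mining proceeds ORF-first: all stop-to-stop open reading frames in all six
frames are enumerated, each translation is scanned for windows similar to
known Kp(10) queries, and every hit is annotated with its amidation-motif
class, upstream dibasic cleavage sites (candidate mature-peptide starts),
splice-acceptor sites in the span 5' of the decapeptide, and a set of
pseudogene flags summarising degeneration evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "GenomeSegment",
    "OrfHit",
    "DecapeptideHit",
    "MaturePeptide",
    "SpliceAcceptorSite",
    "PrecursorCandidate",
    "find_orfs",
    "scan_decapeptides",
    "classify_amidation",
    "predict_cleavage_sites",
    "score_splice_acceptors",
    "diagnose_pseudogene",
    "mine_segment",
    "mine_genome",
    "CONSERVED_POSITIONS",
    "PSEUDOGENE_THRESHOLDS",
]

DNA_ALPHABET = set("ACGTN")
BASIC = {"K", "R"}
DIBASIC_PAIRS = {"KR", "RR", "KK", "RK"}
PYRIMIDINES = {"C", "T"}

#: Kp(10) positions (1-based) that are nearly invariant across vertebrates,
#: with their expected residues: Asn2, Phe6, Arg9.
CONSERVED_POSITIONS = {2: "N", 6: "F", 9: "R"}

#: Default thresholds for pseudogene diagnosis: an ORF shorter than
#: ``short_orf_nt`` is suspiciously small for a precursor CDS; a delimiting
#: stop codon closer than ``close_stop_nt`` to the decapeptide leaves no room
#: for a signal peptide / N-terminal precursor; more than
#: ``max_conserved_subs`` substitutions at the invariant positions suggests
#: relaxed selection.
PSEUDOGENE_THRESHOLDS = {
    "short_orf_nt": 150,
    "close_stop_nt": 60,
    "max_conserved_subs": 1,
}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class GenomeSegment:
    """A named genomic DNA sequence (forward strand, 0-based half-open)."""

    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"segment {self.id!r}: empty sequence")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"segment {self.id!r}: invalid characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OrfHit:
    """A maximal stop-free codon run in one frame of one strand.

    Coordinates are always reported against the forward strand of the parent
    segment, 0-based half-open; delimiting stop codons are excluded from the
    interval.  ``frame`` is the frame on the scanned strand (0-2).
    ``bounded_5`` / ``bounded_3`` record whether the run was delimited by an
    actual stop codon (as opposed to the sequence edge).
    """

    segment_id: str
    strand: str
    frame: int
    start: int
    end: int
    aa_translation: str
    bounded_5: bool = True
    bounded_3: bool = True

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class MaturePeptide:
    """A candidate mature kisspeptin: from one residue after a dibasic
    cleavage site up to and including the last residue of the decapeptide."""

    sequence: str
    length: int
    start: int  # offset within the ORF translation


@dataclass
class SpliceAcceptorSite:
    """An AG dinucleotide preceded by a polypyrimidine tract.

    ``consensus_value`` is 100 x the pyrimidine fraction of the 12 nt
    immediately 5' of the AG.
    """

    position: int
    consensus_value: float


@dataclass
class DecapeptideHit:
    """A 10-residue window of an ORF translation similar to a Kp(10) query."""

    orf: OrfHit
    offset: int  # residue offset of the window within the ORF translation
    window: str
    score: float
    best_query: str
    amidation_class: str = "absent"
    conserved_position_substitutions: list[tuple[int, str, str]] = field(
        default_factory=list
    )
    # forward-strand nucleotide interval of the window (filled by the miner)
    window_start_nt: int | None = None
    window_end_nt: int | None = None


@dataclass
class PrecursorCandidate:
    """A decapeptide hit with full precursor-level annotation."""

    hit: DecapeptideHit
    cleavage_sites: list[int] = field(default_factory=list)
    mature_peptides: list[MaturePeptide] = field(default_factory=list)
    upstream_stop_distance_nt: int = 0
    splice_acceptors: list[SpliceAcceptorSite] = field(default_factory=list)
    pseudogene_flags: set[str] = field(default_factory=set)
    verdict: str = "intact"


def _validate_dna(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)}")
    return seq


def _translate_frame(seq: str, frame: int) -> str:
    """Translate one frame; trailing partial codon dropped.

    Any codon containing N translates to X (even when the ambiguity would
    resolve, e.g. CGN) and never terminates an ORF.
    """
    usable = len(seq) - frame
    usable -= usable % 3
    if usable <= 0:
        return ""
    sub = seq[frame : frame + usable]
    aa = list(str(Seq(sub).translate()))
    for i in range(len(aa)):
        if "N" in sub[3 * i : 3 * i + 3]:
            aa[i] = "X"
    return "".join(aa)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def find_orfs(segment: GenomeSegment, min_len_nt: int = 60) -> list[OrfHit]:
    """Enumerate all maximal stop-to-stop ORFs in all six frames.

    ORFs are stop-delimited, not ATG-initiated: a run of stop-free codons
    bounded by stop codons or the sequence edge.  Codons containing N
    translate to X and do not terminate a run.

    Parameters
    ----------
    segment : GenomeSegment
    min_len_nt : int
        Minimum ORF length in nucleotides; must be >= 3 and divisible by 3.
    """
    if min_len_nt < 3 or min_len_nt % 3:
        raise ValueError("min_len_nt must be >= 3 and divisible by 3")
    L = len(segment)
    hits: list[OrfHit] = []
    for strand in "+-":
        scan = segment.sequence if strand == "+" else _revcomp(segment.sequence)
        for frame in range(3):
            aa = _translate_frame(scan, frame)
            n_codons = len(aa)
            i = 0
            while i < n_codons:
                if aa[i] == "*":
                    i += 1
                    continue
                j = i
                while j < n_codons and aa[j] != "*":
                    j += 1
                if 3 * (j - i) >= min_len_nt:
                    s = frame + 3 * i
                    e = frame + 3 * j
                    if strand == "+":
                        start, end = s, e
                    else:
                        start, end = L - e, L - s
                    hits.append(
                        OrfHit(
                            segment_id=segment.id,
                            strand=strand,
                            frame=frame,
                            start=start,
                            end=end,
                            aa_translation=aa[i:j],
                            bounded_5=i > 0,
                            bounded_3=j < n_codons,
                        )
                    )
                i = j
    hits.sort(key=lambda h: (h.start, h.end, h.strand, h.frame))
    return hits


def _pair_score(a: str, b: str, matrix) -> float:
    """Substitution score; X (unknown residue) never matches anything."""
    if a == "X" or b == "X":
        return 0.0
    return float(matrix[a, b])


def _window_score(window: str, query: str, matrix) -> float:
    return sum(_pair_score(w, q, matrix) for w, q in zip(window, query))


def _self_score(query: str, matrix) -> float:
    return sum(_pair_score(q, q, matrix) for q in query)


def scan_decapeptides(
    orf: OrfHit,
    queries: dict[str, str] | list[str],
    matrix=None,
    rel_threshold: float = 0.4,
    conserved_positions: dict[int, str] | None = None,
) -> list[DecapeptideHit]:
    """Scan an ORF translation for 10-residue windows similar to Kp(10).

    A window is reported when its substitution score against at least one
    query reaches ``rel_threshold`` times that query's self-score.  The best
    query is the one maximising the score-to-self-score ratio.  Windows are
    additionally annotated with substitutions at the conserved Kp(10)
    positions (default: 2=N, 6=F, 9=R).
    """
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must be in (0, 1]")
    if isinstance(queries, list):
        queries = {f"query{i + 1}": q for i, q in enumerate(queries)}
    for qid, q in queries.items():
        if len(q) != 10:
            raise ValueError(f"query {qid!r} must be exactly 10 residues")
    matrix = _BLOSUM62 if matrix is None else matrix
    if conserved_positions is None:
        conserved_positions = CONSERVED_POSITIONS
    selfs = {qid: _self_score(q, matrix) for qid, q in queries.items()}
    aa = orf.aa_translation
    hits: list[DecapeptideHit] = []
    for off in range(len(aa) - 9):
        window = aa[off : off + 10]
        best_qid, best_score, best_ratio = None, 0.0, -1.0
        for qid, q in queries.items():
            sc = _window_score(window, q, matrix)
            ratio = sc / selfs[qid] if selfs[qid] > 0 else 0.0
            if ratio > best_ratio:
                best_qid, best_score, best_ratio = qid, sc, ratio
        if best_qid is None or best_ratio < rel_threshold:
            continue
        subs = [
            (pos, expected, window[pos - 1])
            for pos, expected in sorted(conserved_positions.items())
            if window[pos - 1] != expected
        ]
        hits.append(
            DecapeptideHit(
                orf=orf,
                offset=off,
                window=window,
                score=best_score,
                best_query=best_qid,
                conserved_position_substitutions=subs,
            )
        )
    return hits


def classify_amidation(
    orf_translation: str, window_end: int, stop_after_orf: bool = True
) -> str:
    """Classify the cleavage/amidation motif immediately 3' of a decapeptide.

    Grammar: ``canonical`` = G,[K/R],[K/R]; ``stop_type`` = G,[K/R] then the
    ORF-delimiting stop codon; ``degenerate`` = G,[K/R],non-basic or
    G,non-basic; ``absent`` otherwise (including no downstream context).
    """
    if window_end > len(orf_translation):
        raise ValueError("window_end beyond translation")
    down = orf_translation[window_end:]
    if not down or down[0] != "G":
        return "absent"
    rest = down[1:]
    if len(rest) >= 2 and rest[0] in BASIC:
        return "canonical" if rest[1] in BASIC else "degenerate"
    if len(rest) == 1 and rest[0] in BASIC:
        return "stop_type" if stop_after_orf else "absent"
    if len(rest) >= 1:  # rest[0] not basic
        return "degenerate"
    return "absent"


def predict_cleavage_sites(
    orf_translation: str, window_start: int
) -> tuple[list[int], list[MaturePeptide]]:
    """Predict dibasic (KR/RR/KK/RK) cleavage sites upstream of the
    decapeptide and the mature-peptide variants they define.

    Each dibasic pair wholly 5' of the window yields a candidate mature
    peptide starting immediately after the pair and ending at the last
    residue of the decapeptide.  Variants are returned longest first.
    """
    if window_start <= 0:
        raise ValueError("window_start must be positive")
    sites: list[int] = []
    peptides: list[MaturePeptide] = []
    for i in range(window_start - 1):
        if orf_translation[i : i + 2] in DIBASIC_PAIRS:
            sites.append(i)
            seq = orf_translation[i + 2 : window_start + 10]
            peptides.append(MaturePeptide(sequence=seq, length=len(seq), start=i + 2))
    return sites, peptides


def score_splice_acceptors(
    dna: str,
    search_interval: tuple[int, int],
    min_cv: float = 80.0,
) -> list[SpliceAcceptorSite]:
    """Score AG splice-acceptor candidates in ``search_interval``.

    The consensus value of an AG at position p is 100 x the pyrimidine (C/T)
    fraction of the 12 nt immediately 5' of it; the polypyrimidine tract must
    lie within the interval.  Only sites with consensus value strictly above
    ``min_cv`` are retained, ordered by position.
    """
    if not 0 <= min_cv <= 100:
        raise ValueError("min_cv must be in [0, 100]")
    dna = _validate_dna(dna)
    start, end = search_interval
    if start < 0 or end > len(dna) or start > end:
        raise ValueError("search interval outside sequence")
    sites: list[SpliceAcceptorSite] = []
    for p in range(start + 12, end - 1):
        if dna[p : p + 2] != "AG":
            continue
        tract = dna[p - 12 : p]
        cv = 100.0 * sum(c in PYRIMIDINES for c in tract) / 12.0
        if cv > min_cv:
            sites.append(SpliceAcceptorSite(position=p, consensus_value=cv))
    return sites


def diagnose_pseudogene(
    candidate: PrecursorCandidate,
    short_orf_nt: int = PSEUDOGENE_THRESHOLDS["short_orf_nt"],
    close_stop_nt: int = PSEUDOGENE_THRESHOLDS["close_stop_nt"],
    max_conserved_subs: int = PSEUDOGENE_THRESHOLDS["max_conserved_subs"],
) -> PrecursorCandidate:
    """Set pseudogene flags on a candidate and record a verdict.

    Flags: ``short_orf`` (ORF shorter than ``short_orf_nt``),
    ``no_dibasic_cleavage`` (no upstream dibasic pair, hence no predictable
    mature peptide), ``degenerate_amidation`` (amidation motif degenerate or
    absent), ``conserved_substitutions`` (more than ``max_conserved_subs``
    substitutions at invariant Kp(10) positions), ``close_upstream_stop``
    (delimiting 5' stop codon closer than ``close_stop_nt``).  Verdict is
    ``degenerate`` with two or more flags, else ``intact``.
    """
    flags: set[str] = set()
    hit = candidate.hit
    if hit.orf.length_nt < short_orf_nt:
        flags.add("short_orf")
    if not candidate.cleavage_sites:
        flags.add("no_dibasic_cleavage")
    if hit.amidation_class in ("degenerate", "absent"):
        flags.add("degenerate_amidation")
    if len(hit.conserved_position_substitutions) > max_conserved_subs:
        flags.add("conserved_substitutions")
    if (
        hit.orf.bounded_5
        and candidate.upstream_stop_distance_nt < close_stop_nt
    ):
        flags.add("close_upstream_stop")
    candidate.pseudogene_flags = flags
    candidate.verdict = "degenerate" if len(flags) >= 2 else "intact"
    return candidate


def mine_segment(
    segment: GenomeSegment,
    queries: dict[str, str] | list[str],
    rel_threshold: float = 0.4,
    min_len_nt: int = 60,
    min_cv: float = 80.0,
    matrix=None,
    conserved_positions: dict[int, str] | None = None,
    short_orf_nt: int = PSEUDOGENE_THRESHOLDS["short_orf_nt"],
    close_stop_nt: int = PSEUDOGENE_THRESHOLDS["close_stop_nt"],
    max_conserved_subs: int = PSEUDOGENE_THRESHOLDS["max_conserved_subs"],
) -> list[PrecursorCandidate]:
    """Full precursor mining on one segment: ORFs -> decapeptide windows ->
    amidation, cleavage/mature peptides, splice acceptors, pseudogene flags.
    """
    L = len(segment)
    rc = _revcomp(segment.sequence)
    candidates: list[PrecursorCandidate] = []
    for orf in find_orfs(segment, min_len_nt=min_len_nt):
        hits = scan_decapeptides(
            orf,
            queries,
            matrix=matrix,
            rel_threshold=rel_threshold,
            conserved_positions=conserved_positions,
        )
        if not hits:
            continue
        scan = segment.sequence if orf.strand == "+" else rc
        # ORF interval on the scanned strand
        if orf.strand == "+":
            scan_start = orf.start
        else:
            scan_start = L - orf.end
        for hit in hits:
            w_s = scan_start + 3 * hit.offset
            w_e = w_s + 30
            if orf.strand == "+":
                hit.window_start_nt, hit.window_end_nt = w_s, w_e
            else:
                hit.window_start_nt, hit.window_end_nt = L - w_e, L - w_s
            hit.amidation_class = classify_amidation(
                orf.aa_translation, hit.offset + 10, stop_after_orf=orf.bounded_3
            )
            if hit.offset > 0:
                sites, peptides = predict_cleavage_sites(
                    orf.aa_translation, hit.offset
                )
            else:
                sites, peptides = [], []
            acceptors = (
                score_splice_acceptors(scan, (scan_start, w_s), min_cv=min_cv)
                if w_s - scan_start >= 14
                else []
            )
            cand = PrecursorCandidate(
                hit=hit,
                cleavage_sites=sites,
                mature_peptides=peptides,
                upstream_stop_distance_nt=3 * hit.offset,
                splice_acceptors=acceptors,
            )
            diagnose_pseudogene(
                cand,
                short_orf_nt=short_orf_nt,
                close_stop_nt=close_stop_nt,
                max_conserved_subs=max_conserved_subs,
            )
            candidates.append(cand)
    return candidates


def mine_genome(
    segments: list[GenomeSegment],
    queries: dict[str, str] | list[str],
    **kwargs,
) -> list[PrecursorCandidate]:
    """Mine every segment of a genome; keyword arguments as ``mine_segment``."""
    out: list[PrecursorCandidate] = []
    for seg in segments:
        out.extend(mine_segment(seg, queries, **kwargs))
    return out
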