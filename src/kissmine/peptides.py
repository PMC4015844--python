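"""Pairwise identity and alignment of kisspeptin peptides.

Decapeptides (Kp(10)) are compared by ungapped positional identity with a
fixed denominator of 10 — the only rule under which the published cross-
species percentages are reproducible.  Variable-length mature peptides are
first aligned globally (affine gaps) and a simple progressive profile
aligner builds the multiple alignment consumed by the phylogeny stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "IdentityMatrix",
    "MultipleAlignment",
    "pairwise_identity",
    "identity_matrix",
    "global_align",
    "progressive_align",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP = "-"


@dataclass
class IdentityMatrix:
    """Symmetric matrix of pairwise identity fractions in [0, 1]."""

    labels: list[str]
    values: np.ndarray

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class MultipleAlignment:
    """Labelled rows of equal length over residues plus the gap symbol."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, label: str) -> str:
        return self.rows[self.labels.index(label)].replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def take_columns(self, idx) -> "MultipleAlignment":
        rows = ["".join(r[j] for j in idx) for r in self.rows]
        return MultipleAlignment(list(self.labels), rows)


def _identity_fraction(a: str, b: str) -> float:
    matches = sum(
        1 for x, y in zip(a, b) if x == y and x != "X" and x != GAP
    )
    return matches / len(a)


def pairwise_identity(a: str, b: str, **align_params) -> float:
    """Fraction of exactly matching positions between two peptides.

    Equal-length peptides are compared position-by-position without gaps
    (denominator = length).  Unequal lengths are globally aligned first and
    identity is computed over the alignment columns.  X matches nothing.
    """
    if not a or not b:
        raise ValueError("empty peptide sequence")
    if len(a) == len(b):
        return _identity_fraction(a, b)
    (ra, rb), _ = global_align(a, b, **align_params)
    return _identity_fraction(ra, rb)


def identity_matrix(peptides: dict[str, str] | list[tuple[str, str]]) -> IdentityMatrix:
    """Full symmetric identity matrix over a labelled peptide collection."""
    items = list(peptides.items()) if isinstance(peptides, dict) else list(peptides)
    if len(items) < 2:
        raise ValueError("need at least two peptides")
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate peptide labels")
    n = len(items)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            f = pairwise_identity(items[i][1], items[j][1])
            values[i, j] = values[j, i] = f
    return IdentityMatrix(labels=labels, values=values)


def _score(a: str, b: str, matrix) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(matrix[a, b])


def global_align(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> tuple[tuple[str, str], float]:
    """Optimal global alignment with affine gaps (Gotoh dynamic programming).

    ``gap_open`` is the cost of the first gap position and ``gap_extend`` of
    each subsequent one (both negative).  Traceback ties are broken
    deterministically: diagonal, then up (gap in ``b``), then left.
    Returns the aligned row pair and the optimal score.
    """
    if not a or not b:
        raise ValueError("empty peptide sequence")
    matrix = _BLOSUM62 if matrix is None else matrix
    n, m = len(a), len(b)
    NEG = -np.inf
    M = np.full((n + 1, m + 1), NEG)  # a[i-1] aligned to b[j-1]
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _score(a[i - 1], b[j - 1], matrix)
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    # traceback: prefer diagonal (M), then up (X), then left (Y)
    i, j = n, m
    score = max(M[n, m], X[n, m], Y[n, m])
    state = "M" if M[n, m] >= max(X[n, m], Y[n, m]) else (
        "X" if X[n, m] >= Y[n, m] else "Y"
    )
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                state = "X" if j == 0 else "Y"
                continue
            s = _score(a[i - 1], b[j - 1], matrix)
            prev = M[i, j] - s
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i -= 1
            j -= 1
            if M[i, j] == prev:
                state = "M"
            elif X[i, j] == prev:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            ra.append(a[i - 1])
            rb.append(GAP)
            if M[i - 1, j] + gap_open == X[i, j]:
                state = "M"
            elif X[i - 1, j] + gap_extend == X[i, j]:
                state = "X"
            else:
                state = "M"
            i -= 1
        else:  # Y
            ra.append(GAP)
            rb.append(b[j - 1])
            if M[i, j - 1] + gap_open == Y[i, j]:
                state = "M"
            elif Y[i, j - 1] + gap_extend == Y[i, j]:
                state = "Y"
            else:
                state = "M"
            j -= 1
    return ("".join(reversed(ra)), "".join(reversed(rb))), float(score)


def _profile_columns(rows: list[str]) -> list[str]:
    return ["".join(r[j] for r in rows) for j in range(len(rows[0]))]


def _profile_score(col: str, res: str, matrix, gap_open: float) -> float:
    """Mean substitution score of a residue against a profile column."""
    total = 0.0
    for c in col:
        total += gap_open if c == GAP else _score(c, res, matrix)
    return total / len(col)


def _align_profile(
    rows: list[str],
    seq: str,
    matrix,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], str]:
    """Global alignment of a sequence against a profile (linear-ish gaps,
    same traceback tie-break as global_align); existing gaps are frozen
    ("once a gap, always a gap")."""
    cols = _profile_columns(rows)
    n, m = len(cols), len(seq)
    gap = gap_open + gap_extend  # linear per-column gap cost
    M = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        M[i, 0] = gap * i
    for j in range(1, m + 1):
        M[0, j] = gap * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = M[i - 1, j - 1] + _profile_score(
                cols[i - 1], seq[j - 1], matrix, gap_open
            )
            up = M[i - 1, j] + gap
            left = M[i, j - 1] + gap
            M[i, j] = max(diag, up, left)
    i, j = n, m
    ops: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and M[i, j] == M[i - 1, j - 1] + _profile_score(
            cols[i - 1], seq[j - 1], matrix, gap_open
        ):
            ops.append("D")
            i -= 1
            j -= 1
        elif i > 0 and M[i, j] == M[i - 1, j] + gap:
            ops.append("U")
            i -= 1
        else:
            ops.append("L")
            j -= 1
    ops.reverse()
    new_rows = ["" for _ in rows]
    new_seq: list[str] = []
    ci = si = 0
    for op in ops:
        if op == "D":
            for k, r in enumerate(rows):
                new_rows[k] += r[ci]
            new_seq.append(seq[si])
            ci += 1
            si += 1
        elif op == "U":
            for k, r in enumerate(rows):
                new_rows[k] += r[ci]
            new_seq.append(GAP)
            ci += 1
        else:
            for k in range(len(rows)):
                new_rows[k] += GAP
            new_seq.append(seq[si])
            si += 1
    return new_rows, "".join(new_seq)


def progressive_align(
    peptides: dict[str, str] | list[tuple[str, str]],
    matrix=None,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> MultipleAlignment:
    """Progressive multiple alignment guided by descending pairwise identity.

    The most similar pair seeds the profile; remaining sequences join in
    order of their best identity to any sequence already included.  Gaps
    introduced into the profile are never removed.
    """
    items = list(peptides.items()) if isinstance(peptides, dict) else list(peptides)
    if len(items) < 2:
        raise ValueError("need at least two sequences")
    matrix = _BLOSUM62 if matrix is None else matrix
    labels = [lab for lab, _ in items]
    seqs = {lab: s for lab, s in items}
    n = len(labels)
    ident = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            f = pairwise_identity(items[i][1], items[j][1])
            ident[i, j] = ident[j, i] = f
    # seed with the most identical pair (ties: first in input order)
    besti, bestj, best = 0, 1, -1.0
    for i in range(n):
        for j in range(i + 1, n):
            if ident[i, j] > best:
                besti, bestj, best = i, j, ident[i, j]
    (ra, rb), _ = global_align(
        seqs[labels[besti]], seqs[labels[bestj]],
        matrix=matrix, gap_open=gap_open, gap_extend=gap_extend,
    )
    included = [besti, bestj]
    rows = [ra, rb]
    remaining = [k for k in range(n) if k not in included]
    while remaining:
        # next sequence: highest identity to any included one
        nxt = max(
            remaining,
            key=lambda k: (max(ident[k, i] for i in included), -k),
        )
        rows, new_row = _align_profile(
            rows, seqs[labels[nxt]], matrix, gap_open, gap_extend
        )
        included.append(nxt)
        rows.append(new_row)
        remaining.remove(nxt)
    # restore input order
    order = np.argsort(included, kind="stable")
    ordered_labels = [labels[included[k]] for k in order]
    ordered_rows = [rows[k] for k in order]
    return MultipleAlignment(labels=ordered_labels, rows=ordered_rows)
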