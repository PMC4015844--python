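"""Distance-based phylogenies of mature kisspeptins.

Pipeline: multiple alignment -> pairwise distances (p-distance or
Poisson-corrected) -> neighbor joining -> bootstrap supports by column
resampling -> outgroup rooting.  Trees are ``skbio.TreeNode`` objects;
internal-edge bootstrap supports live in the ``support`` attribute as
percentages in [0, 100].

The join loop is deterministic: Q-criterion ties are broken by the
lexicographically smallest pair of cluster representatives (a cluster is
represented by its smallest tip label), and negative branch lengths are
clamped to zero with the deficit absorbed by the sibling branch so the
joined pair's distance is preserved.
"""

from __future__ import annotations

import math

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .peptides import GAP, MultipleAlignment

__all__ = [
    "distances",
    "nj_tree",
    "bootstrap_supports",
    "root_tree",
    "majority_consensus",
    "tree_splits",
]

POISSON_CAP = 10.0


def _pair_distance(a: str, b: str) -> tuple[int, int]:
    """(mismatches, compared columns) with pairwise gap deletion."""
    mism = comp = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        comp += 1
        if x != y:
            mism += 1
    return mism, comp


def distances(
    msa: MultipleAlignment, method: str = "p", cap: float = POISSON_CAP
) -> DistanceMatrix:
    """Pairwise distances from an alignment.

    ``p``: mismatches / compared columns (pairwise gap deletion).
    ``poisson``: d = -ln(1 - p), capped at ``cap`` for saturated pairs.
    """
    if method not in ("p", "poisson"):
        raise ValueError(f"unknown distance method {method!r}")
    rows, labels = msa.rows, msa.labels
    if len(rows) < 3:
        raise ValueError("need at least 3 sequences")
    n = len(rows)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mism, comp = _pair_distance(rows[i], rows[j])
            if comp == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            p = mism / comp
            if method == "poisson":
                d = -math.log(1.0 - p) if p < 1.0 - 1e-9 else cap
                d = min(d, cap)
            else:
                d = p
            mat[i, j] = mat[j, i] = d
    dm = DistanceMatrix(mat, ids=list(labels))
    dm.method = method
    return dm


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining with deterministic tie-breaking.

    Returns an unrooted tree (trifurcating top node for > 3 taxa).
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    d: dict[frozenset, float] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d[frozenset((a, b))] = float(dm[a, b])

    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    # cluster representative = smallest tip label it contains
    active = sorted(labels)

    def dist(a: str, b: str) -> float:
        return d[frozenset((a, b))]

    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best_pair, best_q = None, np.inf
        for i in range(n):
            for j in range(i + 1, n):
                a, b = active[i], active[j]
                q = (n - 2) * dist(a, b) - r[a] - r[b]
                pair = tuple(sorted((a, b)))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (best_pair is None or pair < best_pair)
                ):
                    best_q, best_pair = q, pair
        a, b = best_pair
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        # clamp negatives; sibling absorbs the deficit (sum preserved)
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = la, lb
        parent = TreeNode(children=[na, nb])
        rep = min(a, b)
        nodes[rep] = parent
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist(a, c) + dist(b, c) - dab)
            d[frozenset((rep, c))] = max(duc, 0.0)
        active = sorted(k for k in active if k not in (a, b)) + [rep]
        active = sorted(set(active))

    # resolve the final three clusters around an unrooted top node
    a, b, c = sorted(active)
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    for lab, ln in ((a, la), (b, lb), (c, lc)):
        nodes[lab].length = max(ln, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return root


def tree_splits(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an (un)rooted tree.

    Each split is canonicalised as the tip set on the side *not* containing
    the lexicographically smallest tip label, making the representation
    independent of rooting.
    """
    tips = sorted(n.name for n in tree.tips())
    ref = tips[0]
    all_tips = set(tips)
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            splits.add(frozenset(side))
    return splits


def bootstrap_supports(
    msa: MultipleAlignment,
    n_replicates: int = 1000,
    seed: int = 0,
    method: str = "p",
) -> TreeNode:
    """NJ tree of the full alignment with bootstrap supports.

    Columns are resampled with replacement per replicate; the support of
    each internal edge is the percentage of replicate trees containing the
    same bipartition.  Reproducible for a fixed seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = nj_tree(distances(msa, method=method))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    ncol = msa.n_columns
    for _ in range(n_replicates):
        idx = rng.integers(0, ncol, size=ncol)
        rep = msa.take_columns(idx)
        try:
            rep_tree = nj_tree(distances(rep, method=method))
        except ValueError:
            continue  # a pair with zero comparable columns in this resample
        for split in tree_splits(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    tips = sorted(n.name for n in tree.tips())
    ref, all_tips = tips[0], set(tips)
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            node.support = 100.0 * counts.get(frozenset(side), 0) / n_replicates
    return tree


def supports_above(tree: TreeNode, threshold: float = 70.0) -> list[float]:
    """Display filter: internal supports at or above ``threshold``."""
    out = []
    for node in tree.non_tips(include_self=False):
        s = getattr(node, "support", None)
        if s is not None and s >= threshold:
            out.append(s)
    return out


def root_tree(tree: TreeNode, outgroup: str | set[str] | list[str]) -> TreeNode:
    """Root an unrooted tree on the edge separating a monophyletic outgroup
    from the ingroup, placing the root at the midpoint of that edge."""
    og = {outgroup} if isinstance(outgroup, str) else set(outgroup)
    tips = {t.name for t in tree.tips()}
    missing = og - tips
    if missing:
        raise ValueError(f"outgroup tips not in tree: {sorted(missing)}")
    if og == tips:
        raise ValueError("outgroup cannot contain every tip")
    target = None
    for node in tree.traverse(include_self=False):
        side = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        if side == og or side == tips - og:
            target = node
            break
    if target is None:
        conflicting = sorted(og)
        raise ValueError(
            f"outgroup is not monophyletic in the unrooted tree: {conflicting}"
        )
    rooted = tree.root_at(target, above=True, branch_attrs=["support"])
    return rooted


def majority_consensus(
    trees: list[TreeNode], threshold: float = 0.5
) -> TreeNode:
    """Majority-rule consensus: bipartitions occurring in more than
    ``threshold`` of the input trees, annotated with their occurrence
    percentage in ``support``."""
    if threshold < 0.5:
        raise ValueError("threshold must be >= 0.5")
    if not trees:
        raise ValueError("no trees given")
    tip_sets = [frozenset(t.name for t in tr.tips()) for tr in trees]
    if len(set(tip_sets)) != 1:
        raise ValueError("trees have mismatched tip sets")
    tips = sorted(tip_sets[0])
    n = len(trees)
    counts: dict[frozenset, int] = {}
    for tr in trees:
        for split in tree_splits(tr):
            counts[split] = counts.get(split, 0) + 1
    kept = {s: c for s, c in counts.items() if c / n > threshold}

    # star tree, then insert splits largest-first (majority splits are
    # pairwise compatible, so insertion order only matters for nesting)
    root = TreeNode(children=[TreeNode(name=t) for t in tips])
    for split, c in sorted(kept.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))):
        # find the smallest clade containing the split
        host = root
        changed = True
        while changed:
            changed = False
            for child in host.children:
                child_tips = (
                    {child.name} if child.is_tip() else {t.name for t in child.tips()}
                )
                if split <= child_tips:
                    host = child
                    changed = True
                    break
        members = []
        for child in list(host.children):
            child_tips = (
                {child.name} if child.is_tip() else {t.name for t in child.tips()}
            )
            if child_tips <= split:
                members.append(child)
        covered = {
            t.name for m in members for t in ([m] if m.is_tip() else m.tips())
        }
        if not members or covered != set(split):
            continue  # incompatible with already-inserted structure
        new = TreeNode()
        for m in members:
            host.remove(m)
            new.append(m)
        new.support = 100.0 * c / n
        host.append(new)
    return root
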