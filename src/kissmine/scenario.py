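"""Dollo-parsimony reconstruction of gene gain/loss scenarios.

Under Dollo parsimony a gene family is gained exactly once (at the origin
node) and may subsequently be lost any number of times, each loss silencing
an entire clade.  Given a rooted species tree and per-tip presence states
the minimal number of losses equals the number of maximal edges whose whole
descendant tip set is absent; tips whose state is ``unknown`` (e.g. because
the corresponding genomic region is missing from the assembly) are assigned
present or absent so as to minimise the loss count, with ties resolved
toward absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from skbio import TreeNode

__all__ = [
    "STATES",
    "ScenarioResult",
    "dollo_losses",
    "compare_hypotheses",
    "build_scenario_table",
]

STATES = ("present", "absent", "unknown")


@dataclass
class ScenarioResult:
    """Most-parsimonious loss scenario for one gene type.

    ``loss_events`` identifies each loss edge by the sorted tuple of tip
    labels below it.  ``uncertain`` is set when any tip state was unknown,
    meaning absence on the affected lineages cannot be ruled out.
    """

    gene_type: str
    origin: str
    loss_events: list[tuple[str, ...]]
    event_count: int
    unknown_assignments: dict[str, str] = field(default_factory=dict)
    uncertain: bool = False


def _resolve_origin(tree: TreeNode, origin) -> TreeNode:
    if origin is None or origin == "root":
        return tree
    if isinstance(origin, TreeNode):
        return origin
    node = tree.find(origin)
    return node


def _clade_tips(node: TreeNode) -> list[str]:
    if node.is_tip():
        return [node.name]
    return [t.name for t in node.tips()]


def dollo_losses(
    tree: TreeNode,
    states: dict[str, str],
    origin=None,
    gene_type: str = "gene",
) -> ScenarioResult:
    """Minimal Dollo loss scenario on a rooted tree.

    Parameters
    ----------
    tree : TreeNode
        Rooted species tree with uniquely labelled tips.
    states : dict
        Tip label -> ``present`` | ``absent`` | ``unknown``.
    origin : node name, TreeNode or None
        Node where the gene was gained; default the root.  Every present
        tip must descend from it.
    """
    onode = _resolve_origin(tree, origin)
    clade = set(_clade_tips(onode))
    all_tips = {t.name for t in tree.tips()} if not tree.is_tip() else {tree.name}
    for tip in all_tips:
        if tip not in states:
            raise ValueError(f"no state for tip {tip!r}")
        if states[tip] not in STATES:
            raise ValueError(f"invalid state {states[tip]!r} for tip {tip!r}")
    outside_present = [
        t for t in all_tips - clade if states[t] == "present"
    ]
    if outside_present:
        raise ValueError(
            "present tips outside the origin clade: "
            + ", ".join(sorted(outside_present))
        )

    INF = math.inf
    can_absent: dict[int, bool] = {}
    cost_present: dict[int, float] = {}

    for node in onode.postorder(include_self=True):
        key = id(node)
        if node.is_tip():
            s = states[node.name]
            can_absent[key] = s in ("absent", "unknown")
            cost_present[key] = 0.0 if s in ("present", "unknown") else INF
        else:
            can_absent[key] = all(can_absent[id(c)] for c in node.children)
            total = 0.0
            for c in node.children:
                lose = 1.0 if can_absent[id(c)] else INF
                total += min(cost_present[id(c)], lose)
            cost_present[key] = total

    loss_events: list[tuple[str, ...]] = []
    assignments: dict[str, str] = {}

    def assign_subtree(node: TreeNode, state: str) -> None:
        for t in [node] if node.is_tip() else node.tips():
            if states[t.name] == "unknown":
                assignments[t.name] = state

    def walk(node: TreeNode) -> None:
        # gene is present at this node
        if node.is_tip():
            if states[node.name] == "unknown":
                assignments[node.name] = "present"
            return
        for c in node.children:
            # tie (equal cost) resolved toward absent: charge loss high
            if can_absent[id(c)] and cost_present[id(c)] >= 1.0:
                loss_events.append(tuple(sorted(_clade_tips(c))))
                assign_subtree(c, "absent")
            else:
                walk(c)

    if onode.is_tip():
        if states[onode.name] == "absent":
            loss_events.append((onode.name,))
        elif states[onode.name] == "unknown":
            assignments[onode.name] = "present"
    else:
        walk(onode)

    uncertain = any(states[t] == "unknown" for t in clade)
    origin_name = onode.name if onode.name else "root"
    return ScenarioResult(
        gene_type=gene_type,
        origin=origin_name,
        loss_events=sorted(loss_events),
        event_count=len(loss_events),
        unknown_assignments=assignments,
        uncertain=uncertain,
    )


def compare_hypotheses(
    tree: TreeNode,
    gene_type: str,
    hypotheses: dict[str, dict[str, str]],
    origin=None,
) -> tuple[dict[str, int], list[str]]:
    """Dollo loss counts for competing per-tip state hypotheses.

    Returns the per-hypothesis event counts and the list of hypotheses
    attaining the minimal count (the most parsimonious; more than one name
    means a tie).
    """
    if len(hypotheses) < 2:
        raise ValueError("need at least two hypotheses")
    counts = {
        name: dollo_losses(tree, states, origin=origin, gene_type=gene_type).event_count
        for name, states in hypotheses.items()
    }
    best = min(counts.values())
    most_parsimonious = [n for n, c in counts.items() if c == best]
    return counts, most_parsimonious


def build_scenario_table(
    tree: TreeNode,
    matrix: pd.DataFrame,
    origins: dict[str, str] | None = None,
) -> dict[str, ScenarioResult]:
    """One most-parsimonious ``ScenarioResult`` per gene type.

    ``matrix`` is taxa x gene types with entries in ``STATES``; ``unknown``
    entries (propagated from region_missing assembly verdicts) mark the
    resulting scenario as uncertain and are never charged as losses on
    their own.
    """
    tips = {t.name for t in tree.tips()}
    extra = set(matrix.index) - tips
    if extra:
        raise ValueError(f"taxa not in tree: {sorted(extra)}")
    results: dict[str, ScenarioResult] = {}
    for gene in matrix.columns:
        states = {t: "absent" for t in tips}
        states.update(matrix[gene].to_dict())
        origin = (origins or {}).get(gene)
        results[gene] = dollo_losses(tree, states, origin=origin, gene_type=gene)
    return results
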