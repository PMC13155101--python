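"""Cross-method agreement: Robinson-Foulds, tanglegrams, discrepancy tables.

Each analysis method (RdRP phylogeny, Hel phylogeny, structural tree,
whole-genome CJD clustering) yields a tree and/or a leaf clustering.
This module quantifies how much they disagree: the Robinson-Foulds
metric on tree pairs, tanglegram layouts with iterative barycenter
untangling, and leaf x method assignment tables from which per-method
discrepancy counts against a reference method are tabulated.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tree_ops import Clustering, PhyloTree

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Robinson-Foulds


def _restrict(tree: PhyloTree, leaves: set[str]) -> PhyloTree:
    out = tree.copy()
    out.dtree.retain_taxa_with_labels(sorted(leaves))
    return out


def nontrivial_bipartitions(tree: PhyloTree) -> set[frozenset[frozenset[str]]]:
    """Unrooted bipartitions with >= 2 leaves on both sides.

    Each bipartition is the frozenset of its two leaf-label sides, so
    rooted/unrooted representations of the same split coincide.
    """
    all_leaves = tree.leaf_set()
    bips: set[frozenset[frozenset[str]]] = set()
    for nd in tree.dtree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        side = frozenset(lf.taxon.label if lf.taxon else lf.label
                         for lf in nd.leaf_iter())
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            bips.add(frozenset((side, other)))
    return bips


def robinson_foulds(t1: PhyloTree, t2: PhyloTree, normalized: bool = True) -> float:
    """Robinson-Foulds distance on the shared leaf set.

    Trees are pruned (on copies) to their shared leaves; the unnormalized
    distance counts non-trivial bipartitions present in exactly one tree.
    Normalization divides by the total non-trivial bipartition count of
    both pruned trees, giving a value in [0, 1].
    """
    shared = set(t1.leaf_set()) & set(t2.leaf_set())
    if len(shared) < 4:
        raise ValidationError(
            f"Robinson-Foulds needs >= 4 shared leaves, got {len(shared)}")
    b1 = nontrivial_bipartitions(_restrict(t1, shared))
    b2 = nontrivial_bipartitions(_restrict(t2, shared))
    rf = len(b1 ^ b2)
    if not normalized:
        return float(rf)
    denom = len(b1) + len(b2)
    return rf / denom if denom else 0.0


def rf_matrix(trees: dict[str, PhyloTree], normalized: bool = True) -> pd.DataFrame:
    """Pairwise RF among named trees (NaN where < 4 shared leaves)."""
    ids = sorted(trees)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            try:
                d = robinson_foulds(trees[a], trees[b], normalized=normalized)
            except ValidationError:
                d = float("nan")
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat


# ---------------------------------------------------------------------------
# Tanglegrams


@dataclass
class TanglegramLayout:
    left_order: list[str]
    right_order: list[str]
    matching: dict[str, str]
    crossings: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {"left_order": self.left_order, "right_order": self.right_order,
             "matching": dict(sorted(self.matching.items())),
             "crossings": self.crossings},
            indent=2, sort_keys=True) + "\n"


def _inversions(seq: list[int]) -> int:
    """Inversion count by merge sort, O(n log n)."""
    if len(seq) < 2:
        return 0
    mid = len(seq) // 2
    left, right = list(seq[:mid]), list(seq[mid:])
    count = _inversions(left) + _inversions(right)
    i = j = k = 0
    while i < len(left) and j < len(right):
        if left[i] <= right[j]:
            seq[k] = left[i]; i += 1
        else:
            seq[k] = right[j]; j += 1
            count += len(left) - i
        k += 1
    seq[k:] = left[i:] + right[j:]
    return count


def crossing_count(layout: TanglegramLayout) -> int:
    """Line crossings = inversions of the matched-pair permutation.

    Unmatched leaves are drawn but contribute no crossings.
    """
    rpos = {lab: i for i, lab in enumerate(layout.right_order)}
    perm = [rpos[layout.matching[lab]] for lab in layout.left_order
            if lab in layout.matching and layout.matching[lab] in rpos]
    return _inversions(perm)


def _nested(tree: PhyloTree):
    """Nested-list view of a tree: a leaf is its label, a node a list."""

    def build(nd):
        kids = nd.child_nodes()
        if not kids:
            return nd.taxon.label if nd.taxon else nd.label
        return [build(c) for c in kids]

    return build(tree.dtree.seed_node)


def _subtree_leaves(node) -> list[str]:
    if isinstance(node, str):
        return [node]
    return [lab for c in node for lab in _subtree_leaves(c)]


def _nested_leaf_order(node) -> list[str]:
    return _subtree_leaves(node)


def _bary_pass(node, pos: dict[str, float]) -> None:
    """Sort children by mean matched-leaf position on the opposite side;
    children without matched leaves keep their current relative position."""
    if isinstance(node, str):
        return

    def mean_pos(c):
        vals = [pos[x] for x in _subtree_leaves(c) if x in pos]
        return float(np.mean(vals)) if vals else None

    keyed = []
    for idx, c in enumerate(node):
        bc = mean_pos(c)
        keyed.append((idx if bc is None else bc, idx, c))
    keyed.sort(key=lambda t: (t[0], t[1]))
    node[:] = [c for _, _, c in keyed]
    for c in node:
        _bary_pass(c, pos)


def _orient_pass(node, pos: dict[str, float]) -> None:
    """Exact one-sided orientation for bifurcations: at each binary node
    pick the child order with fewer pairwise inversions against the fixed
    opposite-side positions (contributions are independent across nodes)."""
    if isinstance(node, str):
        return
    for c in node:
        _orient_pass(c, pos)
    if len(node) == 2:
        a = [pos[x] for x in _subtree_leaves(node[0]) if x in pos]
        b = [pos[x] for x in _subtree_leaves(node[1]) if x in pos]
        inv = sum(1 for x in a for y in b if x > y)
        if inv > len(a) * len(b) - inv:
            node.reverse()
    elif len(node) > 2:  # multifurcation: fall back to barycenter order
        _bary_pass(node, pos)
        return


def _mixed_pass(node, pos):
    _bary_pass(node, pos)
    _orient_pass(node, pos)


_PASS_KINDS = {"orient": _orient_pass, "bary": _bary_pass, "mixed": _mixed_pass}


def _internal_lists(node, acc):
    if isinstance(node, list):
        acc.append(node)
        for c in node:
            _internal_lists(c, acc)
    return acc


def _layout_of(ln, rn, matching) -> TanglegramLayout:
    lay = TanglegramLayout(_nested_leaf_order(ln), _nested_leaf_order(rn), matching)
    lay.crossings = crossing_count(lay)
    return lay


def _descend(ln, rn, matching, rev, iterations, order, kind):
    """Alternate one-sided passes; track the best layout seen after any pass."""
    ln, rn = copy.deepcopy(ln), copy.deepcopy(rn)
    fn = _PASS_KINDS[kind]
    best, best_state = None, None
    for _ in range(iterations):
        for side in order:
            if side == "R":
                pos = {matching[lab]: float(i)
                       for i, lab in enumerate(_nested_leaf_order(ln))
                       if lab in matching}
                fn(rn, pos)
            else:
                pos = {rev[lab]: float(i)
                       for i, lab in enumerate(_nested_leaf_order(rn))
                       if lab in rev}
                fn(ln, pos)
            lay = _layout_of(ln, rn, matching)
            if best is None or lay.crossings < best.crossings:
                best = lay
                best_state = (copy.deepcopy(ln), copy.deepcopy(rn))
    return best, best_state


def _polish(state, matching, rev, max_rounds: int = 3):
    """1-opt refinement: flip one internal node, re-run an orientation
    descent, keep strict improvements."""
    ln, rn = copy.deepcopy(state[0]), copy.deepcopy(state[1])
    cur = _layout_of(ln, rn, matching)
    cur_state = (ln, rn)
    for _ in range(max_rounds):
        improved = False
        for tree in (cur_state[0], cur_state[1]):
            for node in _internal_lists(tree, []):
                node.reverse()
                lay, st = _descend(cur_state[0], cur_state[1], matching, rev,
                                   1, "RL", "orient")
                if lay.crossings < cur.crossings:
                    cur, cur_state = lay, st
                    improved = True
                    break
                node.reverse()
            if improved:
                break
        if not improved:
            break
    return cur


def untangle(
    t_left: PhyloTree,
    t_right: PhyloTree,
    matching: dict[str, str],
    iterations: int = 3,
    seed: int = 0,
) -> TanglegramLayout:
    """Iterative two-sided untangling of a tanglegram.

    Runs a small portfolio of alternating one-sided descents for
    ``iterations`` iterations each — children reordered either by
    barycenter (mean matched-leaf position on the opposite side) or by
    the exact per-node inversion-minimising orientation — keeps the
    lowest-crossing layout seen, and applies a single-flip (1-opt)
    refinement to it. The initial layout is always a candidate, so the
    result never has more crossings than the input; fully deterministic
    (``seed`` is accepted for interface stability, all tie-breaks are
    positional).
    """
    del seed  # tie-breaks are positional and already deterministic
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    left_leaves = t_left.leaf_set()
    right_leaves = t_right.leaf_set()
    bad = sorted([k for k in matching if k not in left_leaves] +
                 [v for v in matching.values() if v not in right_leaves])
    if bad:
        raise ValidationError(f"matching references unknown leaves: {', '.join(bad)}")
    ln0, rn0 = _nested(t_left), _nested(t_right)
    rev = {v: k for k, v in matching.items()}

    best = _layout_of(ln0, rn0, matching)  # unchanged input is candidate 0
    best_state = (ln0, rn0)
    for order in ("RL", "LR"):
        for kind in ("orient", "bary", "mixed"):
            lay, st = _descend(ln0, rn0, matching, rev, iterations, order, kind)
            if lay is not None and lay.crossings < best.crossings:
                best, best_state = lay, st
    polished = _polish(best_state, matching, rev)
    return polished if polished.crossings < best.crossings else best


def tanglegram_svg(layout: TanglegramLayout, width: int = 400,
                   row_height: int = 18) -> str:
    """Minimal deterministic SVG of a tanglegram layout (labels + lines)."""
    n = max(len(layout.left_order), len(layout.right_order), 1)
    h = row_height * (n + 1)
    lines = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{h}">']
    ly = {lab: row_height * (i + 1) for i, lab in enumerate(layout.left_order)}
    ry = {lab: row_height * (i + 1) for i, lab in enumerate(layout.right_order)}
    for lab, y in ly.items():
        lines.append(f'<text x="5" y="{y}" font-size="10">{lab}</text>')
    for lab, y in ry.items():
        lines.append(f'<text x="{width - 80}" y="{y}" font-size="10">{lab}</text>')
    for a in layout.left_order:
        b = layout.matching.get(a)
        if b in ry:
            lines.append(f'<line x1="90" y1="{ly[a]}" x2="{width - 90}" y2="{ry[b]}" '
                         'stroke="grey" stroke-width="1"/>')
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Assignment tables and discrepancy statistics


@dataclass
class AssignmentTable:
    """Leaves x methods matrix of (harmonized) cluster labels.

    ``labels`` holds None where a method dropped a leaf (e.g. the
    structure-quality filter). ``harmonization`` records, per
    non-reference method, the mapping from its original cluster labels
    to reference labels.
    """

    leaves: list[str]
    methods: list[str]
    labels: pd.DataFrame  # index=leaves, columns=methods, object dtype
    reference_method: str
    harmonization: dict[str, dict[str, str]] = field(default_factory=dict)

    def label(self, leaf: str, method: str) -> str | None:
        v = self.labels.loc[leaf, method]
        return None if pd.isna(v) else str(v)

    def to_tsv(self) -> str:
        df = self.labels.copy()
        df.index.name = "leaf"
        return df.to_csv(sep="\t", na_rep="")


@dataclass
class MethodDiscrepancy:
    method_id: str
    n_compared: int
    n_disagree: int

    @property
    def pct_disagree(self) -> float:
        return 100.0 * self.n_disagree / self.n_compared if self.n_compared else 0.0


@dataclass
class DiscrepancyStats:
    reference_method: str
    per_method: dict[str, MethodDiscrepancy]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"method": m.method_id, "n_compared": m.n_compared,
             "n_disagree": m.n_disagree,
             "pct_disagree": round(m.pct_disagree, 4)}
            for m in self.per_method.values()
        ]
        return pd.DataFrame(rows, columns=["method", "n_compared", "n_disagree",
                                           "pct_disagree"])


def build_assignment_table(
    clusterings: list[Clustering],
    reference_method: str,
) -> AssignmentTable:
    """Join clusterings of one rank into a leaf x method label table.

    Non-reference cluster labels are harmonized to the reference label
    sharing the most leaves (ties -> lexicographically smallest reference
    label; the mapping is logged and stored). Clusters overlapping no
    reference cluster keep their original label, so novel groups survive.
    """
    ranks = {c.rank for c in clusterings}
    if len(ranks) > 1:
        raise ValidationError(f"clusterings mix ranks: {sorted(ranks)}")
    method_ids = [c.method_id for c in clusterings]
    if len(set(method_ids)) != len(method_ids):
        raise ValidationError("duplicate method_ids")
    if reference_method not in method_ids:
        raise ValidationError(f"reference method {reference_method!r} not among "
                              f"{method_ids}")
    by_method = {c.method_id: c for c in clusterings}
    ref = by_method[reference_method]
    leaves = sorted(set().union(*[c.leaves() for c in clusterings]))

    labels = pd.DataFrame(index=leaves, columns=method_ids, dtype=object)
    harmonization: dict[str, dict[str, str]] = {}
    for mid, cl in by_method.items():
        if mid == reference_method:
            mapping = {}
        else:
            mapping = {}
            for lab, members in sorted(cl.clusters().items()):
                overlaps: dict[str, int] = {}
                for rlab, rmembers in ref.clusters().items():
                    ov = len(members & rmembers)
                    if ov:
                        overlaps[rlab] = ov
                if overlaps:
                    best = sorted(overlaps.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
                    mapping[lab] = best
                    log.info("harmonize %s: %s -> %s (overlap %d)", mid, lab, best,
                             overlaps[best])
        harmonization[mid] = mapping
        for leaf, lab in cl.assignment.items():
            labels.loc[leaf, mid] = mapping.get(lab, lab)
    return AssignmentTable(leaves=leaves, methods=method_ids, labels=labels,
                           reference_method=reference_method,
                           harmonization=harmonization)


def discrepancy_stats(table: AssignmentTable) -> DiscrepancyStats:
    """Per-method disagreement with the reference on jointly-present leaves."""
    ref = table.labels[table.reference_method]
    per: dict[str, MethodDiscrepancy] = {}
    for mid in table.methods:
        if mid == table.reference_method:
            continue
        col = table.labels[mid]
        both = col.notna() & ref.notna()
        n_compared = int(both.sum())
        n_disagree = int((col[both] != ref[both]).sum())
        per[mid] = MethodDiscrepancy(mid, n_compared, n_disagree)
    return DiscrepancyStats(reference_method=table.reference_method, per_method=per)
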