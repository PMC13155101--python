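"""Independent reference implementations used only to check the package.

These deliberately use different code paths (dendropy's tree comparison,
brute-force enumeration, naive O(n^2)/O(n^3) algorithms) from the
implementations they validate.
"""

from __future__ import annotations

import numpy as np

import dendropy


# ---------------------------------------------------------------------------
# Random trees (newick text, so the oracle side never touches PhyloTree)


def random_binary_newick(labels: list[str], rng: np.random.Generator,
                         with_lengths: bool = True) -> str:
    nodes = [f"{lab}:1" if with_lengths else lab for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(f"({a},{b}):1" if with_lengths else f"({a},{b})")
    return nodes[0] + ";"


# ---------------------------------------------------------------------------
# Robinson-Foulds via dendropy (shared taxon namespace)


def dendropy_rf(newick1: str, newick2: str) -> int:
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(t1, t2))


# ---------------------------------------------------------------------------
# Crossing count, quadratic


def crossings_quadratic(left_order, right_order, matching) -> int:
    rpos = {lab: i for i, lab in enumerate(right_order)}
    pairs = [(i, rpos[matching[lab]]) for i, lab in enumerate(left_order)
             if lab in matching and matching[lab] in rpos]
    n = 0
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            (l1, r1), (l2, r2) = pairs[a], pairs[b]
            if (l1 - l2) * (r1 - r2) < 0:
                n += 1
    return n


# ---------------------------------------------------------------------------
# Exhaustive tanglegram optimum for binary trees


def _nested(dtree) -> list | str:
    def build(nd):
        kids = nd.child_nodes()
        return nd.taxon.label if not kids else [build(c) for c in kids]

    return build(dtree.seed_node)


def _leaves(node):
    return [node] if isinstance(node, str) else [x for c in node for x in _leaves(c)]


def _internals(node, acc):
    if isinstance(node, list):
        acc.append(node)
        for c in node:
            _internals(c, acc)
    return acc


def tanglegram_optimum(t_left, t_right, matching) -> int:
    """Exact minimum crossings over all rotations of both binary trees.

    Enumerates the 2^(n-1) left-tree rotation combinations; for each fixed
    left leaf order the right tree is optimized exactly, because with the
    opposite side fixed the crossing contribution of each internal node's
    child orientation is independent of all other nodes.
    """
    ln = _nested(t_left.dtree)
    rn = _nested(t_right.dtree)
    lints = _internals(ln, [])
    rints = _internals(rn, [])
    assert all(len(n) == 2 for n in lints + rints), "binary trees only"
    rleaves = {id(n): [_leaves(c) for c in n] for n in rints}

    def order(node, flips):
        if isinstance(node, str):
            return [node]
        kids = node[::-1] if flips.get(id(node)) else node
        return [x for c in kids for x in order(c, flips)]

    best = None
    for mask in range(2 ** len(lints)):
        flips = {id(n): bool(mask >> i & 1) for i, n in enumerate(lints)}
        pos = {}
        for i, lab in enumerate(order(ln, flips)):
            if lab in matching:
                pos[matching[lab]] = i
        total = 0
        for n in rints:
            a = [pos[x] for x in rleaves[id(n)][0] if x in pos]
            b = [pos[x] for x in rleaves[id(n)][1] if x in pos]
            inv = sum(1 for x in a for y in b if x > y)
            total += min(inv, len(a) * len(b) - inv)
        if best is None or total < best:
            best = total
    return best


# ---------------------------------------------------------------------------
# Naive agglomerative clustering (UPGMA-family), O(n^3)


def naive_linkage_heights(ids: list[str], d: np.ndarray,
                          method: str = "average") -> dict[frozenset, float]:
    """Merge heights (= distance/2) per cluster, by naive agglomeration."""
    clusters = {frozenset([i]): [i] for i in range(len(ids))}
    dist = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dist[(frozenset([i]), frozenset([j]))] = d[i, j]

    def get(a, b):
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    heights = {}
    while len(clusters) > 1:
        keys = list(clusters)
        best = None
        for x in range(len(keys)):
            for y in range(x + 1, len(keys)):
                dv = get(keys[x], keys[y])
                if best is None or dv < best[0]:
                    best = (dv, keys[x], keys[y])
        dv, a, b = best
        merged = a | b
        heights[frozenset(ids[i] for i in merged)] = dv / 2.0
        for other in clusters:
            if other in (a, b):
                continue
            if method == "average":
                nv = (get(a, other) * len(a) + get(b, other) * len(b)) / (len(a) + len(b))
            elif method == "single":
                nv = min(get(a, other), get(b, other))
            else:
                nv = max(get(a, other), get(b, other))
            dist[(merged, other)] = nv
        del clusters[a], clusters[b]
        clusters[merged] = list(merged)
    return heights
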