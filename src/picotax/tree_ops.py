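"""Trees, dendrograms and fixed-depth rank demarcation.

Phylogenies (from hallmark-gene or structural analyses) and UPGMA-style
dendrograms built from composite Jaccard distance (CJD) matrices are both
represented by :class:`PhyloTree`, a thin wrapper around a dendropy tree.
Rank demarcation is a fixed-depth cut: every edge whose parent lies above
the cut depth and whose child lies at or below it subtends one cluster.

Support values are carried as internal-node labels (the common newick
dialect) and normalised to the unit interval at parse time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ParseError, ValidationError

RANK_PREFIX = {"order": "O", "family": "F", "genus": "G"}


def _rank_prefix(rank: str) -> str:
    return RANK_PREFIX.get(rank, rank[:1].upper() or "C")


# ---------------------------------------------------------------------------
# PhyloTree


class PhyloTree:
    """Rooted or unrooted tree with branch lengths and optional supports.

    Leaf labels are unique strings. Internal-node labels, when numeric,
    are interpreted as support values normalised to [0, 1].
    """

    def __init__(self, dtree: dendropy.Tree, rooted: bool):
        self.dtree = dtree
        self.rooted = rooted
        self._check_leaves()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, support_scale: str = "auto") -> "PhyloTree":
        return read_newick(text, support_scale=support_scale)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.dtree.clone(depth=1), self.rooted)

    # -- basic structure ---------------------------------------------------

    def _check_leaves(self) -> None:
        labels = self.leaf_labels()
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        if dupes:
            raise ValidationError(f"duplicate leaf labels: {', '.join(dupes)}")
        if any(lab is None or lab == "" for lab in labels):
            raise ValidationError("empty leaf label")

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label if lf.taxon else lf.label
                for lf in self.dtree.leaf_node_iter()]

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_labels())

    def n_leaves(self) -> int:
        return len(self.leaf_labels())

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Root-to-node path distance on the branch-length scale."""
        depths: dict[dendropy.Node, float] = {}
        for nd in self.dtree.preorder_node_iter():
            if nd.parent_node is None:
                depths[nd] = 0.0
            else:
                depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
        return depths

    def max_leaf_depth(self) -> float:
        depths = self.node_depths()
        return max(depths[lf] for lf in self.dtree.leaf_node_iter())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = self.node_depths()
        leaf_d = [depths[lf] for lf in self.dtree.leaf_node_iter()]
        span = max(leaf_d) - min(leaf_d)
        scale = max(max(leaf_d), 1e-12)
        return span <= rel_tol * scale

    def leaf_distances(self) -> pd.DataFrame:
        """All-pairs leaf path distances (square symmetric frame)."""
        pdm = self.dtree.phylogenetic_distance_matrix()
        labels = sorted(self.leaf_labels())
        taxa = {t.label: t for t in self.dtree.taxon_namespace if t.label in labels}
        mat = np.zeros((len(labels), len(labels)))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    d = pdm.patristic_distance(taxa[a], taxa[b])
                    mat[i, j] = mat[j, i] = d
        return pd.DataFrame(mat, index=labels, columns=labels)

    # -- supports ----------------------------------------------------------

    @staticmethod
    def node_support(node: dendropy.Node) -> float | None:
        if node.is_leaf() or node.label is None:
            return None
        try:
            return float(node.label)
        except ValueError:
            return None

    def supports(self) -> list[float]:
        vals = [self.node_support(nd) for nd in self.dtree.preorder_internal_node_iter()]
        return [v for v in vals if v is not None]

    # -- serialisation -----------------------------------------------------

    def to_newick(self) -> str:
        s = self.dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".10g",
        )
        return s.strip() + "\n"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree n_leaves={self.n_leaves()} rooted={self.rooted}>"


def read_newick(text: str, support_scale: str = "auto") -> PhyloTree:
    """Parse a newick string, normalising internal-node-label supports.

    ``support_scale``: ``unit`` (already in [0,1]), ``percent`` (0-100,
    divided by 100) or ``auto`` (percent inferred when any value exceeds 1).
    """
    if support_scale not in ("auto", "unit", "percent"):
        raise ValueError(f"unknown support_scale {support_scale!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse exception types
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"duplicate leaf labels: {exc}") from exc
        raise ParseError(f"newick parse failure: {exc}") from exc

    numeric_nodes = []
    for nd in dtree.preorder_internal_node_iter():
        if nd.label is not None:
            try:
                numeric_nodes.append((nd, float(nd.label)))
            except ValueError:
                pass
    scale = support_scale
    if scale == "auto":
        scale = "percent" if any(v > 1.0 for _, v in numeric_nodes) else "unit"
    for nd, v in numeric_nodes:
        s = v / 100.0 if scale == "percent" else v
        if not 0.0 <= s <= 1.0:
            raise ValidationError(f"support {v} out of range after {scale} scaling")
        nd.label = format(s, ".10g")

    rooted = dtree.is_rooted is True or (
        dtree.seed_node is not None and len(dtree.seed_node.child_nodes()) == 2
    )
    return PhyloTree(dtree, rooted=rooted)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


# ---------------------------------------------------------------------------
# Rooting


def _adjacency(dt: dendropy.Tree):
    adj: dict[dendropy.Node, list[tuple[dendropy.Node, float]]] = {}
    for nd in dt.preorder_node_iter():
        adj.setdefault(nd, [])
        for ch in nd.child_nodes():
            w = ch.edge.length or 0.0
            adj[nd].append((ch, w))
            adj.setdefault(ch, []).append((nd, w))
    return adj


def _farthest_leaf(adj, start):
    """(distances, predecessors, farthest leaf) — label tie-break."""
    dist = {start: 0.0}
    pred = {start: None}
    stack = [start]
    while stack:
        nd = stack.pop()
        for nb, w in adj[nd]:
            if nb not in dist:
                dist[nb] = dist[nd] + w
                pred[nb] = nd
                stack.append(nb)
    leaves = [nd for nd in dist if not nd.child_nodes() or nd.taxon is not None]
    leaves = [nd for nd in leaves if nd.taxon is not None]
    far = max(leaves, key=lambda nd: (dist[nd], nd.taxon.label))
    return dist, pred, far


def _midpoint_reroot(dt: dendropy.Tree) -> None:
    """Reroot at the midpoint of the tree diameter (double-sweep)."""
    any_leaf = min(dt.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    adj = _adjacency(dt)
    _, _, a = _farthest_leaf(adj, any_leaf)
    dist_a, pred, b = _farthest_leaf(adj, a)
    target = dist_a[b] / 2.0
    # walk the a->b path until the cumulative distance reaches the midpoint
    path = [b]
    while pred[path[-1]] is not None:
        path.append(pred[path[-1]])
    path.reverse()  # a ... b
    tol = 1e-9
    cum_prev = 0.0
    for prev, nxt in zip(path, path[1:]):
        cum_next = dist_a[nxt]
        if abs(cum_next - target) <= tol and nxt.child_nodes():
            dt.reroot_at_node(nxt, update_bipartitions=False)
            return
        if abs(cum_prev - target) <= tol and prev.child_nodes():
            dt.reroot_at_node(prev, update_bipartitions=False)
            return
        if cum_prev < target < cum_next:
            child = nxt if nxt.parent_node is prev else prev
            parent_side = target - cum_prev if child is nxt else cum_next - target
            child_side = (child.edge.length or 0.0) - parent_side
            dt.reroot_at_edge(child.edge, length1=parent_side,
                              length2=child_side, update_bipartitions=False)
            return
        cum_prev = cum_next
    raise ValidationError("midpoint not found on tree diameter")  # pragma: no cover


def root_tree(
    tree: PhyloTree,
    mode: str = "midpoint",
    outgroup_leaves: list[str] | None = None,
) -> PhyloTree:
    """Root a tree at the midpoint or on the edge above an outgroup clade.

    Leaf set and all pairwise leaf path distances are preserved.
    """
    out = tree.copy()
    dt = out.dtree
    if mode == "midpoint":
        _midpoint_reroot(dt)
    elif mode == "outgroup":
        if not outgroup_leaves:
            raise ValidationError("outgroup mode requires outgroup_leaves")
        present = out.leaf_set()
        missing = sorted(set(outgroup_leaves) - present)
        if missing:
            raise ValidationError(f"outgroup leaves absent from tree: {', '.join(missing)}")
        if set(outgroup_leaves) == present:
            raise ValidationError("outgroup cannot be the entire leaf set")
        dt.is_rooted = True  # treat current seed as root for MRCA lookup
        mrca = dt.mrca(taxon_labels=list(outgroup_leaves))
        if mrca is dt.seed_node:
            # outgroup spans the current root; root on the complement side
            comp = sorted(present - set(outgroup_leaves))
            mrca = dt.mrca(taxon_labels=comp)
        edge = mrca.edge
        if edge.length:
            dt.reroot_at_edge(edge, length1=edge.length / 2.0,
                              length2=edge.length / 2.0,
                              update_bipartitions=False)
        else:
            dt.reroot_at_edge(edge, update_bipartitions=False)
    else:
        raise ValueError(f"unknown rooting mode {mode!r}")
    dt.is_rooted = True
    out.rooted = True
    return out


# ---------------------------------------------------------------------------
# Clusterings and fixed-depth cuts


@dataclass(frozen=True)
class RankCut:
    """A demarcation boundary: rank name plus root-to-point path depth."""

    rank: str
    depth: float

    def __post_init__(self):
        if self.depth < 0:
            raise ValidationError(f"cut depth must be >= 0, got {self.depth}")


@dataclass
class Clustering:
    """A partition of leaf labels into named clusters at one rank."""

    method_id: str
    rank: str
    assignment: dict[str, str]
    cluster_support: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self):
        for leaf, lab in self.assignment.items():
            if not lab:
                raise ValidationError(f"empty cluster label for leaf {leaf!r}")

    def clusters(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for leaf, lab in self.assignment.items():
            out.setdefault(lab, set()).add(leaf)
        return {lab: frozenset(m) for lab, m in out.items()}

    def leaves(self) -> frozenset[str]:
        return frozenset(self.assignment)

    def relabelled(self, mapping: dict[str, str]) -> "Clustering":
        return Clustering(
            self.method_id, self.rank,
            {leaf: mapping.get(lab, lab) for leaf, lab in self.assignment.items()},
            cluster_support={mapping.get(k, k): v for k, v in self.cluster_support.items()},
        )


def _label_clusters(members: list[frozenset[str]], rank: str) -> dict[str, frozenset[str]]:
    """Deterministic labels: sort clusters by their smallest member leaf."""
    prefix = _rank_prefix(rank)
    ordered = sorted(members, key=lambda m: min(m))
    return {f"{prefix}{i + 1:03d}": m for i, m in enumerate(ordered)}


def cut_at_depth(tree: PhyloTree, cut: RankCut, method_id: str = "tree") -> Clustering:
    """Partition leaves by cutting a rooted tree at a fixed depth.

    A cluster is the leaf set below each edge crossing the cut
    (parent depth < cut.depth <= child depth). Leaves whose whole
    root path is shallower than the cut become singletons. Depth 0
    yields a single all-leaf cluster.
    """
    if not tree.rooted:
        raise ValidationError("cut_at_depth requires a rooted tree; root it first "
                              "(root_tree, mode='midpoint' or 'outgroup')")
    leaf_all = tree.leaf_set()
    if cut.depth == 0:
        clusters = [leaf_all]
    else:
        depths = tree.node_depths()
        clusters = []
        covered: set[str] = set()
        for nd in tree.dtree.preorder_node_iter():
            par = nd.parent_node
            if par is None:
                continue
            if depths[par] < cut.depth <= depths[nd]:
                mem = frozenset(
                    lf.taxon.label if lf.taxon else lf.label
                    for lf in nd.leaf_iter()
                )
                clusters.append(mem)
                covered |= mem
        for leaf in leaf_all - covered:  # shallow leaves
            clusters.append(frozenset([leaf]))
    labelled = _label_clusters(clusters, cut.rank)
    assignment = {leaf: lab for lab, mem in labelled.items() for leaf in sorted(mem)}
    # partition sanity
    if len(assignment) != len(leaf_all):
        raise ValidationError("cut did not produce a partition of the leaf set")
    return Clustering(method_id=method_id, rank=cut.rank,
                      assignment=dict(sorted(assignment.items())))


@dataclass(frozen=True)
class ClusterSupport:
    support: float | None
    passes: bool | None  # None = not assessable
    assessable: bool


def cluster_support(
    tree: PhyloTree,
    clustering: Clustering,
    threshold: float = 0.7,
) -> dict[str, ClusterSupport]:
    """Support on the edge subtending each cluster, gated at ``threshold``.

    Singleton clusters and clusters spanning the whole leaf set have no
    subtending internal edge and are marked not assessable (passes=None).
    """
    leaf_all = tree.leaf_set()
    node_leaves: dict[frozenset[str], dendropy.Node] = {}
    for nd in tree.dtree.postorder_node_iter():
        mem = frozenset(lf.taxon.label if lf.taxon else lf.label
                        for lf in nd.leaf_iter())
        node_leaves.setdefault(mem, nd)
    out: dict[str, ClusterSupport] = {}
    for lab, mem in clustering.clusters().items():
        if len(mem) == 1 or mem == leaf_all or mem not in node_leaves:
            out[lab] = ClusterSupport(None, None, False)
            continue
        nd = node_leaves[mem]
        sup = PhyloTree.node_support(nd)
        if sup is None:
            out[lab] = ClusterSupport(None, None, False)
        else:
            out[lab] = ClusterSupport(sup, sup >= threshold, True)
    return out


# ---------------------------------------------------------------------------
# CJD matrices and dendrograms


@dataclass
class CjdMatrix:
    """Symmetric composite-Jaccard-distance matrix in [0, 1].

    A distance of 1.0 marks genome pairs with no detectable relatedness.
    """

    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate ids in CJD matrix")
        if self.d.shape != (n, n):
            raise ValidationError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValidationError("CJD matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-9):
            raise ValidationError("CJD matrix diagonal must be zero")
        if self.d.min() < -1e-12 or self.d.max() > 1.0 + 1e-12:
            raise ValidationError("CJD entries must lie in [0, 1]")


def read_cjd_tsv(text: str) -> CjdMatrix:
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError("CJD TSV row ids and column ids differ")
    return CjdMatrix(ids=[str(x) for x in df.index], d=df.to_numpy(dtype=float))


def write_cjd_tsv(m: CjdMatrix) -> str:
    df = pd.DataFrame(m.d, index=m.ids, columns=m.ids)
    return df.to_csv(sep="\t", float_format="%.10g")


def dendrogram_from_cjd(m: CjdMatrix, linkage: str = "average") -> PhyloTree:
    """Agglomerate a CJD matrix into an ultrametric rooted dendrogram.

    Ultrametric convention: two leaves merged at distance d sit at height
    d/2, so the root-to-leaf depth equals (root merge distance)/2.
    """
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    n = len(m.ids)
    if n == 1:
        dt = dendropy.Tree()
        tax = dt.taxon_namespace.new_taxon(label=m.ids[0])
        dt.seed_node.taxon = tax
        dt.is_rooted = True
        return PhyloTree(dt, rooted=True)
    Z = hierarchy.linkage(squareform(m.d, checks=False), method=linkage)
    dt = dendropy.Tree()
    dt.is_rooted = True
    nodes: dict[int, tuple[dendropy.Node, float]] = {}
    for i, lab in enumerate(m.ids):
        nd = dendropy.Node()
        nd.taxon = dt.taxon_namespace.new_taxon(label=lab)
        nodes[i] = (nd, 0.0)
    for k, (a, b, dist, _cnt) in enumerate(Z):
        h = dist / 2.0
        nd = dendropy.Node()
        for child_idx in (int(a), int(b)):
            child, ch = nodes.pop(child_idx)
            child.edge.length = max(h - ch, 0.0)
            nd.add_child(child)
        nodes[n + k] = (nd, h)
    (root, _root_h), = nodes.values()
    dt.seed_node = root
    return PhyloTree(dt, rooted=True)


# ---------------------------------------------------------------------------
# Clustering TSV i/o


def write_clusterings_tsv(clusterings: list[Clustering]) -> str:
    rows = []
    for cl in clusterings:
        for leaf in sorted(cl.assignment):
            lab = cl.assignment[leaf]
            sup = cl.cluster_support.get(lab)
            rows.append((leaf, cl.method_id, cl.rank, lab,
                         "" if sup is None else format(sup, ".10g")))
    df = pd.DataFrame(rows, columns=["leaf", "method_id", "rank",
                                     "cluster_label", "support"])
    return df.to_csv(sep="\t", index=False)


def read_clusterings_tsv(text: str) -> list[Clustering]:
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str).fillna("")
    need = {"leaf", "method_id", "rank", "cluster_label"}
    if not need <= set(df.columns):
        raise ParseError(f"clustering TSV missing columns {sorted(need - set(df.columns))}")
    out = []
    for (method_id, rank), grp in df.groupby(["method_id", "rank"], sort=True):
        assignment = dict(zip(grp["leaf"], grp["cluster_label"]))
        support: dict[str, float | None] = {}
        if "support" in grp.columns:
            for lab, sup in zip(grp["cluster_label"], grp["support"]):
                if sup != "":
                    support[lab] = float(sup)
        out.append(Clustering(method_id=method_id, rank=rank,
                              assignment=assignment, cluster_support=support))
    return out
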