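"""Synthetic inputs with known ground truth.

Every other module is testable offline: planted ultrametric trees whose
clades are the true clusters, NNI perturbations for tree-distance laws,
toy genomes with embedded hallmark domains plus matching InterPro-style
XML, two-level CJD block matrices with planted order/family structure,
and structure metadata. Identical parameters and seed give byte-identical
outputs; each generator also returns its planted truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import ValidationError
from .genome_domains import GenomeRecord, find_orfs, write_fasta
from .tree_ops import CjdMatrix, Clustering, PhyloTree, _label_clusters

_AA = "ACDEFGHIKLNPQRSTVWY"  # M excluded so planted starts stay unambiguous
_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC", "G": "GGC",
    "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTG", "N": "AAC", "P": "CCG",
    "Q": "CAA", "R": "CGC", "S": "TCC", "T": "ACC", "V": "GTC", "W": "TGG",
    "Y": "TAC", "M": "ATG",
}


# ---------------------------------------------------------------------------
# Planted ultrametric trees


def _random_ultrametric_clade(labels: list[str], height: float,
                              rng: np.random.Generator) -> tuple[dendropy.Node, float]:
    """Random binary ultrametric topology over ``labels``, root at ``height``."""
    if len(labels) == 1:
        nd = dendropy.Node()
        nd.label = labels[0]
        return nd, 0.0

    def build(labs: list[str], h: float) -> tuple[dendropy.Node, float]:
        if len(labs) == 1:
            nd = dendropy.Node()
            nd.label = labs[0]
            return nd, 0.0
        nd = dendropy.Node()
        split = int(rng.integers(1, len(labs)))
        for part in (labs[:split], labs[split:]):
            ch = h * float(rng.uniform(0.3, 0.7)) if len(part) > 1 else 0.0
            child, child_h = build(part, ch)
            child.edge.length = h - child_h
            nd.add_child(child)
        return nd, h

    return build(labels, height)


def make_planted_tree(
    k: int,
    sizes: list[int],
    within_height: float,
    between_height: float,
    seed: int = 0,
    rank: str = "family",
    leaf_names: list[list[str]] | None = None,
) -> tuple[PhyloTree, Clustering]:
    """Ultrametric tree of ``k`` well-separated clades plus truth clustering.

    Clade roots sit at height ``within_height`` above the leaves, the tree
    root at ``between_height``; any cut depth strictly between the root and
    the clade tops recovers the k planted clades exactly. Clade roots carry
    support 1.0.
    """
    if not (between_height > within_height > 0):
        raise ValidationError("need between_height > within_height > 0")
    if len(sizes) != k:
        raise ValidationError(f"sizes has {len(sizes)} entries for k={k}")
    if any(s < 1 for s in sizes):
        raise ValidationError("clade sizes must be >= 1")
    rng = np.random.default_rng(seed)
    if leaf_names is None:
        leaf_names = [[f"c{ci + 1:02d}t{j + 1:02d}" for j in range(s)]
                      for ci, s in enumerate(sizes)]
    if [len(g) for g in leaf_names] != list(sizes):
        raise ValidationError("leaf_names group sizes do not match sizes")

    dt = dendropy.Tree()
    dt.is_rooted = True
    root = dt.seed_node
    clades = []
    for labs in leaf_names:
        clade, _ = _random_ultrametric_clade(list(labs), within_height, rng)
        clade.edge.length = between_height - (within_height if len(labs) > 1 else 0.0)
        if len(labs) > 1:
            clade.label = "1"  # full support on planted clades
        clades.append(clade)
        root.add_child(clade)
    # attach taxa to leaves
    for lf in dt.leaf_node_iter():
        lf.taxon = dt.taxon_namespace.new_taxon(label=lf.label)
        lf.label = None
    tree = PhyloTree(dt, rooted=True)

    labelled = _label_clusters([frozenset(g) for g in leaf_names], rank)
    assignment = {leaf: lab for lab, mem in labelled.items() for leaf in sorted(mem)}
    truth = Clustering(method_id="truth", rank=rank,
                       assignment=dict(sorted(assignment.items())))
    return tree, truth


def perturb_tree_nni(tree: PhyloTree, n_moves: int, seed: int = 0) -> PhyloTree:
    """Apply ``n_moves`` random nearest-neighbour interchanges.

    Each move picks an internal edge (u, v), a child x of v and the
    sibling subtree w of v under u, and swaps x and w. Leaf set is
    preserved; a single move changes exactly one non-trivial bipartition.
    """
    rng = np.random.default_rng(seed)
    out = tree.copy()
    dt = out.dtree
    for _ in range(n_moves):
        # an edge whose parent is a degree-2 root is not an internal edge of
        # the unrooted topology: swapping across it leaves the tree unchanged
        internal_edges = [
            nd for nd in dt.preorder_internal_node_iter()
            if nd.parent_node is not None
            and len(nd.parent_node.child_nodes()) >= 2
            and not (nd.parent_node is dt.seed_node
                     and len(dt.seed_node.child_nodes()) == 2)
        ]
        if not internal_edges:
            raise ValidationError("tree has no internal edge for an NNI move")
        v = internal_edges[int(rng.integers(len(internal_edges)))]
        u = v.parent_node
        siblings = [c for c in u.child_nodes() if c is not v]
        w = siblings[int(rng.integers(len(siblings)))]
        kids = v.child_nodes()
        x = kids[int(rng.integers(len(kids)))]
        v.remove_child(x)
        u.remove_child(w)
        v.add_child(w)
        u.add_child(x)
    return out


# ---------------------------------------------------------------------------
# Toy genomes + InterPro-style XML


@dataclass
class ToyGenomeSet:
    fasta: str
    xml: str
    truth: dict  # genome_id -> expected harvest outcome
    min_aa_len: int


def _toy_xml(entries: list[dict]) -> str:
    ns = "https://ftp.ebi.ac.uk/pub/software/unix/iprscan/5/schema"
    parts = [f'<protein-matches xmlns="{ns}">']
    for e in entries:
        parts.append("  <protein>")
        parts.append(f'    <sequence md5="na">{e["aa"]}</sequence>')
        parts.append(f'    <xref id="{e["orf_id"]}" name="{e["orf_id"]}"/>')
        parts.append("    <matches>")
        for m in e["matches"]:
            parts.append(f'      <hmmer3-match evalue="{m["evalue"]}" score="{m["score"]}">')
            parts.append(f'        <signature ac="{m["ac"]}" name="{m["name"]}">')
            parts.append('          <signature-library-release library="PFAM" version="37.0"/>')
            parts.append("        </signature>")
            parts.append("        <locations>")
            parts.append(f'          <hmmer3-location start="{m["start"]}" end="{m["end"]}" '
                         f'score="{m["score"]}" evalue="{m["evalue"]}"/>')
            parts.append("        </locations>")
            parts.append("      </hmmer3-match>")
        parts.append("    </matches>")
        parts.append("  </protein>")
    parts.append("</protein-matches>")
    return "\n".join(parts) + "\n"


def make_toy_genome_set(
    n: int,
    with_rdrp: float = 1.0,
    with_hel: float = 1.0,
    seed: int = 0,
    protein_len: int = 600,
    min_aa_len: int = 100,
) -> ToyGenomeSet:
    """Toy genomes with planted hallmark domains and matching XML.

    Each genome carries one ORF whose translation holds an RdRP segment
    and/or a Hel segment at known coordinates; fractions control how many
    genomes receive each domain. The truth table records the expected
    kept/omitted decision and the planted domain subsequences.
    """
    if not (0 <= with_rdrp <= 1 and 0 <= with_hel <= 1):
        raise ValidationError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"g{i + 1:03d}" for i in range(n)]
    has_rdrp = {g: False for g in ids}
    has_hel = {g: False for g in ids}
    for g in rng.permutation(ids)[: int(round(with_rdrp * n))]:
        has_rdrp[str(g)] = True
    for g in rng.permutation(ids)[: int(round(with_hel * n))]:
        has_hel[str(g)] = True

    rd_lo, rd_hi = protein_len // 2, protein_len // 2 + 240  # 240-aa RdRP
    hl_lo, hl_hi = 50, 180  # 130-aa Hel

    fasta_records: list[tuple[str, str]] = []
    xml_entries: list[dict] = []
    truth: dict[str, dict] = {}
    for gid in ids:
        prot = "".join(rng.choice(list(_AA), size=protein_len))
        cds = "".join(_CODON[a] for a in prot)
        pad1 = "C" * (3 * int(rng.integers(4, 14)))
        pad2 = "C" * (3 * int(rng.integers(4, 14)))
        seq = pad1 + "ATG" + cds + "TAA" + pad2
        fasta_records.append((gid, seq))
        start = len(pad1)
        genome = GenomeRecord(id=gid, sequence=seq)
        orfs = find_orfs(genome, min_aa_len=min_aa_len)
        planted = [o for o in orfs if o.start == start and o.strand == "+"]
        if len(planted) != 1 or planted[0].aa_sequence != "M" + prot:
            raise ValidationError(f"fixture self-check failed for {gid}")
        orf = planted[0]
        # planted coordinates are on the ORF translation ("M" + prot)
        matches = []
        if has_rdrp[gid]:
            matches.append({"ac": "PF00680", "name": "RdRP_1",
                            "start": rd_lo + 2, "end": rd_hi + 1,
                            "score": 250.0, "evalue": 1e-80})
        if has_hel[gid]:
            matches.append({"ac": "PF00910", "name": "RNA_helicase",
                            "start": hl_lo + 2, "end": hl_hi + 1,
                            "score": 120.0, "evalue": 1e-40})
        matches.append({"ac": "PF99999", "name": "uncharacterised protein",
                        "start": 2, "end": 40, "score": 10.0, "evalue": 0.1})
        xml_entries.append({"orf_id": orf.orf_id, "aa": orf.aa_sequence,
                            "matches": matches})
        reason = ""
        if not has_rdrp[gid] and not has_hel[gid]:
            reason = "no_rdrp_no_hel"
        elif not has_rdrp[gid]:
            reason = "no_rdrp"
        elif not has_hel[gid]:
            reason = "no_hel"
        truth[gid] = {
            "kept": reason == "",
            "reason": reason,
            "orf_id": orf.orf_id,
            "rdrp_seq": orf.aa_sequence[rd_lo + 1: rd_hi + 1] if has_rdrp[gid] else None,
            "hel_seq": orf.aa_sequence[hl_lo + 1: hl_hi + 1] if has_hel[gid] else None,
        }
    return ToyGenomeSet(fasta=write_fasta(fasta_records), xml=_toy_xml(xml_entries),
                        truth=truth, min_aa_len=min_aa_len)


# ---------------------------------------------------------------------------
# CJD block matrices


@dataclass
class CjdBlocks:
    matrix: CjdMatrix
    order_truth: Clustering
    family_truth: Clustering


def make_cjd_blocks(
    orders: list[list[int]],
    within_family: float = 0.5,
    within_order: float = 0.85,
    between_order: float = 0.99,
    seed: int = 0,
    jitter: float = 0.0,
    ids: list[str] | None = None,
) -> CjdBlocks:
    """Two-level block CJD matrix with planted order/family structure.

    ``orders`` lists family sizes per order, e.g. [[3, 2], [4]]. Default
    levels bracket the demarcation boundaries: families merge at 0.5,
    orders at 0.85, unrelated orders at 0.99. Jitter must preserve the
    level ordering or a validation error is raised.
    """
    if not (0 <= within_family < within_order < between_order <= 1):
        raise ValidationError("need 0 <= within_family < within_order < between_order <= 1")
    rng = np.random.default_rng(seed)
    n = sum(sum(fams) for fams in orders)
    if ids is None:
        ids = [f"v{i + 1:03d}" for i in range(n)]
    if len(ids) != n:
        raise ValidationError(f"{len(ids)} ids for {n} taxa")

    order_members: list[frozenset[str]] = []
    family_members: list[frozenset[str]] = []
    level = np.zeros((n, n), dtype=int)  # 0 within family, 1 within order, 2 between
    pos = 0
    for fams in orders:
        o_start = pos
        for size in fams:
            family_members.append(frozenset(ids[pos:pos + size]))
            pos += size
        order_members.append(frozenset(ids[o_start:pos]))
    idx_order = {i: next(k for k, m in enumerate(order_members) if ids[i] in m)
                 for i in range(n)}
    idx_family = {i: next(k for k, m in enumerate(family_members) if ids[i] in m)
                  for i in range(n)}
    base = {0: within_family, 1: within_order, 2: between_order}
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if idx_family[i] == idx_family[j]:
                lvl = 0
            elif idx_order[i] == idx_order[j]:
                lvl = 1
            else:
                lvl = 2
            level[i, j] = level[j, i] = lvl
            val = base[lvl] + (float(rng.uniform(-jitter, jitter)) if jitter else 0.0)
            d[i, j] = d[j, i] = min(max(val, 0.0), 1.0)
    for lo, hi in ((0, 1), (1, 2)):
        lo_vals = d[level == lo]
        hi_vals = d[level == hi]
        if lo_vals.size and hi_vals.size and lo_vals.max() >= hi_vals.min():
            raise ValidationError(
                f"jitter {jitter} breaks the level ordering "
                f"(max level-{lo} {lo_vals.max():.4f} >= min level-{hi} {hi_vals.min():.4f})")
    matrix = CjdMatrix(ids=list(ids), d=d)

    fam_lab = _label_clusters(family_members, "family")
    ord_lab = _label_clusters(order_members, "order")
    family_truth = Clustering("truth", "family", dict(sorted(
        (leaf, lab) for lab, mem in fam_lab.items() for leaf in mem)))
    order_truth = Clustering("truth", "order", dict(sorted(
        (leaf, lab) for lab, mem in ord_lab.items() for leaf in mem)))
    return CjdBlocks(matrix=matrix, order_truth=order_truth, family_truth=family_truth)


# ---------------------------------------------------------------------------
# Structure metadata fixtures


def make_structure_meta_tsv(ids: list[str], seed: int = 0,
                            length_mean: int = 500, plddt_lo: float = 85.0,
                            plddt_hi: float = 95.0) -> str:
    """Structure metadata TSV for the given ids, all passing default QC."""
    rng = np.random.default_rng(seed)
    lines = ["id\tlength_aa\tmean_plddt"]
    for i in sorted(ids):
        length = int(length_mean + rng.integers(-30, 31))
        plddt = float(rng.uniform(plddt_lo, plddt_hi))
        lines.append(f"{i}\t{length}\t{plddt:.2f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Full fixture directory (consumed by the `run` pipeline)


def write_fixture_set(
    path,
    seed: int = 0,
    family_sizes: tuple[int, ...] = (5, 4, 4, 3),
    novel_family_index: int = 3,
    within_height: float = 1.0,
    between_height: float = 3.0,
) -> dict:
    """Write a coherent end-to-end fixture directory and its truth JSON.

    Four analysis methods share one planted family structure: three trees
    (rdrp / hel / struct, differing only in within-clade topology) and one
    CJD block matrix. One planted family is left out of the established
    labels so the consensus stage should propose it as a new taxon.
    """
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    k = len(family_sizes)
    toy = make_toy_genome_set(sum(family_sizes), seed=seed)
    gids = sorted(toy.truth)
    leaf_groups: list[list[str]] = []
    pos = 0
    for s in family_sizes:
        leaf_groups.append(gids[pos:pos + s])
        pos += s

    (path / "genomes.fasta").write_text(toy.fasta)
    (path / "interpro.xml").write_text(toy.xml)

    trees = {}
    truth_cl = None
    for i, mid in enumerate(("rdrp", "hel", "struct")):
        tree, truth_cl = make_planted_tree(
            k, list(family_sizes), within_height, between_height,
            seed=seed * 101 + i, leaf_names=leaf_groups)
        trees[mid] = tree
        (path / f"{mid}.nwk").write_text(tree.to_newick())
    blocks = make_cjd_blocks([list(family_sizes)], seed=seed,
                             ids=[g for grp in leaf_groups for g in grp])
    from .tree_ops import write_cjd_tsv

    (path / "cjd.tsv").write_text(write_cjd_tsv(blocks.matrix))
    (path / "structures.tsv").write_text(make_structure_meta_tsv(gids, seed=seed))

    labelled = {lab: mem for lab, mem in truth_cl.clusters().items()}
    novel_members = frozenset(leaf_groups[novel_family_index])
    novel_label = next(lab for lab, mem in labelled.items() if mem == novel_members)
    established = sorted(lab for lab in labelled if lab != novel_label)
    (path / "established.txt").write_text("\n".join(established) + "\n")

    cut_depth = (between_height - within_height) / 2.0 + within_height / 2.0
    config = f"""\
genomes_fasta: genomes.fasta
interpro_xml: interpro.xml
trees:
  rdrp: rdrp.nwk
  hel: hel.nwk
  struct: struct.nwk
cjd_tsv: cjd.tsv
structures_tsv: structures.tsv
established_labels: established.txt
rank: family
rank_depth: {cut_depth}
reference_method: rdrp
seed: {seed}
"""
    (path / "config.yaml").write_text(config)

    truth = {
        "harvest": toy.truth,
        "family_assignment": truth_cl.assignment,
        "novel_family": {"label": novel_label, "members": sorted(novel_members)},
        "established": established,
    }
    (path / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return truth
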