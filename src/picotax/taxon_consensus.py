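"""Demarcation thresholds and cross-method consensus proposal of new taxa.

Composite-Jaccard-distance (CJD) dendrograms are demarcated with the
order (>0.95) and family (>0.70) lower boundaries used for RNA-virus
orders. Novel groups — clusters whose label is not in the supplied
established-taxa list — are proposed as new taxa when at least
``min_methods_agree`` of the analysis methods recover the same group;
where methods split a group, membership follows the reference method
(RdRP phylogeny primacy) and the proposal is flagged for expert review.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .method_compare import AssignmentTable, DiscrepancyStats
from .tree_ops import Clustering, ClusterSupport, PhyloTree, RankCut, cut_at_depth

log = logging.getLogger(__name__)

PROPOSED = "proposed"
FLAGGED = "flagged_for_review"
REJECTED = "rejected"


@dataclass
class DemarcationConfig:
    """Thresholds governing demarcation and the consensus rule.

    CJD boundaries follow the order/family lower demarcation boundaries
    (>0.95 order, >0.70 family) on the composite-Jaccard scale; the
    bootstrap gate follows the >=0.7 support convention for family
    groupings.
    """

    order_lower_cjd: float = 0.95
    family_lower_cjd: float = 0.70
    bootstrap_min: float = 0.7
    min_methods_agree: int = 2
    methods_total: int = 4
    reference_method: str = "rdrp"
    match_tolerance: str = "exact"  # exact | superset

    def __post_init__(self):
        if not (0 < self.family_lower_cjd < self.order_lower_cjd <= 1):
            raise ValidationError(
                f"need 0 < family_lower_cjd ({self.family_lower_cjd}) < "
                f"order_lower_cjd ({self.order_lower_cjd}) <= 1")
        if not (1 <= self.min_methods_agree <= self.methods_total):
            raise ValidationError(
                f"need 1 <= min_methods_agree ({self.min_methods_agree}) <= "
                f"methods_total ({self.methods_total})")
        if self.match_tolerance not in ("exact", "superset"):
            raise ValidationError(f"unknown match_tolerance {self.match_tolerance!r}")


@dataclass
class TaxonProposal:
    proposal_id: str
    rank: str
    member_leaves: frozenset[str]
    supporting_methods: frozenset[str]
    status: str
    rationale: str

    def __post_init__(self):
        if not self.member_leaves:
            raise ValidationError(f"{self.proposal_id}: empty member set")
        if self.status not in (PROPOSED, FLAGGED, REJECTED):
            raise ValidationError(f"{self.proposal_id}: bad status {self.status!r}")


# ---------------------------------------------------------------------------
# CJD demarcation


def demarcate_cjd(
    dendrogram: PhyloTree,
    cfg: DemarcationConfig | None = None,
    method_id: str = "cjd",
) -> tuple[Clustering, Clustering]:
    """Cut a CJD dendrogram at the order and family boundaries.

    Under the ultrametric convention a merge at CJD ``d`` sits at height
    ``d/2`` above the leaves, so the boundary at CJD ``c`` is the
    root-to-point depth ``H - c/2`` where ``H`` is the leaf depth.
    Family clusters always refine order clusters.
    """
    cfg = cfg or DemarcationConfig()
    if not dendrogram.is_ultrametric():
        raise ValidationError("demarcate_cjd requires an ultrametric dendrogram")
    H = dendrogram.max_leaf_depth()
    cuts = {}
    for rank, cjd in (("order", cfg.order_lower_cjd), ("family", cfg.family_lower_cjd)):
        depth = max(H - cjd / 2.0, 0.0)
        cuts[rank] = cut_at_depth(dendrogram, RankCut(rank, depth), method_id=method_id)
    return cuts["order"], cuts["family"]


# ---------------------------------------------------------------------------
# Consensus proposal


def _novel_groups(table: AssignmentTable, established: set[str]
                  ) -> dict[str, dict[str, frozenset[str]]]:
    """Per method: novel label -> member leaf set."""
    out: dict[str, dict[str, frozenset[str]]] = {}
    for mid in table.methods:
        col = table.labels[mid]
        groups: dict[str, set[str]] = {}
        for leaf, lab in col.dropna().items():
            if str(lab) not in established:
                groups.setdefault(str(lab), set()).add(leaf)
        out[mid] = {lab: frozenset(m) for lab, m in groups.items()}
    return out


def _components(groups: list[tuple[str, str, frozenset[str]]]
                ) -> list[list[tuple[str, str, frozenset[str]]]]:
    """Connected components of (method, label, members) under member overlap."""
    n = len(groups)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if groups[i][2] & groups[j][2]:
                parent[find(i)] = find(j)
    comp: dict[int, list] = {}
    for i in range(n):
        comp.setdefault(find(i), []).append(groups[i])
    return sorted(comp.values(), key=lambda c: min(min(g[2]) for g in c))


def propose_new_taxa(
    table: AssignmentTable,
    established_labels: set[str],
    cfg: DemarcationConfig | None = None,
    supports: dict[str, dict[str, ClusterSupport]] | None = None,
    rank: str = "family",
) -> list[TaxonProposal]:
    """Apply the cross-method consensus rule to novel groups.

    A candidate is a maximal leaf set carrying a non-established label in
    some method. Overlapping candidates from different methods form one
    component; a component recovered identically by at least
    ``min_methods_agree`` methods is proposed (demoted to flagged when its
    reference-method cluster has an assessable bootstrap support below
    ``bootstrap_min``); a component whose methods disagree on membership
    follows the reference method and is flagged for review; components
    recovered by fewer methods than the threshold are rejected.
    """
    cfg = cfg or DemarcationConfig()
    supports = supports or {}
    per_method = _novel_groups(table, established_labels)
    flat = [(mid, lab, members)
            for mid in table.methods
            for lab, members in sorted(per_method.get(mid, {}).items())]
    proposals: list[TaxonProposal] = []
    for idx, comp in enumerate(_components(flat), start=1):
        memberships = {g[2] for g in comp}
        methods = frozenset(g[0] for g in comp)
        ref_groups = [g for g in comp if g[0] == table.reference_method]
        pid = f"NT-{idx:03d}"

        if len(memberships) == 1:
            members = next(iter(memberships))
            if cfg.match_tolerance == "superset":
                recovered = methods
            else:
                recovered = frozenset(g[0] for g in comp if g[2] == members)
            if len(recovered) < cfg.min_methods_agree:
                proposals.append(TaxonProposal(
                    pid, rank, members, recovered, REJECTED,
                    f"recovered by {len(recovered)} method(s); "
                    f"requires >= {cfg.min_methods_agree} of {cfg.methods_total}"))
                continue
            status, why = PROPOSED, (
                f"distinct group recovered identically by {len(recovered)} "
                f"of {cfg.methods_total} methods")
            gate = _bootstrap_gate(members, table, supports, cfg)
            if gate is False:
                status = FLAGGED
                why += (f"; reference-method bootstrap below "
                        f"{cfg.bootstrap_min} — expert review required")
            proposals.append(TaxonProposal(pid, rank, members, recovered, status, why))
        else:
            # methods split the group: reference primacy
            if ref_groups:
                members = max((g[2] for g in ref_groups), key=lambda m: (len(m), sorted(m)))
                src = "reference method"
            else:
                members = max(memberships, key=lambda m: (len(m), sorted(m)))
                src = "largest member group (reference silent)"
            if len(methods) < cfg.min_methods_agree:
                proposals.append(TaxonProposal(
                    pid, rank, members, methods, REJECTED,
                    f"recovered by {len(methods)} method(s); "
                    f"requires >= {cfg.min_methods_agree} of {cfg.methods_total}"))
                continue
            proposals.append(TaxonProposal(
                pid, rank, members, methods, FLAGGED,
                f"membership split between methods; membership follows {src}"))
    return proposals


def _bootstrap_gate(
    members: frozenset[str],
    table: AssignmentTable,
    supports: dict[str, dict[str, ClusterSupport]],
    cfg: DemarcationConfig,
) -> bool | None:
    """True/False where the reference cluster's support is assessable,
    None otherwise (gate passes vacuously)."""
    ref_supports = supports.get(table.reference_method)
    if not ref_supports:
        return None
    ref_col = table.labels[table.reference_method]
    labels = {str(ref_col[leaf]) for leaf in members
              if leaf in ref_col.index and not pd.isna(ref_col[leaf])}
    if len(labels) != 1:
        return None
    cs = ref_supports.get(next(iter(labels)))
    if cs is None or not cs.assessable:
        return None
    return bool(cs.passes)


# ---------------------------------------------------------------------------
# Reporting


def write_proposals_tsv(proposals: list[TaxonProposal]) -> str:
    rows = [
        {"proposal_id": p.proposal_id, "rank": p.rank,
         "members": ";".join(sorted(p.member_leaves)),
         "supporting_methods": ";".join(sorted(p.supporting_methods)),
         "status": p.status, "rationale": p.rationale}
        for p in proposals
    ]
    df = pd.DataFrame(rows, columns=["proposal_id", "rank", "members",
                                     "supporting_methods", "status", "rationale"])
    return df.to_csv(sep="\t", index=False)


def read_proposals_tsv(text: str) -> list[TaxonProposal]:
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str).fillna("")
    out = []
    for _, r in df.iterrows():
        out.append(TaxonProposal(
            proposal_id=r["proposal_id"], rank=r["rank"],
            member_leaves=frozenset(x for x in r["members"].split(";") if x),
            supporting_methods=frozenset(
                x for x in r["supporting_methods"].split(";") if x),
            status=r["status"], rationale=r["rationale"]))
    return out


def write_taxonomy_report(
    proposals: list[TaxonProposal],
    stats: DiscrepancyStats | None = None,
    rf: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Deterministic report artifacts: proposals TSV + human-readable summary."""
    summary = ["# Taxonomy consensus summary", ""]
    counts = {PROPOSED: 0, FLAGGED: 0, REJECTED: 0}
    for p in proposals:
        counts[p.status] += 1
    summary.append(f"Proposals: {counts[PROPOSED]} proposed, "
                   f"{counts[FLAGGED]} flagged for review, "
                   f"{counts[REJECTED]} rejected.")
    summary.append("")
    for p in proposals:
        summary.append(f"- {p.proposal_id} [{p.rank}] {p.status}: "
                       f"{', '.join(sorted(p.member_leaves))} "
                       f"(methods: {', '.join(sorted(p.supporting_methods)) or 'none'})"
                       f" — {p.rationale}")
    if stats is not None:
        summary += ["", "## Method discrepancies vs "
                        f"{stats.reference_method}", ""]
        summary.append(stats.to_frame().to_string(index=False))
    if rf is not None:
        summary += ["", "## Normalized Robinson-Foulds", "",
                    rf.to_string(float_format=lambda v: f"{v:.4f}")]
    return {
        "proposals.tsv": write_proposals_tsv(proposals),
        "summary.txt": "\n".join(summary) + "\n",
    }
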