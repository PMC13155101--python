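"""End-to-end orchestration: harvest -> clusterings -> comparison -> consensus.

Stages run in a fixed order on local files only; every artifact is a
deterministic text file, so re-running on identical inputs reproduces
byte-identical reports. A run manifest records the parameters used.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .errors import PipelineError
from .genome_domains import (SignatureMap, find_orfs, harvest_domains,
                             parse_interpro_xml, read_fasta,
                             write_domain_fastas, write_omission_tsv)
from .method_compare import (build_assignment_table, discrepancy_stats,
                             rf_matrix, robinson_foulds, tanglegram_svg,
                             untangle)
from .structure_qc import qc_filter, read_structure_meta_tsv, write_qc_report_tsv
from .taxon_consensus import (demarcate_cjd, propose_new_taxa,
                              write_taxonomy_report)
from .tree_ops import (RankCut, cluster_support, cut_at_depth,
                       dendrogram_from_cjd, read_cjd_tsv, read_newick,
                       root_tree, write_clusterings_tsv)

log = logging.getLogger(__name__)


def _require(path: Path | None, what: str) -> Path:
    if path is None:
        raise PipelineError(f"missing required input: {what} is not configured")
    if not path.exists():
        raise PipelineError(f"missing required input: {what} file {path} does not exist")
    return path


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full flow; returns a summary dict of stage outputs.

    Stage order: harvest -> trees/clusterings -> structure QC ->
    comparison -> consensus -> reports. Missing tree inputs fail fast
    (tree inference belongs to the external aligner/tree-builder
    contract; the pipeline consumes pre-computed newick files).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "picotax",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "rank": cfg.rank, "rank_depth": cfg.rank_depth,
            "rooting": cfg.rooting, "linkage": cfg.linkage,
            "min_aa_len": cfg.min_aa_len,
            "order_lower_cjd": cfg.order_lower_cjd,
            "family_lower_cjd": cfg.family_lower_cjd,
            "bootstrap_min": cfg.bootstrap_min,
            "min_methods_agree": cfg.min_methods_agree,
            "reference_method": cfg.reference_method,
            "qc_length_frac": cfg.qc_length_frac,
            "qc_plddt_min": cfg.qc_plddt_min,
        },
        "stages": [],
    }
    summary: dict = {"out_dir": str(out)}

    # -- stage 1: hallmark-domain harvest ---------------------------------
    if cfg.genomes_fasta and cfg.interpro_xml:
        fasta = _require(cfg.resolve(cfg.genomes_fasta), "genomes_fasta")
        xml = _require(cfg.resolve(cfg.interpro_xml), "interpro_xml")
        genomes = read_fasta(fasta.read_text())
        orfs = [o for g in genomes
                for o in find_orfs(g, min_aa_len=cfg.min_aa_len,
                                   genetic_code=cfg.genetic_code)]
        sig_path = cfg.resolve(cfg.signature_map)
        mapping = (SignatureMap.from_yaml(sig_path.read_text())
                   if sig_path else SignatureMap())
        hits = parse_interpro_xml(xml.read_text(), {o.orf_id: o for o in orfs},
                                  mapping=mapping)
        kept, omitted = harvest_domains(genomes, orfs, hits)
        for fname, text in write_domain_fastas(kept).items():
            (out / fname).write_text(text)
        (out / "omitted.tsv").write_text(write_omission_tsv(omitted))
        manifest["stages"].append(
            {"stage": "harvest", "n_genomes": len(genomes),
             "n_kept": len({d.genome_id for d in kept}), "n_omitted": len(omitted)})
        summary["harvest"] = {"kept": kept, "omitted": omitted}

    # -- stage 2: trees and rank clusterings ------------------------------
    trees = {}
    clusterings = []
    supports = {}
    for mid, rel in sorted(cfg.trees.items()):
        path = _require(cfg.resolve(rel), f"tree for method {mid!r}")
        tree = read_newick(path.read_text(), support_scale=cfg.support_scale)
        if not tree.rooted:
            tree = root_tree(tree, mode=cfg.rooting,
                             outgroup_leaves=cfg.outgroup_leaves or None)
        trees[mid] = tree
        if cfg.rank_depth is None:
            raise PipelineError(
                "rank_depth is required to cut tree methods into clusterings")
        cl = cut_at_depth(tree, RankCut(cfg.rank, cfg.rank_depth), method_id=mid)
        sup = cluster_support(tree, cl, threshold=cfg.bootstrap_min)
        cl.cluster_support = {lab: cs.support for lab, cs in sup.items()
                              if cs.support is not None}
        clusterings.append(cl)
        supports[mid] = sup
    if cfg.cjd_tsv:
        path = _require(cfg.resolve(cfg.cjd_tsv), "cjd_tsv")
        matrix = read_cjd_tsv(path.read_text())
        dendro = dendrogram_from_cjd(matrix, linkage=cfg.linkage)
        trees[cfg.cjd_method_id] = dendro
        dcfg = cfg.demarcation()
        order_cl, family_cl = demarcate_cjd(dendro, dcfg,
                                            method_id=cfg.cjd_method_id)
        chosen = {"order": order_cl, "family": family_cl}.get(cfg.rank, family_cl)
        clusterings.append(chosen)
        (out / "cjd_order_clusters.tsv").write_text(write_clusterings_tsv([order_cl]))
    if not trees:
        raise PipelineError(
            "no trees or CJD matrix configured and no adapter output supplied; "
            "stage 'clusterings' cannot run")
    (out / "clusterings.tsv").write_text(write_clusterings_tsv(clusterings))
    manifest["stages"].append({"stage": "clusterings",
                               "methods": sorted(c.method_id for c in clusterings)})

    # -- stage 3: structure QC --------------------------------------------
    if cfg.structures_tsv:
        path = _require(cfg.resolve(cfg.structures_tsv), "structures_tsv")
        metas = read_structure_meta_tsv(path.read_text())
        kept_s, decisions = qc_filter(metas, length_frac=cfg.qc_length_frac,
                                      plddt_min=cfg.qc_plddt_min)
        (out / "qc_report.tsv").write_text(write_qc_report_tsv(decisions))
        manifest["stages"].append({"stage": "structure_qc", "n_in": len(metas),
                                   "n_kept": len(kept_s)})
        summary["qc"] = decisions

    # -- stage 4: cross-method comparison ---------------------------------
    rf = rf_matrix(trees, normalized=True)
    (out / "rf_matrix.tsv").write_text(rf.to_csv(sep="\t", float_format="%.6f"))
    ref_id = cfg.reference_method
    if ref_id in trees:
        for mid, tree in sorted(trees.items()):
            if mid == ref_id:
                continue
            shared = sorted(trees[ref_id].leaf_set() & tree.leaf_set())
            layout = untangle(trees[ref_id], tree, {x: x for x in shared},
                              iterations=3, seed=cfg.seed)
            (out / f"tanglegram_{ref_id}_vs_{mid}.json").write_text(layout.to_json())
            (out / f"tanglegram_{ref_id}_vs_{mid}.svg").write_text(tanglegram_svg(layout))
    table = build_assignment_table(clusterings, reference_method=ref_id) \
        if any(c.method_id == ref_id for c in clusterings) else None
    stats = discrepancy_stats(table) if table is not None else None
    if table is not None:
        (out / "assignment_table.tsv").write_text(table.to_tsv())
        report = stats.to_frame()
        all_leaves = set(table.leaves)
        report["n_trimmed"] = [
            len(all_leaves - {l for l in table.leaves
                              if table.label(l, m) is not None})
            for m in report["method"]]
        report["norm_rf"] = [
            robinson_foulds(trees[ref_id], trees[m]) if m in trees else float("nan")
            for m in report["method"]]
        report = report.rename(columns={"n_disagree": "n_fam_disc"})[
            ["method", "n_trimmed", "n_fam_disc", "pct_disagree", "norm_rf"]]
        (out / "discrepancy.tsv").write_text(
            report.to_csv(sep="\t", index=False, float_format="%.6f"))
    manifest["stages"].append({"stage": "compare", "n_methods": len(trees)})

    # -- stage 5: consensus proposals -------------------------------------
    if table is not None and cfg.established_labels:
        est_path = _require(cfg.resolve(cfg.established_labels), "established_labels")
        established = {ln.strip() for ln in est_path.read_text().splitlines()
                       if ln.strip()}
        proposals = propose_new_taxa(table, established, cfg.demarcation(),
                                     supports=supports, rank=cfg.rank)
        for fname, text in write_taxonomy_report(proposals, stats, rf).items():
            (out / fname).write_text(text)
        manifest["stages"].append({"stage": "consensus",
                                   "n_proposals": len(proposals)})
        summary["proposals"] = proposals

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    summary["manifest"] = manifest
    return summary
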