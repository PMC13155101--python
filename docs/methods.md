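# Methods

This note documents the models, rules and numerical choices implemented in
`picotax`, the parameters that matter, what the synthetic fixtures do and
do not emulate, and the known limitations.

## Hallmark-domain harvesting

**ORF model.** `find_orfs` is a start-to-stop finder: in each of the six
reading frames, one ORF per inter-stop segment, running from the first
in-frame `ATG` to the first in-frame stop. `U` is mapped to `T` before
translation; `N` is tolerated (ambiguous codons translate to `X` and are
never treated as stops); any other character raises a parse error naming
its position. Stop-less ORFs at sequence ends are kept and flagged
`partial`. Coordinates are 0-based half-open on the forward strand and
include the stop codon; the translation excludes it. Nested ORFs sharing a
stop are deliberately not enumerated: the downstream contract only needs
translations that contain the annotated domains, and one-ORF-per-segment
keeps `orf_id` numbering stable. Default `min_aa_len` is 100 aa — shorter
than any credible RdRP or Hel domain, long enough to suppress spurious
frames.

**Signature classification.** InterPro-style signatures are mapped to
{RDRP, HEL, OTHER} by an editable `SignatureMap`: accession whitelists
(defaults: Pfam RdRP families PF00680/PF00978/PF00998/PF02123; helicase
families PF00910/PF00270/PF00271/PF04851) checked first, then
case-insensitive name keywords ("RNA-dependent RNA polymerase", "rdrp",
"helicase"). Accession match always wins over a keyword, because curated
accessions are more reliable than free-text names.

**Best hit and the omission rule.** When a genome has several hits of one
class, the excised hit is chosen by span length, then score (higher raw
score, else lower e-value), then ORF order; the choice is logged. A genome
contributes downstream only if both an RdRP and a Hel hit were found;
otherwise it enters the omission report with reason `no_rdrp`, `no_hel` or
`no_rdrp_no_hel`. Kept genomes and omitted genomes always partition the
input exactly.

## Trees, dendrograms, demarcation

**Supports.** Internal-node labels that parse as numbers are treated as
supports and normalised to [0, 1]; `auto` scaling divides by 100 when any
value exceeds 1. Non-numeric labels are preserved untouched.

**Rooting.** Midpoint rooting is computed directly from the tree diameter
(double-sweep farthest-leaf search, deterministic label tie-breaks); when
the midpoint falls exactly on an existing node the tree is rerooted at
that node rather than subdividing a zero-length edge. Outgroup rooting
reroots on the edge above the outgroup's MRCA, splitting it in half. Both
modes preserve all pairwise leaf path distances. Note the usual caveat:
after rerooting, the support stored on a node still refers to the clade
that node now subtends; supports of edges crossed by the new root are not
re-attributed.

**Fixed-depth cutting.** A rank boundary is a root-to-point path depth `d`
on the tree's own branch-length scale. A cluster is the leaf set of each
maximal subtree below an edge with `parent depth < d ≤ child depth`;
leaves whose entire root path is shallower than `d` become singletons;
`d = 0` yields one all-leaf cluster. Labels are deterministic: clusters
sorted by their lexicographically smallest member, numbered with a rank
prefix (`F001`, `O001`, `G001` …). The inclusive child-side boundary makes
a merge exactly at the boundary stay together, so a strict-inequality
demarcation threshold ("distance > c separates") is honoured.

**CJD dendrograms.** A composite-Jaccard-distance matrix is validated
(symmetric, zero diagonal, entries in [0, 1]) and agglomerated with
scipy's average linkage by default (single/complete available). The
ultrametric convention places a merge at distance `d` at height `d/2`
above the leaves. `demarcate_cjd` converts the standard lower demarcation
boundaries — order CJD > 0.95, family CJD > 0.70 — into cut depths
`H − c/2` (`H` = leaf depth) and applies the fixed-depth cut; family
clusters therefore always refine order clusters, and a matrix of all 1.0
(no relatedness) yields singleton orders.

**Bootstrap gate.** A cluster's support is the value on its subtending
edge; threshold 0.7 by default. Singleton clusters and clusters spanning
the whole leaf set have no subtending internal edge and are marked *not
assessable* rather than failing — a missing support is not evidence
against a group.

## Cross-method comparison

**Robinson–Foulds.** Trees are pruned (on copies) to their shared leaf
set (≥ 4 required); the unnormalized distance is the number of
non-trivial bipartitions present in exactly one tree; normalization
divides by the total non-trivial bipartition count of both pruned trees,
which handles multifurcating trees gracefully and bounds the value in
[0, 1]. The implementation enumerates bipartitions explicitly as
frozensets of leaf-label sides; the test suite cross-checks it against
dendropy's independent tree-comparison machinery on random tree pairs.

**Tanglegrams.** Crossings are the inversion count of the matched-pair
permutation (merge-sort, O(n log n); verified against the all-pairs
count). Unmatched leaves are drawn but excluded. Untangling alternates
one-sided passes for 3 iterations (configurable): with one side fixed,
the other tree's children are reordered either by barycenter (mean
matched-leaf position on the opposite side) or by the exact per-node
orientation that minimises pairwise inversions — exact for bifurcations
because, with the opposite side fixed, each node's contribution is
independent of every other node's choice; multifurcations fall back to
barycenter ordering. Because a single alternating descent can stall in a
local optimum, `untangle` runs the small deterministic portfolio of pass
schedules (both pass orders × both pass kinds and their combination),
keeps the lowest-crossing layout seen after any pass, and finishes with a
1-opt refinement (flip one internal node, re-descend, keep strict
improvements). The unchanged input layout is always a candidate, so the
result never has more crossings than the input; all tie-breaks are
positional, so the procedure is deterministic and the `seed` parameter
exists only for interface stability. On random 8-leaf binary tanglegrams
this matches the exhaustive two-sided rotation optimum in ≈ 95% of
instances.

**Assignment tables.** Clusterings of one rank are joined over the union
of their leaf sets; a leaf absent from a method (e.g. dropped by the
structure-QC filter) is recorded as absent and excluded from that
method's comparisons. Non-reference cluster labels are harmonized to the
reference label sharing the most leaves (ties → lexicographically
smallest reference label; every mapping is logged and stored on the
table). Clusters overlapping no reference cluster keep their original
label so that novel groups survive harmonization. Discrepancy statistics
count, per method, the jointly-present leaves (`n_compared`) and the
harmonized-label mismatches (`n_disagree`); percentages are
`100·n_disagree/n_compared`.

## Structure quality control

Per-residue pLDDT is read from CA-atom B-factors (one model; first chain
with a logged warning if several; values outside [0, 100] clamped with a
warning; residues lacking CA atoms are an error naming them) or from a
three-column TSV. When several ranked models share an id, the one with
maximal mean pLDDT wins (ties → first seen). The filter computes the
median length over *all* inputs (even count → mean of the central pair)
before any omission, then omits structures with
`length < 0.8 × median` (strict — a structure at exactly 0.8×median is
kept, reading ">20% shorter" as strict) or `mean pLDDT ≤ 80` (inclusive —
exactly 80 is omitted). Classification is order-invariant, monotone in
the pLDDT threshold, and stable under duplicating the input list.

## Consensus proposal of new taxa

Candidates are maximal leaf sets carrying a label absent from the
supplied established-taxa list in at least one method. Candidates from
different methods are merged into overlap-connected components, so
proposals at one rank are pairwise disjoint. Per component:

- identical membership across methods, recovered by ≥ `min_methods_agree`
  (default 2 of 4) → **proposed**; if the reference-method cluster has an
  assessable support below the bootstrap gate, the proposal is demoted to
  **flagged_for_review** rather than rejected — the gate is only
  assessable for some clusters, so failing it warrants review, not
  silent rejection;
- differing memberships (the methods split the group) → membership
  follows the reference method (hallmark-RdRP primacy); if the reference
  recovers no novel group in the component, the largest member group is
  taken and the case still goes to review — the reference's silence is
  itself a conflict;
- fewer than `min_methods_agree` supporting methods → **rejected**, with
  the count in the rationale.

"Recovered" means exact leaf-set equality by default
(`match_tolerance="exact"`); a `superset` tolerance is available for
noisier data. With `min_methods_agree = methods_total` only unanimous
groups are proposed; with 1, every novel group is — the rule is monotone
in the threshold.

## Pipeline and determinism

`run_pipeline` executes harvest → clusterings (tree cuts at the
configured `rank_depth`; CJD demarcation at the configured boundaries) →
structure QC → comparison (RF matrix, tanglegrams vs the reference,
discrepancy table) → consensus → reports. Every artifact is plain text
with fixed float formatting and sorted keys, and no timestamps are
written, so identical inputs reproduce byte-identical outputs. The run
manifest records the package version, seed and all governing parameters.
External tools appear only as adapter command templates — the alignment
template carries `--localpair --iterate 1000 --leavegappyregion`
verbatim, the tree-builder template the `Q.pfam+F+I+R10` model with 1000
bootstrap replicates — rendered on demand, never executed by the library.

## Synthetic fixtures: what they do and do not show

The generators plant exactly the structures the algorithms are meant to
find: ultrametric k-clade trees (clade tops at `within_height`, root at
`between_height`, supports 1.0 on clades), two-level CJD block matrices
whose default levels (0.5 within family, 0.85 within order, 0.99 between
orders) bracket the demarcation boundaries, toy genomes whose single
planted ORF carries RdRP/Hel segments at known coordinates with matching
InterPro-style XML, and all-passing structure metadata. Jitter, when
requested, must preserve the level ordering or the generator refuses.
Everything is deterministic under its seed.

Passing on these fixtures demonstrates the correctness of the cutting,
comparison, filtering and consensus *rules* — it does not demonstrate
robustness to the things real data add: alignment error, rate variation
and long-branch effects in inferred trees, non-ultrametric CJD noise,
chimeric or partial genomes, domain predictions missing or overlapping in
ways the signature map cannot resolve. No sequence evolution is
simulated. The reported end-to-end sizes (16-genome fixture sets, 8-leaf
tanglegram oracles, 200-pair RF sweeps) were chosen so the exhaustive
oracles stay exact; the algorithms themselves have no such limits.

## Known limitations

- Support re-attribution across rerooting follows the node, not the
  unrooted edge; trees should carry supports rooted compatibly with how
  they will be cut.
- The fixed-depth cut presumes depth is comparable across the tree; for
  strongly non-clock-like phylogenies a per-clade calibration would be
  more defensible than a single depth.
- Maximum-overlap label harmonization can absorb a small novel group into
  a large established family when they overlap; the consensus stage
  therefore works best when clusterings are produced at comparable
  granularity.
- The untangling optimality figure (~95%) is measured on 8-leaf binary
  tanglegrams; for much larger trees the portfolio remains fast but no
  optimality guarantee is claimed.
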