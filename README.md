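# picotax

A toolkit for **automated, multimodal virus taxonomy** at family and genus
rank, aimed at RNA-virus groups — picornaviruses and picorna-like viruses
in particular — where metagenomics delivers new genomes far faster than
manual classification can absorb them.

Modern practice classifies such viruses by several complementary signals:

1. **Hallmark-gene phylogenies** — trees inferred from the RNA-directed RNA
   polymerase (RdRP, the gold-standard marker across the *Riboviria*) and
   the helicase (Hel) domain of the replication block;
2. **Whole-genome profile clustering** — composite Jaccard distances (CJD)
   over shared protein-profile content and genomic organisation, where
   CJD = 1.0 means no detectable relatedness;
3. **Predicted-structure phylogenies** — trees over predicted RdRP folds,
   quality-filtered by per-residue confidence (pLDDT).

`picotax` implements the bespoke computational glue between those methods:

- **Domain harvesting** (`genome_domains`): start-to-stop ORF extraction on
  both strands, InterPro Scan XML parsing, signature→{RDRP, HEL}
  classification via an editable accession/keyword map, excision of the
  single best hit per class, and the completeness rule: a genome is carried
  forward only if *both* RdRP and Hel were identified, otherwise it is
  written to the omission report with its reason.
- **Rank demarcation** (`tree_ops`): newick i/o with support normalisation,
  midpoint/outgroup rooting, and **fixed-depth cutting** of rooted trees
  and UPGMA dendrograms into named rank clusterings. A cluster is the leaf
  set under each edge that crosses the cut depth
  (`parent depth < d ≤ child depth`). CJD dendrograms are cut at the
  standard lower demarcation boundaries, CJD > 0.95 (order) and
  CJD > 0.70 (family), using the ultrametric convention height = CJD/2.
- **Cross-method comparison** (`method_compare`): normalized
  Robinson–Foulds distance on tree pairs (bipartition symmetric difference
  over the shared leaf set), tanglegram layouts with deterministic
  crossing-minimising untangling, and leaf×method assignment tables whose
  labels are harmonized to a reference method by maximum overlap, yielding
  per-method discrepancy counts.
- **Structure QC** (`structure_qc`): pLDDT metadata from PDB B-factors or
  TSV; omit structures more than 20% shorter than the median length
  (strictly, length < 0.8×median) or with mean pLDDT ≤ 80.
- **Consensus proposal** (`taxon_consensus`): a novel group (label not in
  the supplied established-taxa list) is **proposed** as a new taxon when
  at least 2 of the 4 analysis methods recover it identically and its
  reference-method cluster passes the bootstrap gate (support ≥ 0.7 where
  assessable); groups the methods split follow the reference method (RdRP
  primacy) and are **flagged for review**; groups seen by only one method
  are **rejected**.
- **Fixtures** (`fixtures`): seeded generators with known ground truth —
  planted ultrametric trees, NNI perturbations, toy genomes with embedded
  domains plus matching InterPro-style XML, two-level CJD block matrices,
  structure metadata — so the whole pipeline runs offline.
- **Orchestration** (`cli_orchestrate` → `config`/`pipeline`/`cli`): YAML
  configuration, a `picotax` CLI with `fixtures`, `harvest`, `cluster`,
  `compare`, `qc`, `consensus`, `run` and `adapter` subcommands, and
  contract-only adapter templates for the external aligner
  (`mafft --localpair --iterate 1000 --leavegappyregion`) and tree builder
  (IQ-TREE, `Q.pfam+F+I+R10`, 1000 bootstraps) — rendered, never executed.

## Worked example

Generate a synthetic dataset (16 genomes in four planted families, three
trees + one CJD matrix, the fourth family withheld from the established
list) and run the full pipeline:

```sh
picotax fixtures demo/fix --seed 11
picotax run --config demo/fix/config.yaml --out-dir demo/out
```

`demo/out/discrepancy.tsv` tabulates each method against the RdRP
reference — leaves dropped by that method (`n_trimmed`), family-rank
disagreements after label harmonization (`n_fam_disc`), and the normalized
Robinson–Foulds distance of its tree:

```
method	n_trimmed	n_fam_disc	pct_disagree	norm_rf
hel	0	0	0.000000	0.416667
struct	0	0	0.000000	0.416667
cjd	0	0	0.000000	0.280000
```

All four methods assign every genome to the same four families (zero
discrepancies); the non-zero RF values reflect the differing within-family
topologies of the planted trees. `demo/out/proposals.tsv` holds the
consensus verdict on the withheld family:

```
proposal_id	rank	members	supporting_methods	status	rationale
NT-001	family	g014;g015;g016	cjd;hel;rdrp;struct	proposed	distinct group recovered identically by 4 of 4 methods
```

The group `{g014, g015, g016}` is recovered identically by all four
methods and is therefore proposed as a new family; had the methods split
it, membership would follow the RdRP phylogeny and the row would read
`flagged_for_review`.

## Scope

Tree inference, alignment, profile-HMM construction, CJD computation and
structure prediction belong to external tools (MAFFT, IQ-TREE, InterPro
Scan, GRAViTy-V2, ColabFold, FoldTree); `picotax` consumes their outputs
(FASTA, InterPro XML, newick, distance TSV, PDB) and renders their command
lines via adapter templates only. Nomenclature generation and formal
taxonomy-proposal documents are out of scope.
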