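"""Pipeline configuration: YAML loading, validation, adapter templates.

External alignment and tree-inference tools are represented only as
command templates (rendered, never executed by the library); the default
templates carry the standard hallmark-gene settings: mafft
``--localpair --iterate 1000 --leavegappyregion`` and IQ-TREE with the
``Q.pfam+F+I+R10`` model and 1000 bootstrap iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .taxon_consensus import DemarcationConfig

log = logging.getLogger(__name__)

DEFAULT_ADAPTERS = {
    "aligner": "mafft --localpair --iterate 1000 --leavegappyregion {input} > {output}",
    "tree_builder": "iqtree2 -s {input} -m Q.pfam+F+I+R10 -B 1000 --prefix {prefix}",
}


@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end flow."""

    genomes_fasta: str | None = None
    interpro_xml: str | None = None
    trees: dict[str, str] = field(default_factory=dict)  # method_id -> newick path
    cjd_tsv: str | None = None
    cjd_method_id: str = "cjd"
    structures_tsv: str | None = None
    established_labels: str | None = None
    signature_map: str | None = None

    rank: str = "family"
    rank_depth: float | None = None  # fixed-depth cut for the tree methods
    rooting: str = "midpoint"
    outgroup_leaves: list[str] = field(default_factory=list)
    linkage: str = "average"
    min_aa_len: int = 100
    genetic_code: int = 1
    support_scale: str = "auto"

    order_lower_cjd: float = 0.95
    family_lower_cjd: float = 0.70
    bootstrap_min: float = 0.7
    min_methods_agree: int = 2
    reference_method: str = "rdrp"
    match_tolerance: str = "exact"

    qc_length_frac: float = 0.8
    qc_plddt_min: float = 80.0

    adapters: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ADAPTERS))
    seed: int = 0
    log_level: str = "INFO"
    base_dir: Path = field(default_factory=Path)

    def demarcation(self, methods_total: int | None = None) -> DemarcationConfig:
        total = methods_total or max(len(self.trees) + (1 if self.cjd_tsv else 0), 1)
        return DemarcationConfig(
            order_lower_cjd=self.order_lower_cjd,
            family_lower_cjd=self.family_lower_cjd,
            bootstrap_min=self.bootstrap_min,
            min_methods_agree=min(self.min_methods_agree, total),
            methods_total=total,
            reference_method=self.reference_method,
            match_tolerance=self.match_tolerance,
        )

    def resolve(self, rel: str | None) -> Path | None:
        if rel is None:
            return None
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p

    @classmethod
    def from_yaml(cls, text: str, base_dir: str | Path = ".") -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config YAML must be a mapping")
        known = {f.name for f in fields(cls)} - {"base_dir"}
        unknown = sorted(set(raw) - known)
        if unknown:
            log.warning("config: ignoring unknown keys: %s", ", ".join(unknown))
        kwargs = {k: v for k, v in raw.items() if k in known}
        if "adapters" in kwargs:
            merged = dict(DEFAULT_ADAPTERS)
            merged.update(kwargs["adapters"])
            kwargs["adapters"] = merged
        cfg = cls(base_dir=Path(base_dir), **kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.rooting not in ("midpoint", "outgroup"):
            raise ConfigError(f"rooting must be midpoint or outgroup, got {self.rooting!r}")
        if self.linkage not in ("average", "single", "complete"):
            raise ConfigError(f"unsupported linkage {self.linkage!r}")
        if self.rank_depth is not None and self.rank_depth < 0:
            raise ConfigError("rank_depth must be >= 0")
        if self.min_aa_len < 1:
            raise ConfigError("min_aa_len must be >= 1")
        self.demarcation()  # raises on inconsistent thresholds


def adapter_command(tool: str, inputs: dict[str, str],
                    templates: dict[str, str] | None = None) -> str:
    """Render the command line for an external tool (never executed here).

    Unresolved template variables raise a ConfigError naming them.
    """
    templates = templates or DEFAULT_ADAPTERS
    if tool not in templates:
        raise ConfigError(f"no adapter template for tool {tool!r}")
    try:
        return templates[tool].format(**inputs)
    except KeyError as exc:
        raise ConfigError(f"adapter {tool!r}: unresolved template variable {exc}") from exc
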