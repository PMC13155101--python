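"""Predicted-structure confidence metadata and omission filtering.

Structure predictors report a per-residue confidence, the predicted
Local Distance Difference Test (pLDDT, 0-100), conventionally stored in
the B-factor column of the output PDB. Before building a structural
tree, predictions are filtered: structures more than 20% shorter than
the median length (strictly, length < 0.8 x median) or with mean pLDDT
at or below 80 are omitted.
"""

from __future__ import annotations

import io
import logging
import statistics
from dataclasses import dataclass

from Bio.PDB import PDBParser

from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class StructureMeta:
    id: str
    length_aa: int
    mean_plddt: float
    per_residue_plddt: list[float] | None = None

    def __post_init__(self):
        if self.length_aa < 1:
            raise ValidationError(f"{self.id}: length_aa must be positive")
        if not 0.0 <= self.mean_plddt <= 100.0:
            raise ValidationError(f"{self.id}: mean pLDDT {self.mean_plddt} outside [0, 100]")
        if self.per_residue_plddt is not None:
            if len(self.per_residue_plddt) != self.length_aa:
                raise ValidationError(
                    f"{self.id}: {len(self.per_residue_plddt)} per-residue values "
                    f"for length {self.length_aa}")
            mean = sum(self.per_residue_plddt) / self.length_aa
            if abs(mean - self.mean_plddt) > 1e-6:
                raise ValidationError(
                    f"{self.id}: mean_plddt {self.mean_plddt} != per-residue mean {mean}")


@dataclass
class QcDecision:
    meta: StructureMeta
    kept: bool
    reason: str  # "" | too_short | low_plddt | both


# ---------------------------------------------------------------------------
# Readers


def read_structure_pdb(pdb_text: str, structure_id: str) -> StructureMeta:
    """One model, CA B-factors as per-residue pLDDT.

    B-factors outside [0, 100] are clamped with a logged warning;
    residues lacking a CA atom raise an error naming them.
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(structure_id, io.StringIO(pdb_text))
    except Exception as exc:
        raise ParseError(f"{structure_id}: PDB parse failure: {exc}") from exc
    models = list(structure)
    if not models:
        raise ParseError(f"{structure_id}: no model in PDB")
    chains = list(models[0])
    if not chains:
        raise ParseError(f"{structure_id}: empty model")
    if len(chains) > 1:
        log.warning("%s: %d chains present, using the first", structure_id, len(chains))
    residues = [r for r in chains[0] if r.id[0] == " "]
    if not residues:
        raise ParseError(f"{structure_id}: no residues in first chain")
    missing = [str(r.id[1]) for r in residues if "CA" not in r]
    if missing:
        raise ValidationError(
            f"{structure_id}: residues lacking CA atoms: {', '.join(missing)}")
    plddt = []
    for r in residues:
        b = float(r["CA"].get_bfactor())
        if not 0.0 <= b <= 100.0:
            clamped = min(max(b, 0.0), 100.0)
            log.warning("%s residue %s: B-factor %.3f outside [0, 100], clamped to %.1f",
                        structure_id, r.id[1], b, clamped)
            b = clamped
        plddt.append(b)
    return StructureMeta(id=structure_id, length_aa=len(plddt),
                         mean_plddt=sum(plddt) / len(plddt),
                         per_residue_plddt=plddt)


def read_structure_meta_tsv(text: str) -> list[StructureMeta]:
    """TSV schema: id<TAB>length_aa<TAB>mean_plddt (header optional)."""
    out = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "id":
            continue
        if len(parts) < 3:
            raise ParseError(f"structure TSV line {ln}: expected 3 columns, got {len(parts)}")
        out.append(StructureMeta(id=parts[0], length_aa=int(parts[1]),
                                 mean_plddt=float(parts[2])))
    return out


def select_best_models(metas: list[StructureMeta]) -> list[StructureMeta]:
    """Highest-confidence model per id: maximal mean pLDDT, ties -> first seen."""
    best: dict[str, StructureMeta] = {}
    for m in metas:
        cur = best.get(m.id)
        if cur is None or m.mean_plddt > cur.mean_plddt:
            best[m.id] = m
    return [best[i] for i in sorted(best)]


# ---------------------------------------------------------------------------
# Filter


def qc_filter(
    structures: list[StructureMeta],
    length_frac: float = 0.8,
    plddt_min: float = 80.0,
) -> tuple[list[StructureMeta], list[QcDecision]]:
    """Omit structures much shorter than the median or of low confidence.

    The median length is taken over ALL inputs (even count: mean of the
    central pair). Omission when length_aa < length_frac x median
    (strict), or mean pLDDT <= plddt_min (inclusive). Classification is
    independent of input order; returns (kept, all decisions).
    """
    if not structures:
        raise ValidationError("qc_filter needs at least one structure")
    med = statistics.median(s.length_aa for s in structures)
    decisions: list[QcDecision] = []
    for s in sorted(structures, key=lambda x: x.id):
        too_short = s.length_aa < length_frac * med
        low = s.mean_plddt <= plddt_min
        reason = {(False, False): "", (True, False): "too_short",
                  (False, True): "low_plddt", (True, True): "both"}[(too_short, low)]
        decisions.append(QcDecision(meta=s, kept=not (too_short or low), reason=reason))
        if reason:
            log.info("structure %s omitted (%s): length %d vs median %.1f, "
                     "mean pLDDT %.2f (threshold <= %.1f omits)",
                     s.id, reason, s.length_aa, med, s.mean_plddt, plddt_min)
    kept = [d.meta for d in decisions if d.kept]
    return kept, decisions


def write_qc_report_tsv(decisions: list[QcDecision]) -> str:
    lines = ["id\tlength_aa\tmean_plddt\tdecision\treason"]
    for d in decisions:
        lines.append(f"{d.meta.id}\t{d.meta.length_aa}\t{d.meta.mean_plddt:.4f}\t"
                     f"{'kept' if d.kept else 'omitted'}\t{d.reason}")
    return "\n".join(lines) + "\n"
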