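"""ORF extraction, InterPro-style domain hits, and hallmark-gene harvesting.

RNA-virus classification leans on two hallmark domains of the replication
block: the RNA-directed RNA polymerase (RdRP) and the helicase (Hel).
This module finds open reading frames in genome sequences, reads domain
predictions from InterPro Scan XML, classifies signatures into RDRP / HEL,
and excises one best hit per class per genome. A genome contributes
downstream only when *both* domains were identified; otherwise it is
recorded in the omission report with its reason.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from lxml import etree

from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

RDRP = "RDRP"
HEL = "HEL"
OTHER = "OTHER"

_VALID_NT = set("ACGTUN")


# ---------------------------------------------------------------------------
# Records


@dataclass
class GenomeRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("genome id must be non-empty")
        if len(self.sequence) < 1:
            raise ValidationError(f"genome {self.id}: empty sequence")


@dataclass
class OrfRecord:
    """An open reading frame; nt coordinates are 0-based half-open on the
    forward strand, ``end`` includes the stop codon when one was found."""

    orf_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    aa_sequence: str
    partial: bool = False

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(f"{self.orf_id}: bad coordinates [{self.start}, {self.end})")
        if (self.end - self.start) % 3 != 0:
            raise ValidationError(f"{self.orf_id}: span not divisible by 3")
        if self.strand not in "+-":
            raise ValidationError(f"{self.orf_id}: strand must be + or -")


@dataclass
class DomainHit:
    orf_id: str
    domain_class: str  # RDRP / HEL / OTHER
    aa_start: int  # 0-based half-open within the ORF translation
    aa_end: int
    signature_accession: str
    source_db: str = ""
    score: float | None = None
    evalue: float | None = None

    def __post_init__(self):
        if not (0 <= self.aa_start < self.aa_end):
            raise ValidationError(
                f"hit on {self.orf_id}: bad aa coordinates [{self.aa_start}, {self.aa_end})")

    @property
    def span(self) -> int:
        return self.aa_end - self.aa_start

    @property
    def sort_score(self) -> float | None:
        """Comparable goodness: raw score, else -evalue, else None."""
        if self.score is not None:
            return self.score
        if self.evalue is not None:
            return -self.evalue
        return None


@dataclass
class DomainSequence:
    genome_id: str
    domain_class: str
    aa_sequence: str
    provenance: str  # signature_accession|orf_id

    def __post_init__(self):
        if not self.aa_sequence:
            raise ValidationError(f"{self.genome_id}: empty domain sequence")
        if self.domain_class not in (RDRP, HEL):
            raise ValidationError(f"{self.genome_id}: domain_class must be RDRP or HEL")


@dataclass
class OmittedGenome:
    genome_id: str
    reason: str  # no_rdrp | no_hel | no_rdrp_no_hel


# ---------------------------------------------------------------------------
# ORF finding


def _validate_nt(genome: GenomeRecord) -> str:
    seq = genome.sequence.upper()
    for i, c in enumerate(seq):
        if c not in _VALID_NT:
            raise ParseError(
                f"genome {genome.id}: non-nucleotide character {c!r} at position {i}")
    return seq.replace("U", "T")


def _frame_orfs(seq: str, frame: int, min_aa_len: int, genetic_code: int):
    """Start-to-stop ORFs in one forward frame of ``seq``.

    One ORF per inter-stop segment: the first in-frame ATG up to the first
    in-frame stop (or the end of the frame, flagged partial).
    Yields (start_nt, end_nt, aa_sequence, partial).
    """
    usable = len(seq) - frame - (len(seq) - frame) % 3
    if usable < 3:
        return
    aa = str(Seq(seq[frame:frame + usable]).translate(table=genetic_code))
    open_at: int | None = None
    for i, res in enumerate(aa):
        codon = seq[frame + 3 * i: frame + 3 * i + 3]
        if open_at is None:
            if codon == "ATG":
                open_at = i
        if res == "*":
            if open_at is not None:
                prot = aa[open_at:i]
                if len(prot) >= min_aa_len:
                    yield (frame + 3 * open_at, frame + 3 * (i + 1), prot, False)
            open_at = None
    if open_at is not None:  # ran off the end without a stop
        prot = aa[open_at:]
        if len(prot) >= min_aa_len:
            yield (frame + 3 * open_at, frame + usable, prot, True)


def find_orfs(genome: GenomeRecord, min_aa_len: int = 100,
              genetic_code: int = 1) -> list[OrfRecord]:
    """Find start-to-stop ORFs on both strands, ordered by genome position.

    ``end - start`` counts the stop codon when present; the translation
    excludes it. Stop-less ORFs at sequence ends are kept, flagged partial.
    """
    if min_aa_len < 1:
        raise ValueError("min_aa_len must be >= 1")
    fwd = _validate_nt(genome)
    rev = str(Seq(fwd).reverse_complement())
    L = len(fwd)
    found: list[tuple[int, int, str, str, bool]] = []
    for frame in range(3):
        for s, e, prot, part in _frame_orfs(fwd, frame, min_aa_len, genetic_code):
            found.append((s, e, "+", prot, part))
        for s, e, prot, part in _frame_orfs(rev, frame, min_aa_len, genetic_code):
            found.append((L - e, L - s, "-", prot, part))
    found.sort(key=lambda t: (t[0], t[1], t[2]))
    return [
        OrfRecord(orf_id=f"{genome.id}.orf{i + 1}", genome_id=genome.id,
                  start=s, end=e, strand=st, aa_sequence=prot, partial=part)
        for i, (s, e, st, prot, part) in enumerate(found)
    ]


# ---------------------------------------------------------------------------
# Signature classification


@dataclass
class SignatureMap:
    """Accession whitelists plus name keywords mapping signatures to classes.

    Accession matches take precedence over keyword matches; anything
    unmatched is OTHER. Editable via YAML (:meth:`from_yaml`).
    """

    rdrp_accessions: frozenset[str] = frozenset({"PF00680", "PF00978", "PF00998", "PF02123"})
    hel_accessions: frozenset[str] = frozenset({"PF00910", "PF00270", "PF00271", "PF04851"})
    rdrp_keywords: tuple[str, ...] = ("rna-dependent rna polymerase",
                                      "rna dependent rna polymerase", "rdrp")
    hel_keywords: tuple[str, ...] = ("helicase",)

    @classmethod
    def from_yaml(cls, text: str) -> "SignatureMap":
        cfg = yaml.safe_load(text) or {}
        kw = {}
        for k in ("rdrp_accessions", "hel_accessions"):
            if k in cfg:
                kw[k] = frozenset(cfg[k])
        for k in ("rdrp_keywords", "hel_keywords"):
            if k in cfg:
                kw[k] = tuple(str(x).lower() for x in cfg[k])
        return cls(**kw)

    def classify(self, signature_accession: str, signature_name: str) -> str:
        return classify_signature(signature_accession, signature_name, self)


def classify_signature(signature_accession: str, signature_name: str,
                       mapping: SignatureMap) -> str:
    """RDRP / HEL / OTHER by accession whitelist, then name keyword."""
    acc = (signature_accession or "").strip()
    if acc in mapping.rdrp_accessions:
        return RDRP
    if acc in mapping.hel_accessions:
        return HEL
    name = (signature_name or "").lower()
    if any(k in name for k in mapping.rdrp_keywords):
        return RDRP
    if any(k in name for k in mapping.hel_keywords):
        return HEL
    return OTHER


# ---------------------------------------------------------------------------
# InterPro Scan XML


def _local(tag) -> str:
    if not isinstance(tag, str):
        return ""
    return tag.rsplit("}", 1)[-1]


def parse_interpro_xml(
    xml_text: str | bytes,
    orf_index: dict[str, OrfRecord],
    mapping: SignatureMap | None = None,
) -> list[DomainHit]:
    """Parse InterPro Scan XML into DomainHits.

    One hit per signature match location; the XML's 1-based inclusive
    residue coordinates become 0-based half-open. Hits on proteins not in
    ``orf_index`` are logged and skipped; coordinates outside the ORF
    translation raise a validation error naming the orf_id.
    """
    mapping = mapping or SignatureMap()
    data = xml_text.encode() if isinstance(xml_text, str) else xml_text
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed InterPro XML: {exc}") from exc

    hits: list[DomainHit] = []
    for protein in root.iter():
        if _local(protein.tag) != "protein":
            continue
        xref_ids = [x.get("id") for x in protein if _local(x.tag) == "xref" and x.get("id")]
        for match in protein.iterdescendants():
            if not _local(match.tag).endswith("-match"):
                continue
            sig = next((c for c in match if _local(c.tag) == "signature"), None)
            if sig is None:
                continue
            acc = sig.get("ac") or ""
            name = sig.get("name") or sig.get("desc") or ""
            lib = next((r.get("library") for r in sig
                        if _local(r.tag) == "signature-library-release"), "") or ""
            locations = [loc for loc in match.iterdescendants()
                         if _local(loc.tag).endswith("-location")]
            for loc in locations:
                start = loc.get("start")
                end = loc.get("end")
                if start is None or end is None:
                    continue
                score = loc.get("score") or match.get("score")
                evalue = loc.get("evalue") or match.get("evalue")
                for orf_id in xref_ids:
                    orf = orf_index.get(orf_id)
                    if orf is None:
                        log.warning("InterPro hit on unknown protein %r skipped", orf_id)
                        continue
                    aa_start, aa_end = int(start) - 1, int(end)
                    if not (0 <= aa_start < aa_end <= len(orf.aa_sequence)):
                        raise ValidationError(
                            f"hit coordinates {start}-{end} outside translation of {orf_id}"
                            f" (length {len(orf.aa_sequence)})")
                    hits.append(DomainHit(
                        orf_id=orf_id,
                        domain_class=classify_signature(acc, name, mapping),
                        aa_start=aa_start, aa_end=aa_end,
                        signature_accession=acc, source_db=lib,
                        score=float(score) if score is not None else None,
                        evalue=float(evalue) if evalue is not None else None,
                    ))
    return hits


# ---------------------------------------------------------------------------
# Harvest


def _best_hit(cands: list[tuple[int, DomainHit]]) -> tuple[int, DomainHit]:
    """Longest span, then better score, then first by ORF order."""

    def key(item):
        orf_pos, h = item
        s = h.sort_score
        return (-h.span, 0 if s is not None else 1, -(s or 0.0), orf_pos, h.aa_start)

    return min(cands, key=key)


def harvest_domains(
    genomes: list[GenomeRecord],
    orfs: list[OrfRecord],
    hits: list[DomainHit],
) -> tuple[list[DomainSequence], list[OmittedGenome]]:
    """Excise the single best RDRP and HEL hit per genome.

    Genomes lacking either class are omitted with reason
    ``no_rdrp`` / ``no_hel`` / ``no_rdrp_no_hel``; every input genome
    appears exactly once across kept genomes and the omission list.
    """
    orf_by_id = {o.orf_id: o for o in orfs}
    orf_pos: dict[str, int] = {}
    per_genome: dict[str, list[str]] = {}
    for o in orfs:
        per_genome.setdefault(o.genome_id, []).append(o.orf_id)
    for g, ids in per_genome.items():
        for i, oid in enumerate(ids):
            orf_pos[oid] = i

    by_genome_class: dict[str, dict[str, list[tuple[int, DomainHit]]]] = {}
    for h in hits:
        orf = orf_by_id.get(h.orf_id)
        if orf is None:
            raise ValidationError(f"hit references unknown ORF {h.orf_id!r}")
        if h.domain_class not in (RDRP, HEL):
            continue
        by_genome_class.setdefault(orf.genome_id, {}).setdefault(
            h.domain_class, []).append((orf_pos[h.orf_id], h))

    kept: list[DomainSequence] = []
    omitted: list[OmittedGenome] = []
    for g in sorted(genomes, key=lambda x: x.id):
        classes = by_genome_class.get(g.id, {})
        missing = [c for c in (RDRP, HEL) if not classes.get(c)]
        if missing:
            reason = {"RDRP": "no_rdrp", "HEL": "no_hel"}[missing[0]] \
                if len(missing) == 1 else "no_rdrp_no_hel"
            omitted.append(OmittedGenome(genome_id=g.id, reason=reason))
            continue
        for cls in (RDRP, HEL):
            pos, h = _best_hit(classes[cls])
            orf = orf_by_id[h.orf_id]
            if pos != orf_pos[h.orf_id]:  # pragma: no cover - sanity
                raise AssertionError
            log.info("genome %s: %s best hit %s on %s span %d (of %d candidates)",
                     g.id, cls, h.signature_accession, h.orf_id, h.span,
                     len(classes[cls]))
            kept.append(DomainSequence(
                genome_id=g.id, domain_class=cls,
                aa_sequence=orf.aa_sequence[h.aa_start:h.aa_end],
                provenance=f"{h.signature_accession}|{h.orf_id}",
            ))
    return kept, omitted


# ---------------------------------------------------------------------------
# FASTA / report i/o


def read_fasta(text: str) -> list[GenomeRecord]:
    """FASTA reader: id up to first whitespace, remainder is description."""
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records.append(GenomeRecord(id=rec.id, sequence=str(rec.seq),
                                    description=rec.description))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate genome ids in FASTA: {', '.join(dupes)}")
    return records


def write_fasta(records: list[tuple[str, str]]) -> str:
    """Write (header, sequence) pairs as wrapped FASTA."""
    buf = io.StringIO()
    SeqIO.write(
        [SeqRecord(Seq(seq), id=hdr, description="") for hdr, seq in records],
        buf, "fasta",
    )
    return buf.getvalue()


def write_domain_fastas(kept: list[DomainSequence]) -> dict[str, str]:
    """Harvested domains as two FASTA texts keyed ``rdrp.faa`` / ``hel.faa``.

    Headers follow ``<genome_id>|<domain_class>|<signature_accession>``.
    """
    out = {}
    for cls, fname in ((RDRP, "rdrp.faa"), (HEL, "hel.faa")):
        recs = [(f"{d.genome_id}|{d.domain_class}|{d.provenance.split('|')[0]}",
                 d.aa_sequence)
                for d in kept if d.domain_class == cls]
        out[fname] = write_fasta(recs)
    return out


def write_omission_tsv(omitted: list[OmittedGenome]) -> str:
    lines = ["genome_id\treason"]
    for o in sorted(omitted, key=lambda x: x.genome_id):
        lines.append(f"{o.genome_id}\t{o.reason}")
    return "\n".join(lines) + "\n"
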