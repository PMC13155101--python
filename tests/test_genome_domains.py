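"""ORF finding, InterPro XML parsing, signature classification, harvesting."""

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from picotax import (DomainHit, GenomeRecord, ParseError, SignatureMap,
                     ValidationError, classify_signature, find_orfs,
                     harvest_domains, parse_interpro_xml, read_fasta)
from picotax.fixtures import make_toy_genome_set
from picotax.genome_domains import (HEL, OTHER, RDRP, OrfRecord,
                                    write_domain_fastas, write_omission_tsv)


# ---------------------------------------------------------------------------
# find_orfs


class TestFindOrfs:
    def test_no_start_codon_yields_nothing(self):
        assert find_orfs(GenomeRecord("g", "CCCCCC"), min_aa_len=1) == []

    def test_simple_orf_coordinates_and_translation(self):
        (orf,) = find_orfs(GenomeRecord("g", "ATGAAATAA"), min_aa_len=1)
        assert (orf.start, orf.end, orf.strand) == (0, 9, "+")
        assert orf.aa_sequence == "MK"
        assert not orf.partial

    def test_reverse_strand_orf(self):
        rc = str(Seq("ATGAAATAA").reverse_complement())
        (orf,) = find_orfs(GenomeRecord("g", rc), min_aa_len=1)
        assert orf.strand == "-"
        assert orf.aa_sequence == "MK"
        assert (orf.start, orf.end) == (0, 9)

    def test_partial_orf_flagged(self):
        (orf,) = find_orfs(GenomeRecord("g", "ATGAAAAAA"), min_aa_len=1)
        assert orf.partial and orf.aa_sequence == "MKK"

    def test_u_mapped_to_t(self):
        (orf,) = find_orfs(GenomeRecord("g", "AUGAAAUAA"), min_aa_len=1)
        assert orf.aa_sequence == "MK"

    def test_min_len_filter(self):
        assert find_orfs(GenomeRecord("g", "ATGAAATAA"), min_aa_len=3) == []

    def test_bad_character_rejected_with_position(self):
        with pytest.raises(ParseError, match="position 4"):
            find_orfs(GenomeRecord("g", "ATGAR ATAA"[:9].replace(" ", "")))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=12, max_size=120))
    def test_strand_symmetry(self, seq):
        """ORFs of the reverse complement mirror the original with
        strands swapped: identical aa multisets."""
        g = GenomeRecord("g", seq)
        rc = GenomeRecord("g", str(Seq(seq).reverse_complement()))
        fwd = find_orfs(g, min_aa_len=1)
        rev = find_orfs(rc, min_aa_len=1)
        assert sorted(o.aa_sequence for o in fwd) == sorted(o.aa_sequence for o in rev)
        swap = {"+": "-", "-": "+"}
        assert sorted((o.aa_sequence, swap[o.strand]) for o in fwd) == \
            sorted((o.aa_sequence, o.strand) for o in rev)

    def test_orfs_ordered_by_position_and_deterministic(self):
        seq = "ATGAAATAACCCATGTTTTGA"
        orfs = find_orfs(GenomeRecord("g", seq), min_aa_len=1)
        assert [o.start for o in orfs] == sorted(o.start for o in orfs)
        assert orfs == find_orfs(GenomeRecord("g", seq), min_aa_len=1)


# ---------------------------------------------------------------------------
# classify_signature


@pytest.mark.parametrize("acc,name,expected", [
    ("PF00680", "anything", RDRP),
    ("PF00910", "anything", HEL),
    ("PFXXXXX", "a viral helicase domain", HEL),
    ("PFXXXXX", "RNA-dependent RNA polymerase", RDRP),
    ("PF00000", "unknown", OTHER),
    # accession wins over a conflicting name keyword
    ("PF00680", "helicase-like", RDRP),
])
def test_classify_signature(acc, name, expected):
    assert classify_signature(acc, name, SignatureMap()) == expected


def test_signature_map_from_yaml_overrides():
    m = SignatureMap.from_yaml("rdrp_accessions: [XX1]\nhel_keywords: [unwindase]\n")
    assert classify_signature("XX1", "", m) == RDRP
    assert classify_signature("", "putative unwindase", m) == HEL
    assert classify_signature("PF00680", "", m) == OTHER  # default list replaced


# ---------------------------------------------------------------------------
# parse_interpro_xml


NS = "https://ftp.ebi.ac.uk/pub/software/unix/iprscan/5/schema"


def _xml(body: str) -> str:
    return f'<protein-matches xmlns="{NS}">{body}</protein-matches>'


def _orf(orf_id="g1.orf1", aa_len=300):
    return OrfRecord(orf_id=orf_id, genome_id=orf_id.split(".")[0],
                     start=0, end=(aa_len + 1) * 3, strand="+",
                     aa_sequence="M" + "A" * (aa_len - 1))


class TestParseInterproXml:
    def test_zero_matches(self):
        hits = parse_interpro_xml(_xml("<protein><xref id='g1.orf1'/>"
                                       "<matches/></protein>"),
                                  {"g1.orf1": _orf()})
        assert hits == []

    def test_coordinate_convention(self):
        """1-based inclusive 10-250 in the XML becomes 0-based half-open
        [9, 250)."""
        body = ("<protein><xref id='g1.orf1'/><matches>"
                "<hmmer3-match score='99' evalue='1e-30'>"
                "<signature ac='PF00680' name='RdRP_1'>"
                "<signature-library-release library='PFAM' version='37'/>"
                "</signature>"
                "<locations><hmmer3-location start='10' end='250'/></locations>"
                "</hmmer3-match></matches></protein>")
        (hit,) = parse_interpro_xml(_xml(body), {"g1.orf1": _orf()})
        assert (hit.aa_start, hit.aa_end) == (9, 250)
        assert hit.domain_class == RDRP
        assert hit.source_db == "PFAM"
        assert hit.score == 99.0

    def test_two_overlapping_hits_both_returned(self):
        body = ("<protein><xref id='g1.orf1'/><matches>"
                "<hmmer3-match><signature ac='PF00680' name='r1'/>"
                "<locations><hmmer3-location start='10' end='250'/></locations>"
                "</hmmer3-match>"
                "<hmmer3-match><signature ac='PF00978' name='r2'/>"
                "<locations><hmmer3-location start='100' end='260'/></locations>"
                "</hmmer3-match></matches></protein>")
        hits = parse_interpro_xml(_xml(body), {"g1.orf1": _orf()})
        assert len(hits) == 2
        assert all(h.domain_class == RDRP for h in hits)

    def test_unknown_protein_skipped(self, caplog):
        body = ("<protein><xref id='nope.orf9'/><matches>"
                "<hmmer3-match><signature ac='PF00680' name='r'/>"
                "<locations><hmmer3-location start='1' end='5'/></locations>"
                "</hmmer3-match></matches></protein>")
        with caplog.at_level("WARNING"):
            hits = parse_interpro_xml(_xml(body), {"g1.orf1": _orf()})
        assert hits == []
        assert "nope.orf9" in caplog.text

    def test_coordinates_outside_translation_rejected(self):
        body = ("<protein><xref id='g1.orf1'/><matches>"
                "<hmmer3-match><signature ac='PF00680' name='r'/>"
                "<locations><hmmer3-location start='1' end='9999'/></locations>"
                "</hmmer3-match></matches></protein>")
        with pytest.raises(ValidationError, match="g1.orf1"):
            parse_interpro_xml(_xml(body), {"g1.orf1": _orf()})

    def test_malformed_xml(self):
        with pytest.raises(ParseError):
            parse_interpro_xml("<protein-matches><oops", {})


# ---------------------------------------------------------------------------
# harvest_domains


def _hit(orf_id, cls, start, end, score=None):
    return DomainHit(orf_id=orf_id, domain_class=cls, aa_start=start,
                     aa_end=end, signature_accession="SIG", score=score)


class TestHarvest:
    def test_nominal_both_domains_kept(self):
        g = GenomeRecord("g1", "A" * 30)
        orf = _orf("g1.orf1")
        kept, omitted = harvest_domains(
            [g], [orf],
            [_hit("g1.orf1", RDRP, 10, 250), _hit("g1.orf1", HEL, 0, 5)])
        assert [d.domain_class for d in kept] == [RDRP, HEL]
        assert omitted == []
        assert kept[0].aa_sequence == orf.aa_sequence[10:250]

    @pytest.mark.parametrize("classes,reason", [
        ([RDRP], "no_hel"), ([HEL], "no_rdrp"), ([], "no_rdrp_no_hel"),
    ])
    def test_omission_reasons(self, classes, reason):
        g = GenomeRecord("g1", "A" * 30)
        hits = [_hit("g1.orf1", c, 0, 10) for c in classes]
        kept, omitted = harvest_domains([g], [_orf("g1.orf1")], hits)
        assert kept == []
        assert [(o.genome_id, o.reason) for o in omitted] == [("g1", reason)]

    def test_longest_span_wins(self):
        g = GenomeRecord("g1", "A" * 30)
        orf = _orf("g1.orf1")
        kept, _ = harvest_domains(
            [g], [orf],
            [_hit("g1.orf1", RDRP, 0, 100), _hit("g1.orf1", RDRP, 10, 250),
             _hit("g1.orf1", HEL, 0, 10)])
        rdrp = next(d for d in kept if d.domain_class == RDRP)
        assert rdrp.aa_sequence == orf.aa_sequence[10:250]  # 240 > 100 aa

    def test_score_breaks_span_tie(self):
        g = GenomeRecord("g1", "A" * 30)
        orf = _orf("g1.orf1")
        kept, _ = harvest_domains(
            [g], [orf],
            [_hit("g1.orf1", RDRP, 0, 100, score=5.0),
             _hit("g1.orf1", RDRP, 100, 200, score=50.0),
             _hit("g1.orf1", HEL, 0, 10)])
        rdrp = next(d for d in kept if d.domain_class == RDRP)
        assert rdrp.aa_sequence == orf.aa_sequence[100:200]

    def test_partition_property_on_toy_set(self):
        toy = make_toy_genome_set(9, with_rdrp=2 / 3, with_hel=1 / 3, seed=5)
        genomes = read_fasta(toy.fasta)
        orfs = [o for g in genomes for o in find_orfs(g)]
        hits = parse_interpro_xml(toy.xml, {o.orf_id: o for o in orfs})
        kept, omitted = harvest_domains(genomes, orfs, hits)
        kept_ids = {d.genome_id for d in kept}
        omitted_ids = {o.genome_id for o in omitted}
        assert kept_ids | omitted_ids == {g.id for g in genomes}
        assert kept_ids & omitted_ids == set()
        assert len(omitted) == len(omitted_ids)

    def test_outputs_roundtrip_formats(self):
        toy = make_toy_genome_set(4, seed=1)
        genomes = read_fasta(toy.fasta)
        orfs = [o for g in genomes for o in find_orfs(g)]
        hits = parse_interpro_xml(toy.xml, {o.orf_id: o for o in orfs})
        kept, omitted = harvest_domains(genomes, orfs, hits)
        fastas = write_domain_fastas(kept)
        assert fastas["rdrp.faa"].startswith(">g001|RDRP|PF00680")
        back = read_fasta(fastas["rdrp.faa"])
        assert [r.sequence for r in back] == \
            [d.aa_sequence for d in kept if d.domain_class == RDRP]
        assert write_omission_tsv(omitted).startswith("genome_id\treason")
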