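"""I/O, domain-type validation and genetic-code translation."""

import pytest
from hypothesis import given, strategies as st

from cyanomito.seqio import (
    AlignmentMatrix,
    FormatError,
    GeneFeature,
    Genome,
    VariantRecord,
    compare_genetic_codes,
    read_alignment,
    read_fasta,
    read_genbank,
    read_vcf,
    reverse_complement,
    translate_cds,
    write_fasta,
)

# -- FASTA -------------------------------------------------------------------


def test_read_fasta_normalizes_case_and_uracil(tmp_path):
    p = tmp_path / "x.fa"
    p.write_text(">x\nacgu\n")
    (g,) = read_fasta(p)
    assert g.id == "x" and g.sequence == "ACGT"


def test_read_fasta_multiple_records(tmp_path):
    p = tmp_path / "two.fa"
    p.write_text(">a\nAC\n>b\nGT\n")
    genomes = read_fasta(p)
    assert [g.id for g in genomes] == ["a", "b"]
    assert [g.sequence for g in genomes] == ["AC", "GT"]


def test_read_fasta_rejects_non_iupac_naming_position(tmp_path):
    p = tmp_path / "bad.fa"
    p.write_text(">x\nACJGT\n")
    with pytest.raises(FormatError, match="position 2"):
        read_fasta(p)


def test_read_fasta_empty_file_is_format_error(tmp_path):
    p = tmp_path / "empty.fa"
    p.write_text("")
    with pytest.raises(FormatError):
        read_fasta(p)


@given(st.lists(st.text(alphabet="ACGTN", min_size=1, max_size=80),
                min_size=1, max_size=5))
def test_fasta_round_trip_preserves_sequences(tmp_path_factory, seqs):
    """write_fasta(read_fasta(f)) reproduces sequences byte-identically."""
    tmp = tmp_path_factory.mktemp("rt")
    p1, p2 = tmp / "a.fa", tmp / "b.fa"
    genomes = [Genome(id=f"g{i}", sequence=s) for i, s in enumerate(seqs)]
    write_fasta(genomes, p1)
    back = read_fasta(p1)
    write_fasta(back, p2)
    assert [g.sequence for g in back] == seqs
    assert p1.read_bytes() == p2.read_bytes()


# -- Genome invariants -------------------------------------------------------


def test_genome_rejects_empty_and_out_of_range_features():
    with pytest.raises(ValueError):
        Genome(id="x", sequence="")
    with pytest.raises(ValueError, match="outside"):
        Genome(id="x", sequence="ACGT",
               features=[GeneFeature("f", 2, 9, "+", "CDS")])


def test_wrap_feature_extraction_concatenates_across_origin():
    g = Genome(id="x", sequence="AAACGTTT",
               features=[GeneFeature("f", 6, 2, "+", "CDS", wrap=True)])
    assert g.feature_sequence(g.features[0]) == "TTAA"


def test_minus_strand_feature_is_reverse_complemented():
    g = Genome(id="x", sequence="AACGTT",
               features=[GeneFeature("f", 1, 4, "-", "CDS")])
    assert g.feature_sequence(g.features[0]) == reverse_complement("ACG")


# -- GenBank -----------------------------------------------------------------

GENBANK_TOY = """\
LOCUS       TESTMITO                40 bp    DNA     circular PLN 01-JAN-2020
DEFINITION  toy mitogenome.
ACCESSION   TESTMITO
VERSION     TESTMITO.1
FEATURES             Location/Qualifiers
     source          1..40
                     /organism="toy"
     CDS             complement(10..20)
                     /gene="cob"
     CDS             join(35..40,1..6)
                     /gene="wrapgene"
     tRNA            25..30
                     /gene="trnA"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""


def test_read_genbank_converts_coordinates_once(tmp_path):
    """GenBank 1-based inclusive becomes 0-based half-open; complement sets
    strand; join across the origin becomes a single wrap feature."""
    p = tmp_path / "toy.gb"
    p.write_text(GENBANK_TOY)
    g = read_genbank(p)
    assert g.topology == "circular" and len(g) == 40
    by_name = {f.name: f for f in g.features}
    cob = by_name["cob"]
    assert (cob.start, cob.end, cob.strand, cob.wrap) == (9, 20, "-", False)
    wrap = by_name["wrapgene"]
    assert wrap.wrap and (wrap.start, wrap.end) == (34, 6)
    assert by_name["trnA"].kind == "tRNA"


def test_read_genbank_no_features(tmp_path):
    p = tmp_path / "bare.gb"
    p.write_text(
        "LOCUS       BARE                10 bp    DNA     linear PLN 01-JAN-2020\n"
        "DEFINITION  bare.\nACCESSION   BARE\n"
        "ORIGIN\n        1 acgtacgtac\n//\n"
    )
    g = read_genbank(p)
    assert g.features == [] and g.topology == "linear"


def test_read_genbank_missing_origin_is_format_error(tmp_path):
    p = tmp_path / "noseq.gb"
    p.write_text(
        "LOCUS       NOSEQ               10 bp    DNA     linear PLN 01-JAN-2020\n"
        "DEFINITION  none.\nACCESSION   NOSEQ\n//\n"
    )
    with pytest.raises(FormatError):
        read_genbank(p)


# -- translation -------------------------------------------------------------


@pytest.mark.parametrize(
    "nt,code,protein,internal",
    [
        ("ATGAAA", 1, "MK", []),
        ("TGA", 1, "", []),            # lone trailing stop removed
        ("TGA", 4, "W", []),           # code 4 reads TGA as Trp
        ("ATGTGAAAA", 1, "M*K", [1]),  # internal stop reported, not dropped
        ("ATGTGAAAA", 4, "MWK", []),
    ],
)
def test_translate_cds(nt, code, protein, internal):
    r = translate_cds(nt, code)
    assert r.protein == protein
    assert r.internal_stops == internal


def test_translate_cds_requires_triplet_length_and_known_code():
    with pytest.raises(ValueError, match="divisible by 3"):
        translate_cds("ATGA", 1)
    with pytest.raises(ValueError, match="not supported"):
        translate_cds("ATG", 2)


def test_two_code_comparison_flags_divergent_products():
    """A CDS whose code-4 reading differs (TGA readthrough) is flagged: the
    basis for choosing the standard code over the protozoan mitochondrial
    code during annotation."""
    res = compare_genetic_codes("ATGTGAAAA")
    assert res["divergent"]
    assert not compare_genetic_codes("ATGAAA")["divergent"]


# -- alignments --------------------------------------------------------------


def test_read_alignment_attaches_groups(tmp_path, group_map_abc):
    p = tmp_path / "aln.fa"
    p.write_text(">a\nMK-\n>b\nMKC\n>c\nMRC\n")
    aln = read_alignment(p, group_map_abc)
    assert aln.taxa == ["a", "b", "c"] and aln.n_columns == 3
    assert aln.group_of["a"] == "G_type"


def test_read_alignment_rejects_ragged_rows(tmp_path, group_map_abc):
    p = tmp_path / "ragged.fa"
    p.write_text(">a\nMKCDEFGHIK\n>b\nMKCDEFGHI\n>c\nMKCDEFGHIK\n")
    with pytest.raises(FormatError, match="ragged"):
        read_alignment(p, group_map_abc)


def test_read_alignment_rejects_duplicate_taxa(tmp_path, group_map_abc):
    p = tmp_path / "dup.fa"
    p.write_text(">a\nMK\n>a\nMR\n")
    with pytest.raises(FormatError, match="duplicate"):
        read_alignment(p, group_map_abc)


def test_read_alignment_rejects_unmapped_taxon(tmp_path):
    p = tmp_path / "aln.fa"
    p.write_text(">a\nMK\n>zzz\nMR\n")
    with pytest.raises(ValueError, match="zzz"):
        read_alignment(p, {"a": "G_type"})


# -- variants ----------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chrM,length=1000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def test_read_vcf_keeps_snps_skips_indels(tmp_path):
    p = tmp_path / "v.vcf"
    p.write_text(VCF_HEADER
                 + "chrM\t5\t.\tA\tG\t50\tPASS\t.\n"
                 + "chrM\t10\t.\tAT\tA\t50\tPASS\t.\n")
    recs = read_vcf(p)
    assert len(recs) == 1
    assert recs[0] == VariantRecord("chrM", 4, "A", "G")


def test_read_vcf_empty_body(tmp_path):
    p = tmp_path / "v.vcf"
    p.write_text(VCF_HEADER)
    assert read_vcf(p) == []


def test_read_vcf_expands_multiallelic_snp(tmp_path):
    p = tmp_path / "v.vcf"
    p.write_text(VCF_HEADER + "chrM\t7\t.\tA\tC,T\t50\tPASS\t.\n")
    recs = read_vcf(p)
    assert [(r.position, r.ref, r.alt) for r in recs] == [(6, "A", "C"), (6, "A", "T")]


def test_variant_record_rejects_ref_equal_alt():
    with pytest.raises(ValueError):
        VariantRecord("g", 0, "A", "A")
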