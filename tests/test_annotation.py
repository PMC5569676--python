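"""Annotation reading and intragenic-miRNA classification."""

import itertools

import pytest

from intramir.annotation import (
    AnnotationError,
    GeneModel,
    GenomicInterval,
    HostAssignment,
    MiRNARecord,
    TranscriptModel,
    classify_all,
    classify_mirna,
    read_gene_annotation,
    read_mirna_annotation,
    summarize_annotation,
)


def iv(start, end, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, start, end, strand)


def make_gene(gene_id, span, exons, strand="+"):
    tx = TranscriptModel(gene_id + ".t1", gene_id, [iv(a, b, strand) for a, b in exons])
    return GeneModel(
        gene_id, gene_id, iv(*span, strand), [tx], [iv(a, b, strand) for a, b in exons]
    )


def mirna(start, end, strand="+", mid="mir-x"):
    return MiRNARecord(mid, iv(start, end, strand))


# ---------------------------------------------------------------------------
# file readers


GFF3 = """##gff-version 3
chr1\tsrc\tgene\t1001\t5000\t.\t+\t.\tID=G1;Name=GENE1
chr1\tsrc\tmRNA\t1001\t5000\t.\t+\t.\tID=T1;Parent=G1
chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tParent=T1
chr1\tsrc\texon\t4801\t5000\t.\t+\t.\tParent=T1
chr1\tsrc\tCDS\t1051\t1200\t.\t+\t0\tParent=T1
chr1\tsrc\tCDS\t4801\t4900\t.\t+\t0\tParent=T1
"""


def test_gff3_coordinates_become_half_open(tmp_path):
    path = tmp_path / "g.gff3"
    path.write_text(GFF3)
    genes = read_gene_annotation(str(path), "gff3")
    assert len(genes) == 1
    g = genes[0]
    assert (g.span.start, g.span.end) == (1000, 5000)
    assert [(e.start, e.end) for e in g.merged_exons] == [(1000, 1200), (4800, 5000)]
    # UTR derived from CDS end: exonic space 3' of 4900
    assert [(u.start, u.end) for u in g.transcripts[0].utr3] == [(4900, 5000)]


def test_gtf_utr_derived_from_cds_end(tmp_path):
    gtf = (
        'chr1\tsrc\texon\t1001\t2000\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
        'chr1\tsrc\tCDS\t1001\t1200\t.\t+\t0\tgene_id "G1"; transcript_id "T1";\n'
    )
    path = tmp_path / "g.gtf"
    path.write_text(gtf)
    genes = read_gene_annotation(str(path), "gtf")
    utr3 = genes[0].transcripts[0].utr3
    assert [(u.start, u.end) for u in utr3] == [(1200, 2000)]


def test_minus_strand_utr_is_5prime_of_cds_start(tmp_path):
    gtf = (
        'chr1\tsrc\texon\t1001\t2000\t.\t-\t.\tgene_id "G1"; transcript_id "T1";\n'
        'chr1\tsrc\tCDS\t1501\t2000\t.\t-\t0\tgene_id "G1"; transcript_id "T1";\n'
    )
    path = tmp_path / "g.gtf"
    path.write_text(gtf)
    utr3 = read_gene_annotation(str(path), "gtf")[0].transcripts[0].utr3
    assert [(u.start, u.end) for u in utr3] == [(1000, 1500)]


def test_empty_file_gives_empty_list(tmp_path):
    path = tmp_path / "empty.gff3"
    path.write_text("")
    assert read_gene_annotation(str(path), "gff3") == []


def test_malformed_line_names_line_number(tmp_path):
    path = tmp_path / "bad.gff3"
    path.write_text("chr1\tsrc\tgene\toops\n")
    with pytest.raises(AnnotationError, match="line 1"):
        read_gene_annotation(str(path), "gff3")


def test_transcript_with_unknown_gene_errors(tmp_path):
    path = tmp_path / "orphan.gff3"
    path.write_text("chr1\tsrc\tmRNA\t1\t100\t.\t+\t.\tID=T1;Parent=NOPE\n")
    with pytest.raises(AnnotationError, match="unknown gene"):
        read_gene_annotation(str(path), "gff3")


def test_mirna_reader_normalizes_and_links(tmp_path):
    gff = (
        "chr1\tsrc\tmiRNA_primary_transcript\t2001\t2080\t.\t+\t.\tID=mir-1\n"
        "chr1\tsrc\tmiRNA\t2001\t2022\t.\t+\t.\tID=miR-1-5p;Derives_from=mir-1\n"
        "chr1\tsrc\tmiRNA_primary_transcript\t3001\t3080\t.\t+\t.\tID=mir-2\n"
    )
    fasta = ">miR-1-5p\nTAGCTTATCAGACTGATGTTGA\n"
    (tmp_path / "m.gff3").write_text(gff)
    (tmp_path / "m.fa").write_text(fasta)
    recs = read_mirna_annotation(str(tmp_path / "m.gff3"), str(tmp_path / "m.fa"))
    assert len(recs) == 2
    r1 = recs[0]
    assert (r1.precursor.start, r1.precursor.end) == (2000, 2080)
    assert r1.matures["miR-1-5p"] == "UAGCUUAUCAGACUGAUGUUGA"  # T -> U
    assert recs[1].matures == {}  # kept, matures empty


def test_short_mature_rejected_with_warning(tmp_path):
    gff = "chr1\tsrc\tmiRNA_primary_transcript\t1\t80\t.\t+\t.\tID=mir-1\n" \
          "chr1\tsrc\tmiRNA\t1\t7\t.\t+\t.\tID=miR-1-5p;Derives_from=mir-1\n"
    (tmp_path / "m.gff3").write_text(gff)
    (tmp_path / "m.fa").write_text(">miR-1-5p\nACGUACG\n")  # 7 nt < 8
    with pytest.warns(UserWarning, match="shorter than 8"):
        recs = read_mirna_annotation(str(tmp_path / "m.gff3"), str(tmp_path / "m.fa"))
    assert recs[0].matures == {}


# ---------------------------------------------------------------------------
# classification geometry

HOST = make_gene("G1", (1000, 5000), [(1000, 1200), (4800, 5000)])


@pytest.mark.parametrize(
    "pre,expect",
    [
        # fully inside the single merged intron, same strand
        (iv(2000, 2080), ("intronic", "sense", 1)),
        # overlapping the first exon, opposite strand
        (iv(1100, 1180, "-"), ("exonic", "antisense", None)),
        # spanning the exon/intron boundary -> exonic wins
        (iv(1150, 1250), ("exonic", "sense", None)),
        # straddling the gene start -> intragenic (exonic: terminal exon)
        (iv(950, 1050), ("exonic", "sense", None)),
    ],
)
def test_classification_geometry(pre, expect):
    a = classify_mirna(MiRNARecord("m", pre), [HOST])
    assert (a.context, a.orientation, a.intron_index) == expect
    assert a.gene_id == "G1"


def test_intergenic_when_no_gene_overlaps():
    a = classify_mirna(mirna(6000, 6080), [HOST])
    assert a.context == "intergenic"
    assert a.gene_id is None and a.orientation == "not-applicable"


def test_nested_gene_tiebreaks_prefer_sense_then_overlap():
    outer = make_gene("OUT", (1000, 9000), [(1000, 1100), (8900, 9000)])
    inner = make_gene("INN", (2000, 3000), [(2000, 2100), (2900, 3000)], strand="-")
    # precursor inside both spans, + strand: sense host is OUT
    a = classify_mirna(mirna(2200, 2280, "+"), [outer, inner])
    assert a.gene_id == "OUT" and a.context == "intronic"
    # - strand: sense host is INN (intron of the inner gene)
    b = classify_mirna(mirna(2200, 2280, "-"), [outer, inner])
    assert b.gene_id == "INN" and b.context == "intronic" and b.intron_index == 1
    # both antisense candidates -> larger overlap wins
    inner_plus = make_gene("INN", (2000, 3000), [(2000, 2100), (2900, 3000)])
    c = classify_mirna(mirna(950, 1500, "-"), [outer, inner_plus])
    assert c.gene_id == "OUT"


def test_intron_index_counts_5prime_to_3prime_on_minus_strand():
    g = make_gene(
        "GM", (1000, 5000), [(1000, 1200), (2000, 2200), (4800, 5000)], strand="-"
    )
    # genomically-last intron is the 5'-most on '-': index 1
    a = classify_mirna(mirna(3000, 3080, "-"), [g])
    assert a.intron_index == 1
    b = classify_mirna(mirna(1500, 1580, "-"), [g])
    assert b.intron_index == 2


def test_classification_invariant_under_gene_order():
    outer = make_gene("OUT", (1000, 9000), [(1000, 1100), (8900, 9000)])
    inner = make_gene("INN", (2000, 3000), [(2000, 2100), (2900, 3000)], strand="-")
    mirnas = [mirna(2200, 2280, "+", "a"), mirna(2200, 2280, "-", "b"),
              mirna(1050, 1130, "+", "c"), mirna(9500, 9580, "+", "d")]
    far = make_gene("ZZZ", (20000, 21000), [(20000, 21000)])
    for perm in itertools.permutations([outer, inner, far]):
        res = classify_all(mirnas, list(perm))
        assert [(a.gene_id, a.context) for a in res] == [
            ("OUT", "intronic"), ("INN", "intronic"),
            ("OUT", "exonic"), (None, "intergenic"),
        ]


def test_every_mirna_gets_exactly_one_assignment(study_manifest):
    truths = study_manifest["mirnas"]
    n = len(truths)
    counts = {"intronic": 0, "exonic": 0, "intergenic": 0}
    for t in truths:
        counts[t["context"]] += 1
    assert sum(counts.values()) == n


# ---------------------------------------------------------------------------
# summary arithmetic


def ha(mid, gene, context, orientation, idx=None):
    return HostAssignment(mid, gene, context, orientation, idx)


def test_summary_counts_and_sense_fraction():
    assigns = [
        ha("a", "G1", "intronic", "sense", 1),
        ha("b", "G1", "intronic", "sense", 1),
        ha("c", "G2", "intronic", "sense", 2),
        ha("d", "G2", "intronic", "antisense", 1),
    ]
    row = summarize_annotation(assigns).iloc[0]
    assert row["intronic"] == 4
    assert row["intronic_sense_pct"] == pytest.approx(75.0)
    assert row["host_genes"] == 2
    assert row["intragenic"] == 4 and row["intergenic"] == 0


def test_summary_all_intergenic():
    assigns = [ha(str(i), None, "intergenic", "not-applicable") for i in range(3)]
    row = summarize_annotation(assigns).iloc[0]
    assert row["intragenic"] == 0 and row["host_genes"] == 0
    assert row["intergenic"] == 3


def test_two_mirnas_sharing_one_host():
    assigns = [
        ha("a", "G1", "intronic", "sense", 1),
        ha("b", "G1", "exonic", "sense"),
    ]
    row = summarize_annotation(assigns).iloc[0]
    assert row["host_genes"] == 1 and row["intragenic"] == 2
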