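"""circRNA definitions, sequence acquisition models, and peptide list parsing."""

import pytest

from circpept import (
    CircInputError,
    CircRecord,
    MSPeptide,
    TranscriptModel,
    extract_sequence_model2,
    extract_sequence_model3,
    load_sequences_model1,
    read_circ_info,
    read_peptide_list,
    revcomp,
    write_circ_info,
)
from circpept.circ_input import gene_table_from_gtf, read_gtf_exons


# ---------------------------------------------------------------------- info

def test_read_circ_info_parses_blocks(tmp_path):
    p = tmp_path / "info.tsv"
    p.write_text("circA\tchr1\t+\t100-200,300-350\n")
    (rec,) = read_circ_info(p)
    assert rec.circ_id == "circA"
    assert rec.exon_blocks == ((100, 200), (300, 350))
    assert rec.block_span() == 150


@pytest.mark.parametrize(
    "content, match",
    [
        ("circA\tchr1\t+\t200-100\n", "line 1"),
        ("circA\tchr1\t+\t100-200\ncircA\tchr1\t+\t5-9\n", "circA"),
        ("circA\tchr1\t+\tzap\n", "malformed"),
    ],
)
def test_read_circ_info_errors_carry_context(tmp_path, content, match):
    p = tmp_path / "info.tsv"
    p.write_text(content)
    with pytest.raises(CircInputError, match=match):
        read_circ_info(p)


def test_info_roundtrip_idempotent(tmp_path, synth_small):
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    recs = [
        CircRecord(circ_id=c.circ_id, chrom="chr1", strand="+",
                   exon_blocks=((0, len(c.sequence)),))
        for c in synth_small["circs"][:10]
    ]
    write_circ_info(recs, p1)
    write_circ_info(read_circ_info(p1), p2)
    assert p1.read_text() == p2.read_text()


def test_one_based_dialect_converted(tmp_path):
    p = tmp_path / "info.tsv"
    p.write_text("circA\tchr1\t+\t101-200\n")
    (rec,) = read_circ_info(p, dialect={"coords": "1-based-closed"})
    assert rec.exon_blocks == ((100, 200),)


def test_circrecord_invariants():
    with pytest.raises(CircInputError):
        CircRecord(circ_id="c", exon_blocks=((10, 5),))
    with pytest.raises(CircInputError):
        CircRecord(circ_id="c", exon_blocks=((0, 20), (10, 30)))
    with pytest.raises(CircInputError):
        CircRecord(circ_id="c", exon_blocks=((0, 6),), sequence="ATG")


# ------------------------------------------------------------------- model 1

def test_model1_normalizes_and_maps_u_to_t(tmp_path):
    p = tmp_path / "c.fa"
    p.write_text(">circA\natgaaa\n>circB\nAUGAAA\n")
    seqs = load_sequences_model1(p)
    assert seqs == {"circA": "ATGAAA", "circB": "ATGAAA"}


def test_model1_duplicate_header_rejected(tmp_path):
    p = tmp_path / "c.fa"
    p.write_text(">circA\nATG\n>circA\nAAA\n")
    with pytest.raises(CircInputError, match="duplicate"):
        load_sequences_model1(p)


# ------------------------------------------------------------------- model 2

CHROM = "AAATGCAAGGTTT"


def test_model2_plus_strand_concatenates_blocks():
    circ = CircRecord(circ_id="c", chrom="chr1", strand="+",
                      exon_blocks=((2, 6), (9, 12)))
    # oracle: manual slicing CHROM[2:6] + CHROM[9:12]
    assert extract_sequence_model2(circ, {"chr1": CHROM}) == "ATGCGTT"


def test_model2_minus_strand_reverse_complements_whole():
    circ = CircRecord(circ_id="c", chrom="chr1", strand="-",
                      exon_blocks=((2, 6), (9, 12)))
    assert extract_sequence_model2(circ, {"chr1": CHROM}) == "AACGCAT"


def test_model2_errors():
    circ = CircRecord(circ_id="c", chrom="chrX", strand="+", exon_blocks=((2, 6),))
    with pytest.raises(CircInputError, match="chrX"):
        extract_sequence_model2(circ, {"chr1": CHROM})
    circ = CircRecord(circ_id="c", chrom="chr1", strand="+", exon_blocks=((2, 50),))
    with pytest.raises(CircInputError, match="outside"):
        extract_sequence_model2(circ, {"chr1": CHROM})


# ------------------------------------------------------------------- model 3

def test_model3_contiguous_transcript_substring():
    tx = TranscriptModel(transcript_id="t1", chrom="chr1", strand="+",
                         sequence="ATGCGTTAAA", exons=((10, 20),))
    circ = CircRecord(circ_id="c", chrom="chr1", strand="+", exon_blocks=((10, 17),))
    assert extract_sequence_model3(circ, [tx]) == "ATGCGTT"


def test_model3_not_found_lists_candidates():
    tx = TranscriptModel(transcript_id="t1", chrom="chr1", strand="+",
                         sequence="ATGCGTTAAA", exons=((10, 20),))
    circ = CircRecord(circ_id="c", chrom="chr1", strand="+", exon_blocks=((10, 99),))
    with pytest.raises(CircInputError, match="t1"):
        extract_sequence_model3(circ, [tx])


def test_model2_model3_agree_on_shared_exon_structure():
    """A transcript spliced from the same exon blocks yields the same circle."""
    genome = {"chr1": "TTACGGATGCCGTATCAAGGCTTACGAT"}
    blocks = ((3, 9), (14, 22))
    mature = genome["chr1"][3:9] + genome["chr1"][14:22]
    tx = TranscriptModel(transcript_id="t", chrom="chr1", strand="+",
                         sequence=mature, exons=blocks)
    circ = CircRecord(circ_id="c", chrom="chr1", strand="+", exon_blocks=blocks)
    assert extract_sequence_model2(circ, genome) == extract_sequence_model3(circ, [tx])


# ------------------------------------------------------------------ peptides

def test_peptide_list_plain_uppercases(tmp_path):
    p = tmp_path / "peps.txt"
    p.write_text("klaESAQQDSIK\n")  # junction peptide of hsa_circ_0028803
    peps, skipped = read_peptide_list(p)
    assert [x.sequence for x in peps] == ["KLAESAQQDSIK"]
    assert skipped == 0


def test_peptide_list_strips_modifications_and_skips_bad(tmp_path):
    p = tmp_path / "peps.csv"
    p.write_text("score,peptide\n10,PEPT(+15.99)IDE\n3,PEPTIDEX1\n")
    peps, skipped = read_peptide_list(p, dialect="delimited", column="peptide")
    assert [x.sequence for x in peps] == ["PEPTIDE"]
    assert skipped == 1


def test_peptide_list_missing_column(tmp_path):
    p = tmp_path / "peps.tsv"
    p.write_text("a\tb\nx\ty\n")
    with pytest.raises(CircInputError, match="sequence"):
        read_peptide_list(p, dialect="delimited", column="sequence")


def test_mspeptide_rejects_nonstandard():
    with pytest.raises(CircInputError):
        MSPeptide(sequence="PEPTIDEB1")
    with pytest.raises(CircInputError):
        MSPeptide(sequence="")


# ----------------------------------------------------------------------- gtf

def test_gene_table_from_gtf(tmp_path):
    gtf = tmp_path / "a.gtf"
    gtf.write_text(
        'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "GENE1";\n'
        'chr1\tx\texon\t301\t400\t.\t+\t.\tgene_id "GENE2";\n'
    )
    exons = read_gtf_exons(gtf)
    assert list(exons.start) == [100, 300]
    circs = [CircRecord(circ_id="c1", chrom="chr1", strand="+",
                        exon_blocks=((120, 180),)),
             CircRecord(circ_id="c2", chrom="chr2", strand="+",
                        exon_blocks=((120, 180),))]
    table = gene_table_from_gtf(circs, exons)
    assert table == {"c1": "GENE1"}


def test_revcomp():
    assert revcomp("ATGC") == "GCAT"
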