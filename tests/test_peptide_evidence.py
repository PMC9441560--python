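"""Peptide-to-cORF mapping, YY junction judgment, merging, and ribo evidence."""

import pytest

from circpept import (
    CORF,
    CircRecord,
    CorfHit,
    MSPeptide,
    ProteinRecord,
    ReferencePeptide,
    dedupe_peptides,
    filter_linear,
    find_junction_hits,
    junction_span,
    map_to_corf,
    merge_overlapping,
    reference_peptides,
    ribo_evidence,
)


def mk_corf(peptide, circ_id="c", idx=0):
    return CORF(circ_id=circ_id, corf_index=idx, start_nt=0,
                nt_length=3 * len(peptide), laps=0.5, is_infinite=False,
                peptide=peptide, frame_phase=0)


def mk_ref(peptide, boundary, splits=False, circ_id="c"):
    return ReferencePeptide(circ_id=circ_id, frame="+1", peptide=peptide,
                            junction_aa_boundary=boundary,
                            junction_splits_codon=splits)


# -------------------------------------------------------------------- dedupe

def test_dedupe_stable_and_casefolded():
    peps = [MSPeptide("AAK"), MSPeptide("AAK"), MSPeptide("AKR"),
            MSPeptide("aak")]
    assert [p.sequence for p in dedupe_peptides(peps)] == ["AAK", "AKR"]
    assert dedupe_peptides([]) == []


# ------------------------------------------------------------------- mapping

def test_map_to_corf_reports_every_occurrence():
    hits = map_to_corf(MSPeptide("MAA"), [mk_corf("MAAMAAMAA")])
    assert [(h.aa_start, h.aa_end) for h in hits] == [(0, 3), (3, 6), (6, 9)]


def test_map_to_corf_absent_or_too_long():
    assert map_to_corf(MSPeptide("WWW"), [mk_corf("MAAMAA")]) == []
    assert map_to_corf(MSPeptide("M" + "A" * 30), [mk_corf("MAA")]) == []


def test_map_to_corf_il_equivalence_opt_in():
    corf = mk_corf("MKIIR")
    assert map_to_corf(MSPeptide("KLLR"), [corf]) == []
    assert len(map_to_corf(MSPeptide("KLLR"), [corf], il_equivalent=True)) == 1


# --------------------------------------------------------------- junction YY

def test_junction_span_worked_example_yy4():
    """18-residue reference, boundary 10: a 9-mer matching at 6 leaves four
    residues before and five after the junction -> YY4."""
    ref_pep = "ACDEFGHIKLMNPQRSTV"
    ref = mk_ref(ref_pep, boundary=10)
    hit = junction_span(MSPeptide(ref_pep[6:15]), ref)
    assert (hit.left_count, hit.right_count, hit.yy) == (4, 5, 4)


def test_junction_span_entirely_one_side_is_no_span():
    ref = mk_ref("ACDEFGHIKLMNPQRSTV", boundary=10)
    assert junction_span(MSPeptide("ACDEFGHIKL"), ref) is None  # s+n <= b
    assert junction_span(MSPeptide("MNPQRSTV"), ref) is None


def test_junction_span_split_codon_residue_counts_neither_side():
    ref_pep = "ACDEFGHIKLMNPQRSTV"
    ref = mk_ref(ref_pep, boundary=10, splits=True)
    hit = junction_span(MSPeptide(ref_pep[7:16]), ref)  # s=7, n=9 covers b=10
    assert (hit.left_count, hit.right_count, hit.yy) == (3, 5, 3)


def test_junction_span_keeps_max_yy_match():
    # peptide occurs twice; second occurrence is centred on the junction
    ref = mk_ref("AAKWWAAKWW", boundary=6)
    hit = junction_span(MSPeptide("AAKW"), ref)
    assert hit.match_start == 5 and hit.yy == 1


def test_find_junction_hits_threshold_and_multimap(synth_small):
    refs, _ = reference_peptides(synth_small["circs"])
    peps = synth_small["peptides"]
    for t in (2, 4):
        hits = find_junction_hits(peps, refs, min_yy=t)
        assert all(h.yy >= t for h in hits)
        assert all(h.yy == min(h.left_count, h.right_count) for h in hits)


# ------------------------------------------------------------- linear filter

def test_filter_linear_flags_exact_substrings():
    hits = find_junction_hits([MSPeptide("ACDEFKLMNP")],
                              [mk_ref("WACDEFKLMNPW", boundary=6)], min_yy=2)
    prot = ProteinRecord(protein_id="p", sequence="XXXACDEFKLMNPXXX".replace("X", "G"))
    retained, flagged = filter_linear(hits, [prot])
    assert not retained and len(flagged) == 1
    # one-residue mismatch is retained (exact match only)
    retained, flagged = filter_linear(hits,
                                      [ProteinRecord(protein_id="p",
                                                     sequence="ACDEFKLMNA")])
    assert len(retained) == 1 and not flagged
    retained, flagged = filter_linear(hits, [])
    assert len(retained) == 1


# ------------------------------------------------------------------- merging

def test_merge_overlapping_examples():
    corf = mk_corf("ACDEFGHIKLMNPQR")

    def hits(*ivals):
        return [CorfHit(peptide=MSPeptide(corf.peptide[a:b]), circ_id="c",
                        corf_index=0, aa_start=a, aa_end=b) for a, b in ivals]

    (m,) = merge_overlapping(hits((2, 10), (7, 15)), [corf])
    assert (m.aa_start, m.aa_end, m.member_count) == (2, 15, 2)
    assert m.sequence == corf.peptide[2:15]

    two = merge_overlapping(hits((0, 5), (10, 15)), [corf])
    assert [(m.aa_start, m.aa_end) for m in two] == [(0, 5), (10, 15)]

    (m,) = merge_overlapping(hits((0, 5), (4, 9), (8, 12)), [corf])
    assert (m.aa_start, m.aa_end, m.member_count) == (0, 12, 3)


def test_merge_idempotent_and_contains_members():
    corf = mk_corf("ACDEFGHIKLMNPQR")
    hits = [CorfHit(peptide=MSPeptide(corf.peptide[a:b]), circ_id="c",
                    corf_index=0, aa_start=a, aa_end=b)
            for a, b in ((1, 6), (5, 11), (11, 14))]
    merged = merge_overlapping(hits, [corf])
    for m in merged:
        assert m.sequence == corf.peptide[m.aa_start:m.aa_end]
        assert len(m.sequence) >= max(
            h.aa_end - h.aa_start for h in hits
            if h.aa_start >= m.aa_start and h.aa_end <= m.aa_end)
    again = merge_overlapping(
        [CorfHit(peptide=MSPeptide(m.sequence), circ_id="c", corf_index=0,
                 aa_start=m.aa_start, aa_end=m.aa_end) for m in merged],
        [corf])
    assert [(m.aa_start, m.aa_end) for m in again] == \
           [(m.aa_start, m.aa_end) for m in merged]


def test_merge_rejects_inconsistent_member():
    corf = mk_corf("ACDEFGHIKL")
    bad = [CorfHit(peptide=MSPeptide("WWW"), circ_id="c", corf_index=0,
                   aa_start=0, aa_end=3)]
    with pytest.raises(ValueError, match="does not match"):
        merge_overlapping(bad, [corf])


# ---------------------------------------------------------------------- ribo

def test_ribo_evidence_junction_coverage():
    seq = "ATGCGTACGTTAGCATGCAA"
    circ = CircRecord(circ_id="c", sequence=seq)
    L = len(seq)
    doubled = seq + seq
    spanning = doubled[L - 10:L + 10]
    inside = seq[2:18]
    assert ribo_evidence(circ, [spanning]) is True
    assert ribo_evidence(circ, [inside]) is False
    assert ribo_evidence(circ, []) is False
    # reverse complement of a spanning read also counts
    from circpept import revcomp
    assert ribo_evidence(circ, [revcomp(spanning)]) is True
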