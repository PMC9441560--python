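"""Connecting MS peptides to cORFs and back-splice junctions.

The evidence chain: deduplicate the peptide list, map peptides exactly onto
cORF peptides, judge junction spanning on the six-frame reference peptides
(the YY value = min residues on either side of the BSJ), flag peptides that
are explainable by linear parental proteins, merge overlapping junction
peptides into the longest evidenced stretch, and optionally attach ribo-seq
support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .circ_input import CircRecord, MSPeptide, ProteinRecord, revcomp
from .corf_engine import CORF
from .junction_refdb import ReferencePeptide

DEFAULT_MIN_YY = 2  # reporting default; the target-decoy benchmark uses 3


@dataclass(frozen=True)
class JunctionHit:
    """An MS peptide matched across a BSJ on a reference peptide.

    ``yy = min(left_count, right_count)``: at least yy residues of the peptide
    lie wholly on each side of the junction ("YY4" = four on each side).  When
    the junction splits a codon, the straddling residue counts toward neither
    side.
    """

    peptide: MSPeptide
    circ_id: str
    frame: str
    match_start: int
    left_count: int
    right_count: int
    yy: int


@dataclass(frozen=True)
class CorfHit:
    """An exact substring match of an MS peptide on a cORF peptide."""

    peptide: MSPeptide
    circ_id: str
    corf_index: int
    aa_start: int
    aa_end: int


@dataclass(frozen=True)
class MergedPeptide:
    """Union of transitively overlapping peptide matches on one cORF."""

    circ_id: str
    corf_index: int
    aa_start: int
    aa_end: int
    sequence: str
    member_count: int
    spans_bsj: bool


def dedupe_peptides(peps: Iterable[MSPeptide]) -> list[MSPeptide]:
    """Remove repeated peptide sequences, keeping the first occurrence
    (comparison on the uppercase sequence only)."""
    seen: set[str] = set()
    out = []
    for p in peps:
        if p.sequence not in seen:
            seen.add(p.sequence)
            out.append(p)
    return out


def _find_all(needle: str, haystack: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def _fold_il(s: str) -> str:
    return s.replace("I", "L")


def map_to_corf(
    pep: MSPeptide, corfs: Sequence[CORF], il_equivalent: bool = False
) -> list[CorfHit]:
    """All exact substring occurrences of a peptide on the given cORF
    peptides; ``il_equivalent`` folds I and L before matching (MS cannot
    distinguish them)."""
    query = _fold_il(pep.sequence) if il_equivalent else pep.sequence
    hits = []
    for c in corfs:
        target = _fold_il(c.peptide) if il_equivalent else c.peptide
        for s in _find_all(query, target):
            hits.append(
                CorfHit(
                    peptide=pep,
                    circ_id=c.circ_id,
                    corf_index=c.corf_index,
                    aa_start=s,
                    aa_end=s + len(pep.sequence),
                )
            )
    return hits


def junction_span(
    pep: MSPeptide, ref: ReferencePeptide, il_equivalent: bool = False
) -> JunctionHit | None:
    """Judge whether an MS peptide spans the BSJ of a reference peptide.

    For a match at index s with length n against junction boundary b:
    residues wholly left of the BSJ number ``b - s`` and wholly right
    ``s + n - b``; when the BSJ splits codon b, residue b straddles the
    junction and counts toward neither side.  A junction hit requires at
    least one whole residue on each side; among multiple matches the one
    maximizing yy is returned.  Matches never cross a ``*`` (MS peptides
    contain no stop, so an exact match cannot include one).
    """
    query = _fold_il(pep.sequence) if il_equivalent else pep.sequence
    target = _fold_il(ref.peptide) if il_equivalent else ref.peptide
    n = len(query)
    b = ref.junction_aa_boundary
    best: JunctionHit | None = None
    for s in _find_all(query, target):
        if ref.junction_splits_codon:
            left = max(0, b - s)
            right = max(0, s + n - (b + 1))
        else:
            left = max(0, b - s)
            right = max(0, s + n - b)
        if left >= 1 and right >= 1:
            hit = JunctionHit(
                peptide=pep,
                circ_id=ref.circ_id,
                frame=ref.frame,
                match_start=s,
                left_count=left,
                right_count=right,
                yy=min(left, right),
            )
            if best is None or hit.yy > best.yy:
                best = hit
    return best


def find_junction_hits(
    peps: Iterable[MSPeptide],
    refs: Sequence[ReferencePeptide],
    min_yy: int = DEFAULT_MIN_YY,
    il_equivalent: bool = False,
) -> list[JunctionHit]:
    """Best junction hit per (peptide, circRNA) over all six frames, retained
    at ``yy >= min_yy``.  A peptide spanning the BSJs of several circRNAs
    yields one hit per circRNA (multi-mapped, not arbitrated)."""
    hits: list[JunctionHit] = []
    for pep in peps:
        per_circ: dict[str, JunctionHit] = {}
        for ref in refs:
            h = junction_span(pep, ref, il_equivalent)
            if h is None or h.yy < min_yy:
                continue
            prev = per_circ.get(h.circ_id)
            if prev is None or h.yy > prev.yy:
                per_circ[h.circ_id] = h
        hits.extend(per_circ[k] for k in sorted(per_circ))
    return hits


def filter_linear(
    hits: Iterable[JunctionHit], proteins: Sequence[ProteinRecord]
) -> tuple[list[JunctionHit], list[JunctionHit]]:
    """Split hits into (retained, flagged): a junction peptide occurring as an
    exact substring of any linear protein may originate from the parental gene
    (codon degeneracy) and is flagged rather than trusted."""
    retained, flagged = [], []
    prot_seqs = [p.sequence for p in proteins]
    for h in hits:
        if any(h.peptide.sequence in ps for ps in prot_seqs):
            flagged.append(h)
        else:
            retained.append(h)
    return retained, flagged


def merge_overlapping(
    hits: Iterable[CorfHit],
    corfs: Sequence[CORF],
    yy_index: Mapping[str, JunctionHit] | None = None,
) -> list[MergedPeptide]:
    """Merge transitively overlapping matches on the same cORF into the
    longest evidenced peptide.

    Within each (circRNA, cORF) group, intervals sharing at least one residue
    are unioned to a fixpoint (min start, max end); the merged sequence is cut
    from the cORF peptide so it stays a literally evidenced substring.
    ``spans_bsj`` is true when any member peptide has a junction hit.
    """
    yy_index = yy_index or {}
    corf_by_key = {(c.circ_id, c.corf_index): c for c in corfs}
    groups: dict[tuple[str, int], list[CorfHit]] = {}
    for h in hits:
        groups.setdefault((h.circ_id, h.corf_index), []).append(h)

    merged: list[MergedPeptide] = []
    for key in sorted(groups):
        corf = corf_by_key.get(key)
        if corf is None:
            raise ValueError(f"hit references unknown cORF {key}")
        members = sorted(groups[key], key=lambda h: (h.aa_start, h.aa_end))
        for m in members:
            if corf.peptide[m.aa_start : m.aa_end] != m.peptide.sequence:
                raise ValueError(
                    f"{key}: member {m.peptide.sequence} does not match cORF substring"
                )
        # sweep: strict overlap (>= 1 shared residue) required to merge
        cur = [members[0]]
        cur_start, cur_end = members[0].aa_start, members[0].aa_end
        def emit(start: int, end: int, mem: list[CorfHit]) -> None:
            merged.append(
                MergedPeptide(
                    circ_id=key[0],
                    corf_index=key[1],
                    aa_start=start,
                    aa_end=end,
                    sequence=corf.peptide[start:end],
                    member_count=len(mem),
                    spans_bsj=any(m.peptide.sequence in yy_index for m in mem),
                )
            )
        for m in members[1:]:
            if m.aa_start < cur_end:
                cur.append(m)
                cur_end = max(cur_end, m.aa_end)
            else:
                emit(cur_start, cur_end, cur)
                cur = [m]
                cur_start, cur_end = m.aa_start, m.aa_end
        emit(cur_start, cur_end, cur)
    return merged


def ribo_evidence(
    circ: CircRecord, ribo_seqs: Iterable[str], min_flank: int = 6
) -> bool:
    """True iff any ribo-seq-derived nucleotide sequence (or its reverse
    complement) covers the BSJ of the doubled circle with at least
    ``min_flank`` nt on each side."""
    if circ.sequence is None:
        raise ValueError(f"{circ.circ_id}: no sequence")
    L = len(circ.sequence)
    doubled = circ.sequence * 2
    for raw in ribo_seqs:
        for read in (raw.upper().replace("U", "T"),):
            for probe in (read, revcomp(read)):
                for s in _find_all(probe, doubled):
                    if s <= L - min_flank and s + len(probe) >= L + min_flank:
                        return True
    return False
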