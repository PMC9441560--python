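"""Circular ORF enumeration by rolling translation.

A circRNA has no ends, so an ORF may start anywhere on the circle, run across
the back-splice junction, and wrap around ("roll") multiple laps before the
first in-frame stop.  The template trick makes this a linear scan: the circle
sequence is repeated three times and 2 extra nucleotides are appended so that
start codons straddling the junction (A^TG, AT^G) are still visible; an ORF
that finds no stop within three laps is an infinite cORF (icORF, rolling
translation) and its peptide is truncated at exactly three laps.

Candidate peptides must start with AUG-encoded Met and exceed 20 residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from Bio.Data.CodonTable import standard_dna_table

log = logging.getLogger("circpept")

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA

START_CODON = "ATG"

LAP_GROUPS = ("less than one lap", "less than two laps", "more than two laps")


def translate_codon(codon: str) -> str:
    """Standard-code translation of one codon; stops are '*', anything
    ambiguous (e.g. containing N) is 'X'.  An 'X' never equals a stop."""
    if codon in _STOP_CODONS:
        return "*"
    return _CODON_TABLE.get(codon, "X")


def translate_nt(seq: str) -> str:
    """Translate a nucleotide string codon by codon; trailing partial codon
    ignored; stops retained as '*'."""
    return "".join(
        translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - 2, 3)
    )


@dataclass(frozen=True)
class CorfConfig:
    """Enumeration parameters.

    ``repeats``/``tail_nt`` define the template (three copies + 2 nt) and are
    fixed by the method; ``min_peptide_len`` is the strict lower bound on
    candidate peptide length (retained iff length > 20).
    """

    repeats: int = 3
    tail_nt: int = 2
    min_peptide_len: int = 20
    start_codon: str = START_CODON


@dataclass(frozen=True)
class CORF:
    """A predicted circular open reading frame.

    ``start_nt`` is the 0-based start-codon offset on the circle;
    ``nt_length`` counts start codon through the last codon before the stop
    (stop excluded), so ``laps = nt_length / L`` and the peptide has
    ``nt_length / 3`` residues.  Infinite cORFs carry exactly three laps of
    peptide.  ``frame_phase = start_nt mod 3`` identifies the reading phase
    on the circle.
    """

    circ_id: str
    corf_index: int
    start_nt: int
    nt_length: int
    laps: float
    is_infinite: bool
    peptide: str
    frame_phase: int


def build_template(seq: str, cfg: CorfConfig = CorfConfig()) -> str:
    """Repeat the circle ``repeats`` times and append the first ``tail_nt``
    bases (length 3L+2 for L >= 2)."""
    if not seq:
        raise ValueError("empty circRNA sequence")
    return seq * cfg.repeats + seq[: cfg.tail_nt]


def _scan_circle(circ_id: str, seq: str, cfg: CorfConfig):
    """Yield raw (start, nt_length, is_infinite, peptide) before dedup."""
    L = len(seq)
    template = build_template(seq, cfg)
    max_nt = cfg.repeats * L  # translation budget: three laps
    # working buffer long enough to translate max_nt from any start in [0, L)
    buf = seq * (cfg.repeats + 1) + seq[: cfg.tail_nt + 2]
    for p in range(L):
        if template[p : p + 3] != cfg.start_codon:
            continue
        nt_len = None
        n_codons = max_nt // 3
        for i in range(1, n_codons):
            codon = buf[p + 3 * i : p + 3 * i + 3]
            if codon in _STOP_CODONS:
                nt_len = 3 * i
                break
        if nt_len is None:
            yield p, max_nt, True, translate_nt(buf[p : p + max_nt])
        else:
            yield p, nt_len, False, translate_nt(buf[p : p + nt_len])


def enumerate_corfs(circ_id: str, seq: str, cfg: CorfConfig = CorfConfig()) -> list[CORF]:
    """All possible longest cORFs of one circle.

    Every AUG on the circle (junction-spanning ones included) opens a
    candidate; translation runs to the first in-frame stop or, failing that
    within three laps, is marked infinite and truncated at three laps.
    Candidates sharing the same reading phase and the same stop position on
    the circle are redundant nested ORFs: only the longest (5'-most start)
    is kept.
    """
    if len(seq) < 3:
        raise ValueError(f"{circ_id}: sequence shorter than 3 nt")
    L = len(seq)
    best: dict[tuple[int, object], tuple[int, int, bool, str]] = {}
    for p, nt_len, inf, pep in _scan_circle(circ_id, seq, cfg):
        stop_key = "inf" if inf else (p + nt_len) % L
        key = (p % 3, stop_key)
        cur = best.get(key)
        if cur is None or nt_len > cur[1] or (nt_len == cur[1] and p < cur[0]):
            best[key] = (p, nt_len, inf, pep)
    ordered = sorted(best.values(), key=lambda t: (t[0], -t[1]))
    return [
        CORF(
            circ_id=circ_id,
            corf_index=i,
            start_nt=p,
            nt_length=nt_len,
            laps=nt_len / L,
            is_infinite=inf,
            peptide=pep,
            frame_phase=p % 3,
        )
        for i, (p, nt_len, inf, pep) in enumerate(ordered)
    ]


def filter_peptides(corfs: Iterable[CORF], cfg: CorfConfig = CorfConfig()) -> list[CORF]:
    """Keep candidate circRNA-derived peptides: strictly more than
    ``min_peptide_len`` residues and an AUG (Met) start; order preserved."""
    return [
        c for c in corfs
        if len(c.peptide) > cfg.min_peptide_len and c.peptide.startswith("M")
    ]


def lap_group(corf: CORF) -> str:
    """Three lap groups: <1 lap, <2 laps, and the stopless rolling group.

    Finite cORFs with laps in [2, 3) fall outside the published trichotomy;
    they are assigned to "less than two laps" with a warning.
    """
    if corf.is_infinite:
        return LAP_GROUPS[2]
    if corf.laps < 1:
        return LAP_GROUPS[0]
    if corf.laps >= 2:
        log.warning(
            "%s cORF %d: finite cORF with %.2f laps assigned to group 2",
            corf.circ_id, corf.corf_index, corf.laps,
        )
    return LAP_GROUPS[1]
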