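"""Back-splice-junction reference peptide database.

The diagnostic sequence of a circRNA is its back-splice junction (BSJ): the
joint between the 3' end and the 5' end of the circular exon sequence.  A
window of about 200 nt centred on the BSJ (k nt per side, default 100, capped
at the circle length) is translated in six reading frames; MS peptides that
match these reference peptides across the junction are the core evidence of
translation.  A decoy database of reverse-complemented circles flows through
the identical pipeline for target-decoy FDR estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .circ_input import CircRecord, CircInputError, revcomp
from .corf_engine import translate_nt

FRAMES_FWD = ("+1", "+2", "+3")
FRAMES_REV = ("-1", "-2", "-3")
DECOY_PREFIX = "DECOY_"

DEFAULT_FLANK = 100  # nt per side of the BSJ ("about 200 bp" in total)


@dataclass(frozen=True)
class JunctionWindow:
    """Nucleotide window around a BSJ.

    ``junction_nt_offset`` indexes the first nucleotide after the BSJ within
    the window, i.e. the first base of the circle's 5' end.
    """

    circ_id: str
    window: str
    junction_nt_offset: int
    half_width_k: int

    def __post_init__(self) -> None:
        if not 0 < self.junction_nt_offset < len(self.window):
            raise ValueError(f"{self.circ_id}: junction offset outside window")


@dataclass(frozen=True)
class ReferencePeptide:
    """One of six frame translations of a junction window.

    ``junction_aa_boundary`` is the residue index b such that residues [0, b)
    lie wholly before the BSJ; when the BSJ falls inside codon b,
    ``junction_splits_codon`` is true and residue b straddles the junction.
    Internal stops are kept as ``*`` (matching refuses to cross them);
    ambiguous codons translate to ``X``.
    """

    circ_id: str
    frame: str
    peptide: str
    junction_aa_boundary: int
    junction_splits_codon: bool


def junction_window(circ_id: str, seq: str, k: int = DEFAULT_FLANK) -> JunctionWindow:
    """Build the BSJ-flanking window: last k' nt of the circle + first k' nt,
    with k' = min(k, L) so short circles contribute at most one full copy per
    side."""
    if not seq:
        raise CircInputError(f"{circ_id}: empty sequence")
    if k < 1:
        raise ValueError("k must be >= 1")
    kp = min(k, len(seq))
    return JunctionWindow(
        circ_id=circ_id,
        window=seq[-kp:] + seq[:kp],
        junction_nt_offset=kp,
        half_width_k=k,
    )


def six_frame_translate(win: JunctionWindow) -> list[ReferencePeptide]:
    """Translate a junction window in all six reading frames.

    Forward frames +1/+2/+3 read the window at offsets 0/1/2; reverse frames
    -1/-2/-3 read its reverse complement, where the junction offset mirrors to
    ``len(window) - junction_nt_offset``.  For a frame at offset f with
    junction offset j, the residue boundary is floor((j - f)/3) and the codon
    is split when (j - f) mod 3 != 0.
    """
    w = win.window
    if len(w) < 3:
        raise CircInputError(f"{win.circ_id}: window shorter than 3 nt")
    out: list[ReferencePeptide] = []
    for strand_seq, frames, j in (
        (w, FRAMES_FWD, win.junction_nt_offset),
        (revcomp(w), FRAMES_REV, len(w) - win.junction_nt_offset),
    ):
        for f, frame in enumerate(frames):
            n_codons = (len(strand_seq) - f) // 3
            pep = translate_nt(strand_seq[f : f + 3 * n_codons])
            boundary = max(0, min(n_codons, (j - f) // 3))
            splits = (j - f) % 3 != 0
            out.append(
                ReferencePeptide(
                    circ_id=win.circ_id,
                    frame=frame,
                    peptide=pep,
                    junction_aa_boundary=boundary,
                    junction_splits_codon=splits,
                )
            )
    return out


def reference_peptides(
    circs: Iterable[CircRecord], k: int = DEFAULT_FLANK
) -> tuple[list[ReferencePeptide], list[str]]:
    """Six reference peptides per circRNA; per-circ failures are collected and
    skipped rather than aborting the batch."""
    refs: list[ReferencePeptide] = []
    failures: list[str] = []
    for c in circs:
        try:
            if c.sequence is None:
                raise CircInputError(f"{c.circ_id}: no sequence")
            refs.extend(six_frame_translate(junction_window(c.circ_id, c.sequence, k)))
        except (CircInputError, ValueError) as e:
            failures.append(f"{c.circ_id}: {e}")
    return refs, failures


def build_reference_db(
    circs: Sequence[CircRecord],
    k: int = DEFAULT_FLANK,
    out: str | Path | None = None,
    wrap: int = 60,
) -> tuple[list[ReferencePeptide], list[str]]:
    """Build the reference peptide FASTA plus a sidecar boundary index.

    Headers encode ``circ_id|frame|junction_aa_boundary|splits_codon``; the
    sidecar TSV (``<out>.index.tsv``) repeats those fields so downstream
    junction judgment never re-parses headers.
    """
    refs, failures = reference_peptides(circs, k)
    if out is not None:
        out = Path(out)
        with open(out, "w") as fh:
            for r in refs:
                fh.write(f">{r.circ_id}|{r.frame}|{r.junction_aa_boundary}|"
                         f"{int(r.junction_splits_codon)}\n")
                if wrap:
                    for i in range(0, len(r.peptide), wrap):
                        fh.write(r.peptide[i : i + wrap] + "\n")
                else:
                    fh.write(r.peptide + "\n")
        with open(out.with_suffix(out.suffix + ".index.tsv"), "w") as fh:
            fh.write("circ_id\tframe\tjunction_aa_boundary\tsplits_codon\n")
            for r in refs:
                fh.write(f"{r.circ_id}\t{r.frame}\t{r.junction_aa_boundary}\t"
                         f"{int(r.junction_splits_codon)}\n")
    return refs, failures


def build_decoy_db(circs: Iterable[CircRecord]) -> list[CircRecord]:
    """Reverse-complement decoys: virtual circles that do not exist in nature
    but are sequence-equivalent, id-prefixed ``DECOY_`` and fed through the
    identical pipeline."""
    decoys = []
    for c in circs:
        if c.sequence is None:
            raise CircInputError(f"{c.circ_id}: no sequence for decoy")
        cid = (c.circ_id[len(DECOY_PREFIX):] if c.circ_id.startswith(DECOY_PREFIX)
               else DECOY_PREFIX + c.circ_id)
        decoys.append(
            CircRecord(
                circ_id=cid,
                chrom=c.chrom,
                strand=c.strand,
                exon_blocks=c.exon_blocks,
                sequence=revcomp(c.sequence),
                parent_gene=c.parent_gene,
            )
        )
    return decoys
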