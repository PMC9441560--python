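"""Input handling: circRNA definitions, exon sequences, MS peptide lists, proteins.

A circRNA is described either by its exonic sequence directly (model 1), or by
genomic exon blocks to be sliced out of a genome FASTA (model 2), or by its
span on a mature transcript (model 3).  MS peptides arrive as plain one-per-line
text or as delimited search-engine exports with a peptide column.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger("circpept")

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
VALID_NT = set("ACGTN")

_MOD_RE = re.compile(r"[\(\[][^\)\]]*[\)\]]")  # (+15.99), [Oxidation] etc.


class CircInputError(ValueError):
    """Raised on malformed circRNA definitions or sequence sources."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CircRecord:
    """One circRNA: identity, genomic exon blocks, strand, circular exon sequence.

    Exon blocks are 0-based half-open genomic intervals, sorted ascending and
    non-overlapping.  ``sequence`` is the concatenated exonic sequence reading
    5'->3' on the circRNA (i.e. already reverse-complemented for minus-strand
    circles); its length equals the summed block lengths when both are present.
    """

    circ_id: str
    chrom: str = ""
    strand: str = "+"
    exon_blocks: tuple[tuple[int, int], ...] = ()
    sequence: str | None = None
    parent_gene: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise CircInputError(f"{self.circ_id}: strand must be '+' or '-'")
        blocks = tuple((int(a), int(b)) for a, b in self.exon_blocks)
        for a, b in blocks:
            if a >= b:
                raise CircInputError(f"{self.circ_id}: empty/inverted block {a}-{b}")
        for (a1, b1), (a2, b2) in zip(blocks, blocks[1:]):
            if a2 < b1:
                raise CircInputError(f"{self.circ_id}: overlapping or unsorted blocks")
        self.exon_blocks = blocks
        if self.sequence is not None:
            self.sequence = normalize_nt(self.sequence, self.circ_id)
            if blocks and len(self.sequence) != self.block_span():
                raise CircInputError(
                    f"{self.circ_id}: sequence length {len(self.sequence)} != "
                    f"summed block length {self.block_span()}"
                )

    def block_span(self) -> int:
        return sum(b - a for a, b in self.exon_blocks)

    @property
    def length(self) -> int:
        """Full circle length L (from the sequence when present, else blocks)."""
        if self.sequence is not None:
            return len(self.sequence)
        return self.block_span()


@dataclass(frozen=True)
class MSPeptide:
    """An identified MS/MS peptide sequence (search-engine output)."""

    sequence: str
    source_id: str | None = None
    engine_score: float | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise CircInputError("empty peptide sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise CircInputError(
                f"peptide {self.sequence!r}: non-standard residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """A linear protein, used to flag junction peptides explainable linearly."""

    protein_id: str
    sequence: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise CircInputError(f"{self.protein_id}: empty protein sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def normalize_nt(seq: str, label: str = "?") -> str:
    """Uppercase, map U->T, and validate the A/C/G/T/N alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_NT
    if bad:
        raise CircInputError(f"{label}: invalid nucleotide(s) {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# circRNA info file
# ---------------------------------------------------------------------------

#: Default dialect: tab-separated columns circ_id, chrom, strand, blocks where
#: blocks is "start-end,start-end,..." in the convention named by ``coords``.
DEFAULT_DIALECT: dict = {
    "circ_id": 0,
    "chrom": 1,
    "strand": 2,
    "blocks": 3,
    "sep": "\t",
    "coords": "0-based-half-open",  # or "1-based-closed" (BED-adjacent vs GTF-adjacent)
}


def _parse_blocks(text: str, coords: str, line_no: int) -> tuple[tuple[int, int], ...]:
    blocks = []
    for part in text.replace(";", ",").split(","):
        part = part.strip()
        if not part:
            continue
        m = re.fullmatch(r"(\d+)-(\d+)", part)
        if not m:
            raise CircInputError(f"line {line_no}: malformed block {part!r}")
        a, b = int(m.group(1)), int(m.group(2))
        if coords == "1-based-closed":
            a -= 1
        if a >= b:
            raise CircInputError(f"line {line_no}: coordinate start >= end in {part!r}")
        blocks.append((a, b))
    if not blocks:
        raise CircInputError(f"line {line_no}: no exon blocks")
    return tuple(sorted(blocks))


def read_circ_info(path: str | Path, dialect: Mapping | None = None) -> list[CircRecord]:
    """Parse a tab-separated circRNA info file into :class:`CircRecord` rows.

    The ``dialect`` mapping names the column index of each field, the separator,
    and the coordinate convention of the file (converted to 0-based half-open
    on read).  Raises :class:`CircInputError` with the offending line number on
    malformed coordinates and on duplicate circRNA ids.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    records: list[CircRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split(d["sep"])
            try:
                circ_id = cols[d["circ_id"]].strip()
                chrom = cols[d["chrom"]].strip()
                strand = cols[d["strand"]].strip()
                blocks_text = cols[d["blocks"]].strip()
            except IndexError:
                raise CircInputError(f"line {line_no}: expected >= 4 columns") from None
            if circ_id in seen:
                raise CircInputError(f"line {line_no}: duplicate circ_id {circ_id!r}")
            seen.add(circ_id)
            blocks = _parse_blocks(blocks_text, d["coords"], line_no)
            try:
                records.append(
                    CircRecord(circ_id=circ_id, chrom=chrom, strand=strand,
                               exon_blocks=blocks)
                )
            except CircInputError as e:
                raise CircInputError(f"line {line_no}: {e}") from None
    return records


def write_circ_info(records: Iterable[CircRecord], path: str | Path) -> None:
    """Serialize records back to the default info dialect (round-trip safe)."""
    with open(path, "w") as fh:
        for r in records:
            blocks = ",".join(f"{a}-{b}" for a, b in r.exon_blocks)
            fh.write(f"{r.circ_id}\t{r.chrom}\t{r.strand}\t{blocks}\n")


# ---------------------------------------------------------------------------
# sequence acquisition, models 1-3
# ---------------------------------------------------------------------------

def load_sequences_model1(fasta: str | Path) -> dict[str, str]:
    """Model 1: circRNA exon sequences supplied directly as FASTA.

    Headers carry circ_ids; sequences are uppercased and U is mapped to T.
    Duplicate headers and empty records are errors.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id in out:
            raise CircInputError(f"duplicate FASTA record {rec.id!r}")
        seq = str(rec.seq)
        if not seq:
            raise CircInputError(f"empty FASTA record {rec.id!r}")
        out[rec.id] = normalize_nt(seq, rec.id)
    return out


def extract_sequence_model2(circ: CircRecord, genome) -> str:
    """Model 2: slice exon blocks out of a genome and join them 5'->3'.

    ``genome`` is any mapping of chromosome name to a sliceable nucleotide
    source (a dict of strings, or a ``pyfaidx.Fasta``).  Plus-strand circles
    concatenate blocks in genomic order; minus-strand circles are
    reverse-complemented as a whole so the result reads 5'->3'.
    """
    if circ.chrom not in genome:
        raise CircInputError(f"{circ.circ_id}: chromosome {circ.chrom!r} not in genome")
    chrom_seq = genome[circ.chrom]
    chrom_len = len(chrom_seq)
    parts = []
    for a, b in circ.exon_blocks:
        if a < 0 or b > chrom_len:
            raise CircInputError(
                f"{circ.circ_id}: block {a}-{b} outside {circ.chrom} (len {chrom_len})"
            )
        parts.append(str(chrom_seq[a:b]))
    seq = normalize_nt("".join(parts), circ.circ_id)
    if circ.strand == "-":
        seq = revcomp(seq)
    return seq


@dataclass(frozen=True)
class TranscriptModel:
    """A mature mRNA sequence plus the genomic exons it was spliced from."""

    transcript_id: str
    chrom: str
    strand: str
    sequence: str
    exons: tuple[tuple[int, int], ...]  # genomic, 0-based half-open, ascending

    def genomic_to_tx(self, gpos: int) -> int | None:
        """Map a genomic coordinate to a transcript offset (plus strand only
        needs the forward cumsum; minus strand counts from the transcript 3'
        end of the genomic layout)."""
        off = 0
        for a, b in self.exons:
            if a <= gpos <= b:  # b allowed: half-open end maps to past-the-end
                fwd = off + (gpos - a)
                if self.strand == "+":
                    return fwd
                return len(self.sequence) - fwd
            off += b - a
        return None


def extract_sequence_model3(circ: CircRecord, transcripts: Sequence[TranscriptModel]) -> str:
    """Model 3: cut the circle out of a mature transcript (introns excluded).

    The circle's genomic start (first base of its first exon) and end (last
    base of its last exon) must both map inside a single transcript's exon
    map; the contiguous transcript substring between them is returned.
    Circles spanning two transcripts are rejected (no chimeric joins).
    """
    g_start = circ.exon_blocks[0][0]
    g_end = circ.exon_blocks[-1][1]
    tried = []
    for tx in transcripts:
        if tx.chrom != circ.chrom:
            continue
        tried.append(tx.transcript_id)
        t1 = tx.genomic_to_tx(g_start)
        t2 = tx.genomic_to_tx(g_end)
        if t1 is None or t2 is None:
            continue
        lo, hi = min(t1, t2), max(t1, t2)
        sub = tx.sequence[lo:hi]
        if not sub:
            continue
        return normalize_nt(sub, circ.circ_id)
    raise CircInputError(
        f"{circ.circ_id}: boundaries not found in any transcript "
        f"(tried: {', '.join(tried) or 'none'})"
    )


# ---------------------------------------------------------------------------
# MS peptide lists and proteins
# ---------------------------------------------------------------------------

def read_peptide_list(
    path: str | Path,
    dialect: str = "plain",
    column: str | int = "peptide",
) -> tuple[list[MSPeptide], int]:
    """Read identified MS peptides; returns ``(peptides, n_skipped)``.

    ``plain`` is one peptide per line; ``delimited`` is a CSV/TSV export with
    a header row and a peptide column named (or indexed) by ``column``.
    Modification annotations in parentheses/brackets are stripped; rows with
    residues outside the 20-letter alphabet are skipped with a warning.
    """
    rows: list[tuple[str, str | None]] = []
    if dialect == "plain":
        with open(path) as fh:
            rows = [(ln.strip(), None) for ln in fh if ln.strip()]
    elif dialect == "delimited":
        with open(path, newline="") as fh:
            sample = fh.read(4096)
            fh.seek(0)
            sep = "\t" if "\t" in sample.splitlines()[0] else ","
            reader = csv.reader(fh, delimiter=sep)
            header = next(reader, None)
            if header is None:
                raise CircInputError(f"{path}: empty delimited file")
            if isinstance(column, int):
                idx = column
            else:
                if column not in header:
                    raise CircInputError(f"{path}: missing column {column!r}")
                idx = header.index(column)
            for r in reader:
                if len(r) > idx and r[idx].strip():
                    rows.append((r[idx].strip(), None))
    else:
        raise CircInputError(f"unknown peptide dialect {dialect!r}")

    peptides: list[MSPeptide] = []
    skipped = 0
    for raw, src in rows:
        seq = _MOD_RE.sub("", raw).upper()
        try:
            peptides.append(MSPeptide(sequence=seq, source_id=src))
        except CircInputError:
            skipped += 1
            log.warning("skipping non-standard peptide row %r", raw)
    return peptides, skipped


def read_gtf_exons(path: str | Path):
    """Minimal GTF exon table: DataFrame with chrom, start (0-based), end,
    strand, gene_id.  Only 'exon' features are kept."""
    import pandas as pd

    rows = []
    attr_re = re.compile(r'gene_id "([^"]+)"')
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            m = attr_re.search(f[8])
            rows.append(
                dict(chrom=f[0], start=int(f[3]) - 1, end=int(f[4]),
                     strand=f[6], gene_id=m.group(1) if m else "")
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])


def gene_table_from_gtf(circs: Iterable[CircRecord], gtf_exons) -> dict[str, str]:
    """Map each circRNA to the annotated gene whose exons overlap its blocks
    the most (parental gene); circles with no overlap are omitted."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for row in gtf_exons.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end,
                                                         row.gene_id)
    table: dict[str, str] = {}
    for c in circs:
        tree = trees.get(c.chrom)
        if tree is None:
            continue
        overlap: dict[str, int] = {}
        for a, b in c.exon_blocks:
            for iv in tree.overlap(a, b):
                ov = min(b, iv.end) - max(a, iv.begin)
                overlap[iv.data] = overlap.get(iv.data, 0) + ov
        if overlap:
            table[c.circ_id] = max(sorted(overlap), key=lambda g: overlap[g])
    return table


def read_proteins(fasta: str | Path) -> list[ProteinRecord]:
    """Linear protein FASTA for the parental-gene filter."""
    out = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        out.append(ProteinRecord(protein_id=rec.id, sequence=str(rec.seq)))
    return out
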