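"""Target-decoy self-evaluation of the junction pipeline.

The decoy database holds reverse-complemented ("virtual") circles that do not
exist in nature but are statistically equivalent to real ones.  Running the
identical evidence pipeline on both and counting circles with retained
junction evidence gives FDR = decoy_calls / target_calls.  The published
benchmark condition — peptides spanning the BSJ by more than two amino
acids — corresponds to a YY threshold of 3.

A subtlety makes the cORF-mapping step essential here: the decoy's junction
window is exactly the reverse complement of the target's, so a six-frame
reference database alone matches identically on both.  What breaks the
symmetry is the requirement that a junction peptide also maps onto a
predicted cORF (AUG start, > 20 aa) of the same circle — ORF structure does
not survive reverse complementation.  A "call" therefore requires both.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .circ_input import CircRecord, MSPeptide
from .corf_engine import CorfConfig, enumerate_corfs, filter_peptides
from .junction_refdb import build_decoy_db, reference_peptides, DEFAULT_FLANK
from .peptide_evidence import dedupe_peptides, find_junction_hits, map_to_corf

BENCHMARK_MIN_YY = 3  # "span BSJs more than two amino acids"


@dataclass(frozen=True)
class FdrResult:
    """Counts of translatable-circRNA calls against the real and decoy
    databases; ``fdr`` is undefined (None) when there are no target calls."""

    target_calls: int
    decoy_calls: int
    fdr: float | None
    yy_condition: int

    @property
    def defined(self) -> bool:
        return self.fdr is not None


def count_translatable_calls(
    circs: Sequence[CircRecord],
    peptides: Sequence[MSPeptide],
    min_yy: int,
    flank: int = DEFAULT_FLANK,
    il_equivalent: bool = False,
    corf_cfg: CorfConfig = CorfConfig(),
) -> int:
    """Number of circRNAs called translatable: >= 1 peptide that both spans
    the BSJ at the YY threshold and maps onto a filtered cORF of the circle."""
    refs, _ = reference_peptides(circs, flank)
    hits = find_junction_hits(peptides, refs, min_yy=min_yy,
                              il_equivalent=il_equivalent)
    by_circ: dict[str, list] = {}
    for h in hits:
        by_circ.setdefault(h.circ_id, []).append(h.peptide)
    seq_by_id = {c.circ_id: c.sequence for c in circs}
    calls = 0
    for circ_id, peps_here in by_circ.items():
        corfs = filter_peptides(
            enumerate_corfs(circ_id, seq_by_id[circ_id], corf_cfg), corf_cfg
        )
        if any(map_to_corf(p, corfs, il_equivalent) for p in peps_here):
            calls += 1
    return calls


def run_target_decoy(
    circs: Sequence[CircRecord],
    peptides: Iterable[MSPeptide],
    min_yy: int = BENCHMARK_MIN_YY,
    flank: int = DEFAULT_FLANK,
    il_equivalent: bool = False,
) -> FdrResult:
    """Run the evidence pipeline once on targets and once on their
    reverse-complement decoys with the same peptide list; FDR =
    decoy calls / target calls."""
    peps = dedupe_peptides(list(peptides))
    if not peps:
        raise ValueError("empty peptide list")
    target_calls = count_translatable_calls(circs, peps, min_yy, flank, il_equivalent)
    decoys = build_decoy_db(circs)
    decoy_calls = count_translatable_calls(decoys, peps, min_yy, flank, il_equivalent)
    fdr = decoy_calls / target_calls if target_calls > 0 else None
    return FdrResult(
        target_calls=target_calls,
        decoy_calls=decoy_calls,
        fdr=fdr,
        yy_condition=min_yy,
    )


def write_fdr_tsv(result: FdrResult, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("target_calls\tdecoy_calls\tfdr\tyy_condition\tseed\n")
        fdr_txt = "NA" if result.fdr is None else f"{result.fdr:.6f}"
        fh.write(f"{result.target_calls}\t{result.decoy_calls}\t{fdr_txt}\t"
                 f"{result.yy_condition}\t{'' if seed is None else seed}\n")
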