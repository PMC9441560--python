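"""Per-circRNA evidence aggregation, summary tables, and SVG sketches.

The end of the pipeline: for each circRNA that kept at least one junction
peptide above the YY threshold, gather its best cORF, merged peptides, coding
score, IRES label, lap group, class, and ribo-seq flag into a CircReport;
write the deterministic summary TSV, the draw-parameter file, and two small
SVG pictures per circle (circle/spiral diagram and sequence panel).
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .circ_input import CircRecord, MSPeptide, ProteinRecord
from .corf_engine import CORF, CorfConfig, enumerate_corfs, filter_peptides, lap_group
from .junction_refdb import DEFAULT_FLANK, reference_peptides
from .peptide_evidence import (
    DEFAULT_MIN_YY,
    JunctionHit,
    MergedPeptide,
    dedupe_peptides,
    filter_linear,
    find_junction_hits,
    map_to_corf,
    merge_overlapping,
    ribo_evidence,
)
from .scoring_class import CodingModel, ScoringConfig, classify_circ, label_ires, score_corfs

log = logging.getLogger("circpept")


@dataclass
class CircReport:
    """Aggregated evidence for one predicted translatable circRNA."""

    circ_id: str
    length: int
    parent_gene: str = "unannotated"
    best_corf: CORF | None = None
    group: str = ""
    junction_hits: list[JunctionHit] = field(default_factory=list)
    merged: list[MergedPeptide] = field(default_factory=list)
    coding_score: int | None = None
    ires_score: float | None = None
    ires_label: str = "Non-IRES"
    circ_class: str = ""
    ribo_flag: bool = False

    @property
    def best_yy(self) -> int:
        return max((h.yy for h in self.junction_hits), default=0)


def annotate_parent_gene(report: CircReport, gene_table: Mapping[str, str]) -> CircReport:
    """Attach the parental-gene annotation when present, else 'unannotated'."""
    report.parent_gene = gene_table.get(report.circ_id, "unannotated")
    return report


def build_reports(
    circs: Sequence[CircRecord],
    peptides: Sequence[MSPeptide],
    proteins: Sequence[ProteinRecord] = (),
    ires_scores: Mapping[str, float] | None = None,
    coding_model: CodingModel | None = None,
    ribo_seqs: Sequence[str] = (),
    gene_table: Mapping[str, str] | None = None,
    min_yy: int = DEFAULT_MIN_YY,
    flank: int = DEFAULT_FLANK,
    corf_cfg: CorfConfig = CorfConfig(),
    scoring_cfg: ScoringConfig = ScoringConfig(),
    il_equivalent: bool = False,
) -> list[CircReport]:
    """Run the full evidence pipeline and return one report per predicted
    translatable circRNA (>= 1 retained junction hit at the YY threshold).

    Stage counts are logged so the narrowing evidence funnel is auditable.
    """
    circs = [c for c in circs if c.sequence]
    peps = dedupe_peptides(peptides)
    log.info("pipeline: %d circRNAs, %d unique peptides", len(circs), len(peps))

    refs, failures = reference_peptides(circs, flank)
    for msg in failures:
        log.warning("reference DB: %s", msg)
    hits = find_junction_hits(peps, refs, min_yy=min_yy, il_equivalent=il_equivalent)
    log.info("junction judgment: %d hits on %d circRNAs at yy>=%d",
             len(hits), len({h.circ_id for h in hits}), min_yy)
    hits, flagged = filter_linear(hits, proteins)
    log.info("linear-protein filter: %d retained, %d flagged", len(hits), len(flagged))

    by_circ: dict[str, list[JunctionHit]] = {}
    for h in hits:
        by_circ.setdefault(h.circ_id, []).append(h)

    yy_index = {h.peptide.sequence: h for h in hits}
    reports: list[CircReport] = []
    for circ in circs:
        if circ.circ_id not in by_circ:
            continue
        corfs = filter_peptides(enumerate_corfs(circ.circ_id, circ.sequence, corf_cfg),
                                corf_cfg)
        corf_hits = []
        for h in by_circ[circ.circ_id]:
            corf_hits.extend(map_to_corf(h.peptide, corfs, il_equivalent))
        if not corf_hits:
            # junction evidence that maps onto no predicted cORF is discarded
            # (ORF structure, unlike junction matching, is strand-specific)
            continue
        merged = merge_overlapping(corf_hits, corfs, yy_index)
        hit_corf_idx = {m.corf_index for m in merged}
        candidates = [c for c in corfs if c.corf_index in hit_corf_idx] or corfs
        best = max(candidates, key=lambda c: c.nt_length, default=None)

        rep = CircReport(
            circ_id=circ.circ_id,
            length=circ.length,
            best_corf=best,
            group=lap_group(best) if best else "",
            junction_hits=sorted(by_circ[circ.circ_id],
                                 key=lambda h: (-h.yy, h.peptide.sequence)),
            merged=merged,
            ribo_flag=ribo_evidence(circ, ribo_seqs) if ribo_seqs else False,
        )
        if coding_model is not None and best is not None:
            rep.coding_score = score_corfs([best], coding_model)[(best.circ_id,
                                                                  best.corf_index)]
        if ires_scores is not None and circ.circ_id in ires_scores:
            rep.ires_score = ires_scores[circ.circ_id]
        labels = label_ires({circ.circ_id: rep.ires_score or 0.0}, scoring_cfg)
        rep.ires_label = labels[circ.circ_id]
        if rep.group:
            rep.circ_class = classify_circ(rep.group, rep.ires_label)
        annotate_parent_gene(rep, gene_table or {})
        reports.append(rep)
    log.info("final: %d predicted translatable circRNAs", len(reports))
    return sorted(reports, key=lambda r: r.circ_id)


SUMMARY_COLUMNS = [
    "circ_id", "parent_gene", "length", "best_yy", "n_junction_peptides",
    "top_peptide", "merged_peptide", "corf_start", "corf_nt_length", "laps",
    "lap_group", "coding_score", "ires_score", "ires_label", "class",
    "ribo_evidence",
]


def write_summary(reports: Sequence[CircReport], out: str | Path) -> None:
    """One deterministic row per predicted translatable circRNA, sorted by
    circ_id; reruns on identical inputs are byte-identical."""
    with open(out, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for r in sorted(reports, key=lambda r: r.circ_id):
            best = r.best_corf
            longest_merged = max(r.merged, key=lambda m: (m.aa_end - m.aa_start,
                                                          m.sequence),
                                 default=None)
            row = [
                r.circ_id,
                r.parent_gene,
                str(r.length),
                str(r.best_yy),
                str(len(r.junction_hits)),
                r.junction_hits[0].peptide.sequence if r.junction_hits else "NA",
                longest_merged.sequence if longest_merged else "NA",
                str(best.start_nt) if best else "NA",
                str(best.nt_length) if best else "NA",
                f"{best.laps:.4f}" if best else "NA",
                r.group or "NA",
                "NA" if r.coding_score is None else str(r.coding_score),
                "NA" if r.ires_score is None else f"{r.ires_score:.4f}",
                r.ires_label,
                r.circ_class or "NA",
                str(int(r.ribo_flag)),
            ]
            fh.write("\t".join(row) + "\n")


def write_draw_params(reports: Sequence[CircReport], out: str | Path) -> None:
    """Visualization parameters, one line per circRNA: length, cORF
    start/length/laps, junction position (always nt 0), IRES location or NA."""
    with open(out, "w") as fh:
        fh.write("circ_id\tlength\tcorf_start\tcorf_nt_length\tlaps\t"
                 "junction_nt\tires_location\n")
        for r in sorted(reports, key=lambda r: r.circ_id):
            best = r.best_corf
            fh.write("\t".join([
                r.circ_id,
                str(r.length),
                str(best.start_nt) if best else "NA",
                str(best.nt_length) if best else "NA",
                f"{best.laps:.4f}" if best else "NA",
                "0",
                "NA",
            ]) + "\n")


def read_draw_params(path: str | Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows


# ---------------------------------------------------------------------------
# SVG sketches (plain string templates; validated as XML by the tests)
# ---------------------------------------------------------------------------

_SVG_HEAD = ('<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}" '
             'viewBox="0 0 {w} {h}">')


def _spiral_path(cx: float, cy: float, r0: float, laps: float,
                 start_frac: float, dr_per_lap: float = 12.0, step=0.02) -> str:
    """Polyline approximation of an arc that spirals outward with each lap;
    angle 0 (12 o'clock) is the junction, start_frac is the cORF start as a
    fraction of the circle."""
    pts = []
    t = 0.0
    while t <= laps + 1e-9:
        ang = 2 * math.pi * (start_frac + t) - math.pi / 2
        r = r0 + dr_per_lap * t
        pts.append(f"{cx + r * math.cos(ang):.2f},{cy + r * math.sin(ang):.2f}")
        t += step
    return "M" + " L".join(pts)


def render_svg(report: CircReport, outdir: str | Path) -> tuple[Path, Path]:
    """Write two SVG pictures for one circRNA: (1) circle with the cORF arc
    (spiralling outward when laps > 1), a junction tick and an IRES arc when
    located; (2) a sequence panel with the merged peptide highlighted."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    w = h = 360
    cx = cy = w / 2
    r = 110.0
    parts = [_SVG_HEAD.format(w=w, h=h)]
    parts.append(f'<circle cx="{cx}" cy="{cy}" r="{r}" fill="none" '
                 'stroke="#888" stroke-width="2"/>')
    parts.append(f'<line x1="{cx}" y1="{cy - r - 10}" x2="{cx}" y2="{cy - r + 10}" '
                 'stroke="#d62728" stroke-width="3"/>')  # BSJ tick at 12 o'clock
    parts.append(f'<text x="{cx + 6}" y="{cy - r - 12}" font-size="11">BSJ</text>')
    best = report.best_corf
    if best is not None and report.length:
        start_frac = best.start_nt / report.length
        d = _spiral_path(cx, cy, r + 8, best.laps, start_frac)
        parts.append(f'<path d="{d}" fill="none" stroke="#1f77b4" stroke-width="4"/>')
        parts.append(f'<text x="10" y="20" font-size="12">{report.circ_id} '
                     f'L={report.length} laps={best.laps:.2f} '
                     f'class={report.circ_class or "NA"}</text>')
    circle_path = outdir / f"{report.circ_id}.circle.svg"
    circle_path.write_text("\n".join(parts) + "\n</svg>\n")

    parts = [_SVG_HEAD.format(w=720, h=160)]
    parts.append(f'<text x="10" y="24" font-size="13">{report.circ_id} '
                 f'({report.ires_label}, yy={report.best_yy})</text>')
    pep = ""
    if report.merged:
        pep = max(report.merged, key=lambda m: m.aa_end - m.aa_start).sequence
    elif best is not None:
        pep = best.peptide
    shown = pep[:60] + ("..." if len(pep) > 60 else "")
    parts.append('<rect x="10" y="44" width="700" height="30" fill="#fde9c8"/>')
    parts.append(f'<text x="14" y="64" font-size="12" font-family="monospace">'
                 f'{shown}</text>')
    if best is not None:
        parts.append(f'<text x="10" y="110" font-size="11">cORF start '
                     f'{best.start_nt} nt, {best.nt_length} nt, '
                     f'{len(best.peptide)} aa</text>')
    seq_path = outdir / f"{report.circ_id}.sequence.svg"
    seq_path.write_text("\n".join(parts) + "\n</svg>\n")

    for p in (circle_path, seq_path):  # must parse as well-formed XML
        ET.fromstring(p.read_text())
    return circle_path, seq_path
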