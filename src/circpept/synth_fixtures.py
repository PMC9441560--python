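"""Seeded synthetic circRNAs with planted junction-spanning evidence.

Stands in for public circRNA catalogues and MS search results so every
pipeline stage and the target-decoy benchmark run self-contained.  A fraction
of circles receive a planted cORF that starts upstream of the back-splice
junction and runs across it; "true" MS peptides are sampled from those
planted peptides so they span the BSJ with a known YY value, and noise
peptides are uniform random residue strings in the typical tryptic length
range.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .circ_input import CircRecord, MSPeptide
from .corf_engine import _STOP_CODONS, translate_nt

_BASES = np.array(list("ACGT"))
_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_SENSE_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - _STOP_CODONS
)


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for the synthetic study conditions.

    Circle lengths cover the short-exonic range typical of back-spliced
    circles; planted cORF arms (codons on each side of the BSJ) guarantee the
    >20 aa candidate filter is passed and junction peptides with yy >= 3
    exist.  Noise peptide lengths 7-25 residues follow the usual tryptic
    range.
    """

    seed: int = 0
    n_circ: int = 100
    length_range: tuple[int, int] = (120, 360)
    frac_with_corf: float = 0.5
    frac_true_junction_peptides: float = 0.5
    n_noise_peptides: int = 100
    peptide_length_range: tuple[int, int] = (7, 25)
    min_arm_codons: int = 5  # codons on each side of the BSJ in planted cORFs
    icorf_fraction: float = 0.0  # fraction of planted cORFs made stopless

    def __post_init__(self) -> None:
        for frac in (self.frac_with_corf, self.frac_true_junction_peptides,
                     self.icorf_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 90:
            raise ValueError("length_range must be non-empty and >= 90 nt")
        if self.peptide_length_range[0] > self.peptide_length_range[1]:
            raise ValueError("empty peptide_length_range")


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_BASES, size=n))


def gen_circ_set(cfg: SynthConfig) -> tuple[list[CircRecord], pd.DataFrame]:
    """Random circles, a stated fraction with a planted BSJ-crossing cORF.

    Returns the records plus a ground-truth table with one row per circle:
    ``circ_id, length, has_corf, start_nt, nt_length, arm_left_aa, peptide,
    is_infinite``.  Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[CircRecord] = []
    truth_rows = []
    n_planted = round(cfg.n_circ * cfg.frac_with_corf)
    for i in range(cfg.n_circ):
        circ_id = f"synthcirc_{i:05d}"
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        plant = i < n_planted
        plant_icorf = plant and (rng.random() < cfg.icorf_fraction)
        if plant_icorf:
            L -= L % 3  # rolling cORFs need a frame-preserving circumference
        seq = _random_seq(rng, L)
        row = dict(circ_id=circ_id, length=L, has_corf=False, start_nt=-1,
                   nt_length=0, arm_left_aa=0, peptide="", is_infinite=False)
        if plant_icorf:
            # stopless circle: overwrite every codon of one phase with sense
            # codons; ATG at a junction-upstream position starts the icORF
            a = int(rng.integers(cfg.min_arm_codons, L // 6))
            start = L - 3 * a
            # body codons exclude ATG so the planted start is the unique
            # (and hence 5'-most) Met of the stopless phase
            body = [c for c in _SENSE_CODONS if c != "ATG"]
            codons = rng.choice(body, size=L // 3)
            codons[0] = "ATG"
            # place codons[0] (the ATG) at the codon slot starting nt L-3a
            lap = "".join(np.roll(codons, -a))
            seq = list(lap)
            row.update(has_corf=True, start_nt=start, nt_length=3 * L,
                       arm_left_aa=a, is_infinite=True,
                       peptide=translate_nt("".join(codons)) * 3)
        elif plant:
            # finite cORF: a codons before the BSJ, b after, then a stop
            max_total = (L - 3) // 3
            a = int(rng.integers(cfg.min_arm_codons, 13))
            b_lo = max(cfg.min_arm_codons, 22 - a)  # total > 20 aa
            b = int(rng.integers(b_lo, max(b_lo + 1, min(max_total - a, 30))))
            start = L - 3 * a
            codons = [None] * (a + b + 1)
            codons[0] = "ATG"
            for j in range(1, a + b):
                codons[j] = str(rng.choice(_SENSE_CODONS))
            codons[a + b] = str(rng.choice(sorted(_STOP_CODONS)))
            for j, codon in enumerate(codons):
                for k, base in enumerate(codon):
                    seq[(start + 3 * j + k) % L] = base
            orf_nt = "".join(codons[:-1])
            row.update(has_corf=True, start_nt=start, nt_length=3 * (a + b),
                       arm_left_aa=a, peptide=translate_nt(orf_nt))
        records.append(CircRecord(circ_id=circ_id, sequence="".join(seq)))
        row["length"] = len(records[-1].sequence)
        truth_rows.append(row)
    return records, pd.DataFrame(truth_rows)


def gen_peptides(
    circs: list[CircRecord], truth: pd.DataFrame, cfg: SynthConfig
) -> tuple[list[MSPeptide], pd.DataFrame]:
    """MS peptide list: true junction-spanning peptides sampled from planted
    cORFs (yy >= 3 by construction) plus uniform-random noise peptides.

    Returns peptides and a label table ``sequence, label, circ_id, yy``.
    A noise peptide that happens to occur in any planted cORF peptide is
    relabeled true (vanishingly rare at >= 7 residues).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    planted = truth[truth.has_corf]
    n_true = round(len(planted) * cfg.frac_true_junction_peptides)
    chosen = planted.iloc[:n_true] if n_true else planted.iloc[:0]

    peptides: list[MSPeptide] = []
    labels = []
    lo, hi = cfg.peptide_length_range
    for _, row in chosen.iterrows():
        pep_full, a = row.peptide, int(row.arm_left_aa)
        # window [s, e) around the junction residue boundary a with >= 3
        # residues on each side
        left = int(rng.integers(3, min(a, hi // 2) + 1))
        max_right = min(len(pep_full) - a, hi - left)
        right = int(rng.integers(3, max(4, max_right + 1)))
        right = min(right, max_right)
        s, e = a - left, a + right
        seq = pep_full[s:e]
        peptides.append(MSPeptide(sequence=seq, source_id=str(row.circ_id)))
        labels.append(dict(sequence=seq, label="true", circ_id=row.circ_id,
                           yy=min(left, right)))

    corf_peps = list(planted.peptide)
    for i in range(cfg.n_noise_peptides):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_AA20, size=n))
        label = "true" if any(seq in cp for cp in corf_peps) else "noise"
        peptides.append(MSPeptide(sequence=seq, source_id=f"noise_{i:05d}"))
        labels.append(dict(sequence=seq, label=label, circ_id="", yy=0))
    return peptides, pd.DataFrame(labels)


def write_fixture_files(outdir: str | Path, cfg: SynthConfig) -> dict[str, Path]:
    """Write circ FASTA, info TSV, peptide list, protein FASTA and truth
    tables for shell use; returns the path of each artefact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    circs, truth = gen_circ_set(cfg)
    peps, labels = gen_peptides(circs, truth, cfg)
    paths = {
        "circ_fasta": outdir / "circles.fa",
        "circ_info": outdir / "circles.info.tsv",
        "peptides": outdir / "peptides.txt",
        "proteins": outdir / "proteins.fa",
        "truth_circ": outdir / "truth.circles.tsv",
        "truth_pep": outdir / "truth.peptides.tsv",
    }
    with open(paths["circ_fasta"], "w") as fh:
        for c in circs:
            fh.write(f">{c.circ_id}\n{c.sequence}\n")
    with open(paths["circ_info"], "w") as fh:
        for c in circs:
            fh.write(f"{c.circ_id}\tsynthchr\t+\t0-{len(c.sequence)}\n")
    with open(paths["peptides"], "w") as fh:
        fh.writelines(p.sequence + "\n" for p in peps)
    with open(paths["proteins"], "w") as fh:  # unrelated decoys for map_gene
        rng = np.random.default_rng(cfg.seed + 2)
        for i in range(5):
            fh.write(f">synthprot_{i}\n" + "".join(rng.choice(_AA20, size=200)) + "\n")
    truth.to_csv(paths["truth_circ"], sep="\t", index=False)
    labels.to_csv(paths["truth_pep"], sep="\t", index=False)
    return paths
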