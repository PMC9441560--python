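# circpept

Predict **translatable circRNAs** from identified MS/MS peptides.

Circular RNAs (circRNAs) are covalently closed transcripts formed by
back-splicing. A small fraction of them are translated, and the only peptide
evidence that can distinguish a circRNA product from its linear host
transcript is a peptide that **spans the back-splice junction (BSJ)** — the
joint between the circle's 3' and 5' ends, a sequence that does not exist on
any linear mRNA. `circpept` takes peptide lists produced by an MS/MS search
engine (pFind, MaxQuant, Mascot exports, or plain text) and decides, circRNA
by circRNA, whether the peptides support translation.

## Method

For a circle of sequence $S$ with length $L$:

1. **Junction reference database** — the window
   $S[L-k:] \,\|\, S[:k]$ (default $k=100$, ≈200 nt total) around the BSJ is
   translated in all **six reading frames**; each reference peptide records
   the residue boundary $b$ of the junction and whether the junction splits a
   codon.
2. **Circular ORF (cORF) enumeration** — the template $S\,S\,S + S[0{:}2]$
   (three laps plus 2 nt, so start codons straddling the junction, `A^TG` and
   `AT^G`, are visible) is scanned for AUG; each ORF is translated to its
   first in-frame stop or, failing that within three laps, flagged as an
   **infinite cORF** (rolling translation) and truncated at exactly three
   laps. Candidates need >20 aa and an AUG start. `laps = nt\_length / L`.
3. **Junction judgment (YY)** — an MS peptide matching a reference peptide at
   offset $s$ with length $n$ has $\mathrm{left}=b-s$ and
   $\mathrm{right}=s+n-b$ whole residues on either side of the BSJ (a
   junction-split residue counts toward neither side);
   $YY=\min(\mathrm{left},\mathrm{right})$. A call requires both a junction
   hit at the YY threshold **and** an exact match on a predicted cORF —
   junction matching alone is symmetric under reverse complementation and
   carries no strand information.
4. **Post-processing** — overlapping junction peptides are merged into the
   longest literally-evidenced stretch; peptides that also occur in linear
   parental proteins are flagged; a Gaussian Naive Bayes model
   (composition + length + dipeptide features, 8:2 train/test split) scores
   each cORF 0/1 for coding-likeness; an IRES score table is thresholded
   strictly at 0.5 (`IRES` / `Non-IRES`); the lap group of the best cORF
   (<1 lap, <2 laps, stopless rolling) × IRES label places each circle in
   one of six classes I–VI.
5. **Target-decoy FDR** — the identical pipeline runs on reverse-complement
   decoy circles; $\mathrm{FDR} = \text{decoy calls} / \text{target calls}$.

## Worked example

Generate a synthetic data set (30 circles, some with planted BSJ-crossing
cORFs and matching tryptic peptides plus random noise peptides), then run the
pipeline:

```sh
circpept simulate --seed 5 --n-circ 30 --outdir fix
circpept build-db --sequence fix/circles.fa --decoy --out refdb.fa
circpept map-peptides --sequence fix/circles.fa --peptides fix/peptides.txt \
    --min-yy 2 --out hits.tsv
circpept evaluate-fdr --sequence fix/circles.fa --peptides fix/peptides.txt \
    --out fdr.tsv
circpept report --sequence fix/circles.fa --peptides fix/peptides.txt \
    --svg --outdir rep
```

This prints (stderr) and writes:

```
wrote 180 reference peptides (0 failures)     # 6 frames x 30 circles
8 junction hits (0 peptide rows skipped)
target=8 decoy=0 fdr=0.0000
8 translatable circRNAs -> rep
```

`hits.tsv` lists each junction-spanning peptide with its residue counts:

```
peptide             circ_id          frame  match_start  left  right  yy
LIPSGKPKSRMVSTLPV   synthcirc_00000  +2     29           4     13     4
```

`yy=4` means at least four residues of the peptide lie on each side of the
BSJ. The summary (`rep/result.summary.tsv`) adds the merged peptide, the best
cORF (start, length, laps), lap group, IRES label and class — e.g.
`synthcirc_00000` is class II: its cORF covers 0.34 laps (<1 lap) and no IRES
score was supplied. `rep/draw_circ/` holds two SVG sketches per circle
(circle/spiral diagram and sequence panel).

Python API mirrors the CLI: `circpept.build_reports(circs, peptides, ...)`,
`circpept.enumerate_corfs`, `circpept.run_target_decoy`, etc.

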