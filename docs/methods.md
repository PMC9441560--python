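# Methods

## Problem and model

A back-spliced circRNA of exonic sequence $S$ (length $L$) differs from its
linear host only at the back-splice junction (BSJ), where the 3' end of the
last exon is joined to the 5' end of the first. Peptides identified by MS/MS
can therefore attribute translation to the circle only if they cross this
junction. `circpept` formalizes that attribution as a chain of filters; each
stage is a pure function of its inputs, and the stage counts are logged so
the narrowing funnel is auditable.

## Junction reference peptides

The window is the concatenation of the last $k'$ and first $k'$ nucleotides
of the circle, $k' = \min(k, L)$ with $k = 100$ per side by default
(`--junction-flank`); the junction sits at nucleotide offset $k'$. Choice
notes: the total window is "about 200 nt" by construction; when $L < k$ the
window is the doubled circle rather than a re-centred one — doubling keeps
the junction offset independent of $L$ and never fabricates sequence beyond
one full lap per side.

The window is translated at offsets 0/1/2 of both strands (six frames).
Internal stops are kept as `*` — splitting at stops would destabilize the
junction coordinate; instead, matching can simply never cross a `*` because
MS peptides contain no stop character. Ambiguous codons (any `N`) translate
to `X`, which matches nothing and never counts as a stop. For a frame at
offset $f$ and junction offset $j$ (mirrored to $2k'-j$ on the reverse
strand), the residue boundary is $b = \lfloor (j-f)/3 \rfloor$ and the
junction splits codon $b$ when $(j-f) \bmod 3 \neq 0$. Both strands are
always translated regardless of annotated strand; strand is metadata here.

## cORF enumeration

The scan template is $SSS + S[0{:}2]$: three copies expose ORFs of up to
three laps, and the two extra bases make junction-straddling AUGs (`A^TG`,
`AT^G`) visible to a linear scan. Each AUG at a circle position $p \in
[0, L)$ is translated codon-by-codon (internally on a longer rotation
buffer) until the first in-frame stop, or until $3L$ nucleotides are
consumed, in which case the cORF is infinite (icORF) and its peptide is
truncated at exactly three laps. The stop codon is excluded from
`nt_length`, so `laps = nt_length / L` and the peptide has `nt_length / 3`
residues.

Nested AUGs in one reading phase that run to the same stop describe the same
translation product with shorter N-termini; enumeration reports one maximal
ORF per (phase, stop-position) pair, keeping the 5'-most start. For infinite
ORFs the dedup key is (phase, ∞). Note that a circle with no stop codon in a
given phase rolls forever regardless of whether $L$ is divisible by 3; the
mechanical rule (no stop within three laps ⇒ infinite) is what the
implementation and its brute-force test oracle both apply.

Candidate circRNA-derived peptides must exceed 20 residues (strict) and
start with Met; the enumerator only opens ORFs at AUG, so the start check is
a construction invariant.

## Junction judgment and YY

An exact match of an MS peptide (offset $s$, length $n$) on a reference
peptide with boundary $b$ has $b-s$ residues wholly before and $s+n-b$
wholly after the junction; when the junction splits codon $b$, residue $b$
is chimeric and is counted on neither side (the conservative choice — it
lowers YY by at most 1). A junction hit requires ≥1 whole residue on each
side; $YY = \min(\text{left}, \text{right})$. Among multiple occurrences of
the peptide on one reference the maximal-YY match is kept; across frames
of one circle the best hit is kept; hits on different circles are all
reported (multi-mapped, not arbitrated). The default reporting threshold is
$YY \geq 2$ (`--min-yy`); the target-decoy benchmark condition "more than
two amino acids" is $YY \geq 3$.

A **call** (predicted translatable circRNA) additionally requires that at
least one junction peptide occurs verbatim in a filtered cORF peptide of the
same circle. This is not redundant: the decoy junction window is exactly the
reverse complement of the target window, and six-frame translation is closed
under reverse complementation, so junction matching alone accepts targets
and decoys identically. ORF structure (AUG placement, stop positions, the
>20 aa filter) does not survive reverse complementation and is the entire
source of target/decoy discrimination.

I/L equivalence in matching is off by default (opt-in `--il-equivalent`),
since folding isoleucine/leucine enlarges the match space.

## Merging, linear filter, ribo evidence

Matches on the same cORF are merged when they share at least one residue,
iterated to a fixpoint (equivalently: interval union under strict overlap).
Disjoint-but-close peptides are *not* bridged — a merged peptide must remain
a literally evidenced substring of the cORF. Merging is idempotent. A
junction peptide that occurs exactly in any supplied linear protein is
flagged (possibly explainable by the parental gene through codon
degeneracy) and removed from the retained set. Ribo-seq support is a simple
coverage test: a supplied nucleotide sequence (or its reverse complement)
must occur in the doubled circle covering the junction with ≥6 nt on each
side (`min_flank`).

## Coding potential and classes

The coding model is Gaussian Naive Bayes on a versioned feature schema
(`comp20+loglen+dipep400/v1`): 20 amino-acid composition fractions, log
length, 400 dipeptide frequencies. Training data are user-supplied positives
(proteins, ncRNA-encoded peptides) versus randomly generated negatives; the
set is shuffled and split 8:2 stratified with a fixed seed, and the held-out
accuracy is stored on the model. Output per cORF is the hard 0/1 class. The
schema is a design choice, versioned so alternatives can be swapped without
invalidating persisted models.

IRES scoring is pluggable: a two-column TSV of precomputed scores (from any
external IRES predictor) is thresholded strictly at 0.5 — exactly 0.5 is
`Non-IRES`. `Non-IRES` circles are labeled, never dropped.

Classes: (<1 lap, IRES)→I, (<1 lap, Non-IRES)→II, (<2 laps, IRES)→III,
(<2 laps, Non-IRES)→IV, (rolling, IRES)→V, (rolling, Non-IRES)→VI. The
numbering beyond class I is a fixed package convention. Finite cORFs with
laps in [2, 3) fall outside the trichotomy and are assigned to the <2-laps
group with a warning.

## Target-decoy FDR

Decoys are reverse complements of the target circles (`DECOY_` prefix),
processed by the identical pipeline. $\mathrm{FDR} = \text{decoy calls} /
\text{target calls}$ (undefined at zero target calls). The ratio form (not
decoy/(target+decoy)) is a documented choice.

## Synthetic study conditions

The generator emulates a circRNA catalogue plus an MS search result:

- circles of 120–360 nt, uniform random sequence; 60% receive a planted cORF
  crossing the BSJ: `ATG` placed $3a$ nt upstream of the junction
  ($a \in [5, 12]$ codons), $b$ sense codons after it ($a+b \geq 22$, so the
  >20 aa filter passes), then a stop. Optionally a fraction are made
  stopless (icORFs): $L$ forced to a multiple of 3 and one whole phase
  written with non-stop, non-ATG codons so the planted start is the unique
  Met of its phase.
- "true" peptides are substrings of planted cORF peptides crossing the
  junction with ≥3 residues on each side; noise peptides are uniform random
  residues of 7–25 aa (typical tryptic lengths). A noise peptide colliding
  with a cORF substring is relabeled true; at ≥7 residues this is
  vanishingly rare.

The benchmark (500 circles, 150 true + 300 noise peptides, $YY \geq 3$) is
what `scripts/acceptance.py` recomputes; at these conditions the measured
FDR is 0 and planted recall is 1.0 — sizes chosen so the whole benchmark
runs in seconds. What this does **not** show about real data: no spectral
noise or PSM-level error (the search engine's FDR is upstream), no homology
between circles and a real proteome (the linear-protein filter is exercised
only functionally), no base-composition bias, and IRES scores are external
inputs rather than predictions, so the IRES arm is tested only as labeling
logic.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; info-file dialects declare
  their convention and are converted on read.
- Minus-strand model-2 extraction reverse-complements the concatenated
  blocks so outputs always read 5'→3'; model-3 rejects circles spanning two
  transcripts rather than fabricating chimeric joins.
- `U` is accepted and mapped to `T`; `N` is allowed and translates to `X`.
- Empty sequences, windows <3 nt, circles <3 nt, malformed coordinates and
  duplicate ids are hard errors with the offending id/line; per-circle
  failures inside batch database construction are collected and skipped.
- All outputs (summary TSV, draw parameters, FASTA, fixture files) are
  sorted deterministically and byte-identical across reruns at a fixed seed.

## Limitations

Only AUG starts are considered; cORFs rolling more than three laps are
truncated by design; the spectral search itself (and PSM rescoring) is out
of scope — the pipeline begins at identified peptide lists; GO/KEGG
enrichment of parental genes is delegated to external tooling; SVG output is
a sketch for orientation, not publication graphics.
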