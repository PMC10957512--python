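# Methods

This note records the model, the parameter choices, and the design
decisions behind `vdjannot`, in enough detail to reproduce or deliberately
change any of them.

## Coordinate model

All internal coordinates are 0-based half-open on the *working-sense*
sequence (the input, or its reverse complement when annotating the minus
strand). The CSV/GFF3 writers convert to 1-based inclusive coordinates on
the input sequence with a sense column; extracting a reported range from
the input and reverse-complementing when sense is `-` always reproduces the
reported feature sequence. Each search runs on a single working sense;
hits are never mixed across senses, and a gene is only ever called in one
sense.

## Similarity search

The external backend shells out to NCBI `blastn` (alleles as database,
assembly as query) with gap open 5, gap extend 5, mismatch penalty −1,
word size 11 for V and 7 for D/J, and e-value cutoffs 10 (V, J) and 100
(D — the wider cutoff compensates for D-REGIONs as short as 8 nt). The
internal backend is an ungapped seed-and-extend aligner honouring the same
word sizes and ±1 match/mismatch scores, with X-drop 16 and a
Karlin–Altschul-style e-value surrogate (λ = 1.28, K = 0.46). Only the
*ordering* of surrogate e-values matters downstream; absolute values are
approximate. Because the internal extension is ungapped, indel-containing
divergence between assembly and reference is better served by the external
backend; for substitution-level divergence the two agree.

Consolidation groups transitively overlapping hits (any overlap ≥ 1 nt)
per gene type and keeps the hit maximising (match fraction rounded to two
decimals, −e-value, aligned length, lexicographically earliest allele
name). The winner is extended to full allele length by offset arithmetic
on its allele interval, clamped at assembly edges with a truncation note.

## Motif model

A PWM stores per-position probabilities over A,C,G,T. Scores are natural-log
likelihoods; an N base contributes log 0.25. `build_pwm` uses
`(count + pseudocount) / (n + 4·pseudocount)` with pseudocount 0.1 by
default (avoids −∞ on unseen bases with minimal distortion). The pass
threshold is the minimum log-likelihood of the PWM's own training
sequences, so no known-good training motif is ever rejected; stricter
thresholds can be written into the motif files. Paired searches (heptamer +
spacer + nonamer and L-PART1 + intron + L-PART2) maximise the *sum* of the
two motif log-likelihoods over every placement in the search window — the
spacer contributes a placement constraint only, with tolerance 0 by default
— with ties broken toward the canonical spacer, then the leftmost
placement. Heptamer and nonamer are weighted equally.

## Search geometry (LocusConfig defaults)

| parameter | default | meaning |
|---|---|---|
| `v.spacer_length` | 23 nt | V RSS spacer |
| `v.v_end_adjust_max` | 10 nt | how far the V-REGION 3′ end may be pulled back |
| `v.rss_search_window` | 40 nt | how far beyond the match end the heptamer may start |
| `v.leader_search_window` | 500 nt | upstream span searched for L-PART1 |
| `v.l_part2_length` | 11 nt | L-PART2 length |
| `d.spacer_5/3_length` | 12 nt | D RSS spacers |
| `d.d_end_adjust_max` | 12 nt | D boundary relocation window |
| `j.spacer_length` | 23 nt | J RSS spacer |
| `j.j_end_adjust_max` | 5 nt | J 5′ boundary relocation window |
| `j.j_motif_pattern` | `TKGGGG` | IUPAC pattern for the [W/F]-G-X-G core start |
| `j.j_motif_offset` | 31 nt | expected motif start, measured from the J 3′ end |
| `j.j_motif_tolerance` | 3 nt | motif shift tolerance (in-frame shifts only) |

The V windows cover canonical leader–intron spans and heptamer-abutting
RSS geometry. `d_end_adjust_max` is one minimal spacer length: the
boundary estimate of a very short D match can be off by the order of a
motif length when a longer, lower-identity overlapping match wins
consolidation, and a ±5 window was observed (once in a 1000-implant trial)
to miss a planted RSS that ±12 recovers. The J-motif is matched only at
in-frame shifts (±3) so the motif stays in the reading frame implied by
the J 3′ end; the donor splice is the GT dinucleotide immediately after
the J-REGION with no tolerance.

An RSS is reported *absent* (with a note) when no placement fits the
window or when both motifs of the best placement score below threshold;
the V-REGION end is then left unchanged. N bases in feature windows add a
note but do not reject a candidate, since draft assemblies contain gaps.

## IMGT position transfer

The gapped reference alignment defines which alignment column each
ungapped reference base occupies (IMGT position = column // 3 + 1). A
global pairwise alignment (match 2, mismatch −1, gap open −5, extend −1)
of the candidate V-REGION to the ungapped reference carries those columns
onto the candidate. Cysteines are checked at positions 23 and 104
(codon ∈ {TGT, TGC}); stop codons are partitioned at position 104, with a
stop *at* 104 counting as "before" since it destroys the cysteine. When no
gapped reference exists the same transfer runs against the ungapped
closest allele with its own codon numbering, flagged as lower confidence.
`in_frame` means the net indel length against the closest allele is a
multiple of three.

## Classification rules

* **V** Functional ⇔ RSS heptamer and nonamer pass thresholds and match
  the consensus if defined; a leader exists whose parts pass thresholds
  and splice to a stop-free sequence in frame with the V-REGION; the
  V-REGION is in frame with Cys23 and Cys104 present and no stop before
  104. Stops strictly after 104 only add a note. Otherwise ORF when the
  V-REGION is stop-free, else pseudogene.
* **D** kept only when all four RSS motifs pass thresholds (the RSS is the
  only checkable feature); Functional when all four also match the
  consensus (if defined), else ORF. Never pseudogene: an unrearranged D
  has no reading frame of its own.
* **J** taken forward when at least one of nonamer/heptamer passes;
  Functional when both pass (and match consensus), the J-motif is found
  and the donor splice present, with stops before the motif noted but
  permitted; ORF when stop-free at/after the motif, else pseudogene.

When several leader framings exist, stop-free ATG-initiated in-frame
framings win outright; likelihood ranks within a tier. A missing motif
group contributes a −10⁶ sentinel to an annotation's joint likelihood so
comparisons in consolidation stay well defined.

## Overlap resolution

Applied uniformly across gene types on input coordinates: exact duplicates
(identical features — two candidates can relocate onto the same RSS
geometry) collapse first; all Functional annotations are retained with
mutual-overlap notes; non-functional annotations overlapping a Functional
one are discarded; each transitive group of remaining non-functionals
keeps the highest joint likelihood. Likelihood ties break toward the
longer annotation, then the allele name, then the distance to the nearer
assembly edge — a deliberately strand-symmetric key, so resolution
commutes with reverse complementation (a "leftmost" rule would not).

## Synthetic data

The generator builds miniature heavy-chain-style loci (V cluster → D
cluster → J cluster) with i.i.d. uniform intergenic sequence, 2000–6000 nt
by default (≈ 90 kb for the default 10 V + 5 D + 5 J). Motif instances are
drawn from the training sets of synthetic PWM models seeded from the
field-canonical consensus motifs (heptamer CACAGTG, nonamer ACAAAAACC,
reverse-complemented on the 5′ side of D and J) plus deterministic
single-base variants; leaders are 46 + 11 nt, ATG-initiated, and stop-free
for every training combination; V-REGIONs are copied from a 108-codon
synthetic reference family (Cys23/Trp41/Cys104 conserved, ~7 codons
mutated per allele, most alleles carrying a two-codon CDR gap in the
IMGT-style alignment); J-REGIONs (54–60 nt) embed the motif 31 nt from
their 3′ end. Engineered defects are minimal edits (≤ 3 nt, or a 1 nt
deletion for the frameshift), each dictating its classification: consensus
breaks use threshold-passing training variants so the motif *pass/consensus*
distinction is exercised, not the threshold.

What the generator does **not** emulate: sequencing error, assembly gaps in
genes, indel divergence between implant and reference, promoter elements,
pseudogene architectures other than the defect menu, and non-random
intergenic sequence (real loci contain repeats and gene relics). Passing
tests therefore demonstrate the correctness of the method's logic and
geometry, not recall on real genomic data.

## Problem sizes

The test suite and the acceptance script use 50 and 20 loci of ~90 kb for
planted recovery, 28 single-defect cases, 200 motif-search oracle
instances, 500 consolidation fuzz cases, 20/10 strand-symmetry loci, and
10 cross-reference loci (150 V+J implants at 5% reference divergence) —
sizes at which the full suite completes in a few minutes on one CPU with
the internal backend.

## Known limitations

* Directed search only: D alleles absent from the reference set are not
  discovered de novo.
* Low-coverage similarity hits in non-genic sequence are annotated and
  usually classified pseudogene; filtering them is left to the reader of
  the report (the match fraction and identity columns make them easy to
  spot).
* The internal aligner is ungapped; use the BLAST+ backend when the
  reference set is expected to differ from the assembly by indels.
* The e-value surrogate of the internal backend is calibrated for ranking,
  not for statistical interpretation.
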