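# vdjannot

Directed annotation of immunoglobulin (IG) and T cell receptor (TR) V, D,
and J genes in genomic assemblies.

Antigen-receptor loci contain many highly similar gene segments whose
usability depends not only on the core coding region but on regulatory
flanking elements: the recombination signal sequence (RSS — a conserved
heptamer, a 12 or 23 nt spacer, and a nonamer), the two leader exons
L-PART1 and L-PART2 that encode the signal peptide, the J-motif
([W/F]-G-X-G) and the donor splice site of J genes. Curating these features
by hand is slow; `vdjannot` automates it for anyone assembling or re-examining
IG/TR loci: it finds candidate genes by similarity to a germline reference
set, localises each flanking feature by position-weight-matrix (PWM)
likelihood, and classifies every gene as **Functional**, **ORF**, or
**pseudogene** from its sequence hallmarks alone.

## Method

1. **Candidate discovery.** Reference alleles are searched against the
   assembly (`blastn`, or a built-in seed-and-extend backend) with
   word size 11 for V and 7 for D/J, gap open/extend 5/5, mismatch
   penalty −1, and e-value cutoffs 10 (V, J) / 100 (D). Overlapping hits
   are consolidated to the best match per locus position — preferring
   matches covering a larger fraction of their allele, then lower e-value —
   and extended to full allele length.
2. **Feature location.** At the V 3′ end, heptamer–spacer–nonamer
   placements are scored exhaustively by joint log-likelihood
   `log P(heptamer) + log P(nonamer)` and the V-REGION end is adjusted to
   abut the best heptamer. The 5′ leader is found the same way: L-PART2 is
   the window ending at the V-REGION start behind an AG acceptor; L-PART1
   candidates are upstream windows followed by a GT donor, ranked first by
   whether the spliced leader is ATG-initiated, stop-free, and in frame
   with the V-REGION, then by joint likelihood. D genes get this treatment
   at both ends, J genes at their 5′ end plus a J-motif and donor-splice
   check.
3. **Classification.** A gene is Functional when every hallmark is intact
   (motifs pass their PWM thresholds and match the canonical consensus when
   one is defined; the leader splices cleanly; the V-REGION is in frame
   with cysteines at IMGT positions 23 and 104 and no stop before 104).
   Stops after position 104 (V) or before the J-motif (J) are permitted
   with a note, since junction formation can excise them. Otherwise the
   gene is an ORF if stop-free, else a pseudogene; D genes, having no
   reading frame of their own, are only ever Functional or ORF.
4. **Consolidation.** Functional annotations are always retained (overlaps
   noted); non-functional annotations overlapping a Functional one are
   discarded; among mutually overlapping non-functional annotations only
   the highest joint motif likelihood survives.

## Worked example

Simulate a small locus with known ground truth, then annotate it:

```bash
vdjannot simulate demo --seed 5 --n-v 2 --n-d 1 --n-j 1
vdjannot annotate demo/assembly.fasta demo/motifs \
    --v_ref demo/ref_V.fasta --d_ref demo/ref_D.fasta --j_ref demo/ref_J.fasta \
    --v_ref_gapped demo/ref_V_gapped.fasta \
    --out demo/report.csv --gff demo/report.gff3
```

```
wrote synthetic locus (23220 nt, 4 genes) to demo
9 genes annotated
```

The report (`demo/report.csv`) contains, per gene, its functionality,
1-based inclusive coordinates on the input sequence, sense, closest
reference allele, and one `start/end/seq` column triple per feature:

```
gene_type functionality  start   end sense      allele  percent_identity
        V    pseudogene    586   903     +  IGHV1-1*01            100.00
        V    Functional   4684  5181     +  IGHV1-4*01            100.00
        V    pseudogene   6896  7213     +  IGHV1-8*01             93.75
        V    Functional   7571  8104     + IGHV1-11*01            100.00
        V    pseudogene   9619  9942     + IGHV1-12*01            100.00
        D    Functional  12479 12550     +  IGHD1-4*01            100.00
        J    Functional  18387 18487     +    IGHJ6*01            100.00
        V    pseudogene  19451 19774     + IGHV1-11*01            100.00
        V    pseudogene  21428 21745     +  IGHV1-1*01            100.00
```

The four implanted genes are recovered as Functional with exact feature
coordinates (compare `demo/truth.csv`). The pseudogene rows are
low-coverage similarity matches in intergenic sequence: a directed search
annotates every location with a similarity hit, and locations lacking the
functional hallmarks are reported as pseudogene candidates rather than
silently dropped. `percent_identity` is the identity of the best
underlying similarity hit.

`vdjannot annotate --both-senses` annotates both strands; genes are always
called in a single sense and reported with a sense column.

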