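# ppredit

Design and evaluation of synthetic PLS-class PPR RNA-editing factors, and
statistical detection of C-to-U RNA editing from strand-specific RNA-seq
nucleotide counts.

Plant organellar C-to-U RNA editing is directed by pentatricopeptide repeat
(PPR) proteins: tandem arrays of ~35-amino-acid helix-turn-helix motifs in a
`(P1-L1-S1)n-P2-L2-S2-E1-E2-DYW` arrangement, where each P/L/S motif contacts
one RNA base and the amino acids at the 5th and last positions of the motif
(the "5/35 combination") determine which base is preferred — the PPR code
(e.g. TD → G, TN → A, NS → C, ND → U). The cytidine deaminated by the DYW
domain lies 4 nt 3′ of the base aligned with the S2 motif. `ppredit` is for
researchers engineering such factors and analysing their activity: it covers
consensus-based factor design, PPR-code binding prediction and genome
scanning, and the statistics of detecting (off-)target editing events in
treatment-vs-control RNA-seq.

## What it computes

**Factor design** (`ppredit.motifs`). Position-specific plurality consensus
of aligned motif collections (highest per-column residue count, no minimum
threshold; gaps never win and all-gap columns are dropped), then programming
of the consensus scaffold against a target RNA: for each contacting motif
aligned to base *b*, the (5th, last) pair is the code-table entry for
(motif type, *b*).

**Binding scoring and scanning** (`ppredit.scoring`). A scoring table maps
(5th, last, base) → score; an alignment's score is the exact sum over
contacting motifs. Genome scans (both strands, optionally circular) emit one
window per candidate site, by default anchored on windows whose predicted
edit position — S2-aligned base + 4 nt — carries a C in transcript sense.

**Editing detection** (`ppredit.counts`, `ppredit.stats`, `ppredit.detect`).
Strand-specific A/C/G/T counts per position (from SAM via pysam, or
simulated), stored in transcript sense. Every transcript-sense reference C
enters the candidate family; each candidate's 2×2 table of edited (T) /
unedited (C) counts in treatment vs control is tested with a two-sided
Fisher exact test, corrected with the Simes-Hochberg step-up procedure
across the whole family, and summarised by a pseudocounted odds ratio

    OR = ((a + 0.5)(d + 0.5)) / ((b + 0.5)(c + 0.5)),

with a site called significant when the adjusted p < α (0.05) and
ln(OR) > 2. Median-of-ratios (pseudo-reference) size factors normalise
transcript count matrices, and editing calls are projected through GFF3
gene models into codons (synonymous / nonsynonymous / intron /
UTR-intergenic).

**Synthetic data** (`ppredit.simulate`). Seeded generators for
chloroplast-like genomes with planted binding/editing sites, Poisson-depth
binomially edited count tables with uniform sequencing error, SAM read
sets, and diverged motif collections — each with a serialisable truth
record for recovery scoring.

## Worked example

`examples/detect_editing.py` simulates a 2 kb genome at 500× coverage with
one site edited at 40% in the treatment and 0% in the control (0.1%
sequencing error), then screens every candidate C:

```
screened 714 candidate C sites on both strands
significant: synth_plastid:1018 (+)  37.1% edited  ln(OR) = 6.32  p_adj = 3.36e-60
(planted site was position 1018; a call needs adjusted p < 0.05
 AND ln odds ratio > 2, so sequencing noise stays below the threshold)
```

The single planted site is recovered as the only significant call: its
observed editing fraction (37.1%) is a binomial draw around the planted 40%,
and its ln odds ratio clears the threshold while the other 713 candidates —
carrying only sequencing errors — do not. The other examples
(`design_editing_factor.py`, `scan_genome.py`, `offtarget_analysis.py`,
`normalise_transcript_counts.py`) walk through factor design, genome
scanning, the full report-bundle pipeline and count normalisation the same
way.

A thin CLI mirrors the library for shell use:
`ppredit design | scan | simulate | count | detect | normalise | annotate | run`.

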