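# Methods

This note documents the models, conventions and numerical choices behind
`ppredit`, in the spirit of a methods supplement: what is computed, under
which assumptions, and where the design was genuinely open.

## Factor model and consensus design

A PLS-class editing factor is an ordered motif array matching
`(P1-L1-S1)+ [P2-L2-S2] [E1 [E2 [DYW]]]` (the final P1-L1-S1 triplet may be
truncated so minimal test factors are representable). All six P/L/S motif
types contact exactly one RNA base, aligned one-to-one 5′→3′; E1/E2/DYW
contact none. This fixed convention is the package's interpretation of the
standard PLS architecture diagrams; alternatives (e.g. non-contacting L
motifs) can be emulated by scoring-table choice but not by changing the
alignment.

Consensus scaffolds are built per motif category (type × triplet position,
because the first, second and third P1-L1-S1 triplets of natural factors
differ subtly) by plurality with no minimum threshold: each column's most
frequent residue wins. Gaps are excluded from the counts, so a gap never
wins a column; all-gap columns are dropped. Ties are broken by the fixed
canonical one-letter amino-acid order (alphabetical). The tie rule is a
package decision — plurality consensus tools do not document theirs — and
is deterministic by construction. Raw residue counts are used rather than
scoring-matrix-weighted counts.

Design substitutes the code-table pair for each programmed motif's aligned
base into consensus positions 5 and last. Motif types listed in a
`fixed_tail` map keep the supplied residues instead (the typical use fixes
L2/S2/E1/E2 to a natural factor's residues, since the code is least certain
for those positions). The N-terminal cap is configurable; the shipped
default is `MGNS` (Met-Gly-Asn-Ser), with `MGDS` noted as an equally
defensible variant — both orderings appear in the engineering literature
and the package deliberately does not adjudicate.

The code and scoring tables are editable config files, not hard-coded
constants. The shipped defaults follow the commonly cited code
(TN→A, TD→G, ND→U, NS→C, applied uniformly to all P/L/S types) with
scoring values chosen so each code pair's preferred base scores highest;
they are package defaults for demonstration, not empirical ground truth.
Unseen (5th, last) pairs score the table's `default_score` (0, neutral)
rather than raising, since natural factors contain many unclassified
combinations. Whether L2/S2 contacts deserve a separate table is unknown;
a single table keyed purely on (5th, last, base) is used.

## Coordinates, strands and the edit-site offset

The predicted edited C lies 4 nt 3′ (transcript orientation) of the base
aligned with the S2 motif, or with the last contacting motif for factors
without S2. A scan window therefore spans `n_contacting + 4` bases for the
canonical arrangement. Internally all coordinates are 0-based half-open on
the forward strand; written reports use 1-based inclusive positions.
Minus-strand scanning reads the reverse complement, so a forward-strand G
can be a minus-strand edited C; a minus-strand window's `window_start` is
the leftmost forward-strand base it covers. Circular references (plastid
genomes) are handled by extending the sequence with its first
`window span − 1` bases before scanning and folding coordinates modulo the
length. DNA input is accepted everywhere and treated as RNA sense (T ≡ U).

## Counting and detection

Base counts are tallied per position and transcript strand from alignment
records (unmapped/secondary/supplementary skipped; indel-spanning reads
contribute nothing at the spanned positions; a base-quality floor is
configurable). Minus-strand observations are complemented so stored counts
are in transcript sense and editing is always C→T in storage. Read-strand →
transcript-strand assignment follows the library convention: `forward`
(read orientation = transcript) or `reverse` (dUTP-type kits); mate 2 is
always flipped relative to mate 1.

Candidates are all transcript-sense reference Cs on either strand with
combined C+T coverage ≥ 1 (floor configurable). Per candidate the table
(a, b; c, d) = (treat T, treat C; control T, control C) is tested with the
two-sided Fisher exact test ("probability mass ≤ observed" rule, as
implemented in scipy; a one-sided alternative is a flag away via the same
scipy call), and the whole family is corrected with Simes-Hochberg
(statsmodels `multipletests`). Effect sizes are odds ratios with a 0.5
pseudocount added to all four cells, so they are finite for any table;
logs default to base e and the significance rule is
`p_adj < α (0.05) AND ln OR > 2`. Both thresholds are configurable; the
natural-log choice for an unannotated "log" follows the convention of the
statistical stack used. Treatment sites with zero C+T coverage report a
missing (NaN) editing percentage rather than 0. Percent edited is
`100·a/(a+b)` — edited over edited-plus-unedited site-covering reads; a
denominator including reads carrying other bases would differ in the third
decimal at realistic error rates, and the package documents this choice
rather than matching any particular rounding.

Size factors use the DESeq2-style pseudo-reference: per-gene geometric mean
across samples (genes with any zero excluded), size factor = median of
count/reference ratios, fold-differences reported as log2 of normalised
ratios against a named baseline.

Effect annotation projects the C→U substitution through GFF3 CDS features
(same strand only), splicing multi-segment CDS, honouring the first
segment's phase, and translating with the standard genetic code (plastid
CDS use the standard table). Sites inside a same-strand gene but between
its CDS segments are `intron`; everything else non-coding is
`UTR/intergenic`. CDS with incomplete terminal codons are skipped with a
warning.

## Synthetic data model

The generator emulates the inputs of a chloroplast editing study at desk
scale: an i.i.d. random genome at configurable GC (default 0.36,
plastid-like), circular by default, with an optional planted factor target
whose edited C is placed at the +4 offset and whose −1 base is set to a
pyrimidine (so the optional purine-inhibition penalty never silently
affects the intended target). Coverage is Poisson per position and strand
(default mean 200; scenario scripts use 200–500), each read base is edited
with the site's efficiency (treatment and control efficiencies are
independent truth fields) and then miscalled uniformly to one of the other
three bases with the error rate (default 0.1%). The optional −1-purine
penalty multiplies efficiency at sites whose upstream base is A/G; it is
off by default because the inhibitory effect is reported qualitatively,
not quantitatively. Treatment and control use disjoint seeded substreams,
so a truth record regenerates its counts byte-identically.

What the simulation does *not* model: realistic quality profiles, PCR
duplicates, splice-aware or paired reads, transcript-abundance structure,
mapping bias, or correlated errors. Passing recovery tests therefore shows
the statistical machinery behaves as specified under binomial sampling —
not that real libraries meet those assumptions.

## Scenario sizes and numerical choices

Test and acceptance scenarios use genomes of 0.3–10 kb: a 1.4 kb genome at
GC 0.36 yields a candidate family of ≈500 C sites across both strands,
which is the family size used for the null (family-wise error) and
planted-recovery suites, with 20 seeded replicates each; the design→scan
round trip uses 10 kb. Recovery scenarios plant sites at 5–40% efficiency
at 500× coverage against a 0% control. At 500×, a 5% site yields ≈25
edited reads and a Fisher p ≈ 6×10⁻⁸, which survives Hochberg correction
across ≈500 candidates with two orders of magnitude to spare; at 200× the
same site's best attainable p (~2×10⁻³) cannot survive any genome-wide
family, which is why sensitivity claims here are always stated jointly
with coverage and family size.

Floating-point conventions: alignment totals are plain sums of per-motif
scores (no rounding); Fisher agreement with exact integer enumeration is
required to 1e-7 relative, matching the tolerance of the standard
two-sided rule's probability comparison; scan ordering is fully
deterministic (score desc, then name, coordinate, strand), as are all
generators under a fixed seed.

## Known limitations

- The shipped code/scoring tables are illustrative defaults; quantitative
  binding prediction requires an empirically derived table.
- Binding scores are additive per-motif lookups: no cooperativity, RNA
  structure or accessibility terms.
- U-to-C "reverse" editing is not called (T-position counts are still
  tallied and can be inspected).
- The Fisher/Hochberg machinery treats sites as independent; overlapping
  reads induce mild dependence that the family-wise guarantee inherits
  only approximately.
- Annotation assumes well-formed GFF3 CDS with correct phase; it does not
  repair inconsistent models.
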