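# Methods

This note documents the models and procedures implemented in `mitoremodel`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Genome records and nomenclature

All analyses operate on `AnnotatedMitogenome` records: a nucleotide sequence
over {A,C,G,T,N}, a circular/linear topology, and an ordered list of gene
features. Coordinates are 0-based half-open internally; GenBank and the
feature-table TSV are 1-based inclusive and convert at the boundary. A
feature on a circular genome may wrap the replication origin; wrapping
features are stored as a single feature with a wrap flag rather than split
in two, so every gene contributes exactly one entry to gene order.

Gene names are normalized onto one canonical vocabulary — 13 protein-coding
genes (ND1–ND6, ND4L, COX1–COX3, CYTB, ATP6, ATP8), 2 rRNAs (rrnL, rrnS) and
22 tRNAs — from the common annotation dialects ("COI", "nad4l", "16S
ribosomal RNA", "tRNA-Leu (UAA)", ...). The two leucine and two serine
isoacceptors are disambiguated by the anticodon qualifier when present, else
by an anticodon/family suffix in the name; a leucine or serine tRNA with
neither is labeled `trnL?`/`trnS?`, carried through I/O but excluded from
presence scoring and gene orders. Unknown labels are likewise carried but
excluded from gene-order and codon-usage computations, with a logged
warning. Mitochondrial CDSs frequently end on incomplete stop codons
completed by polyadenylation, so `extract_cds` trims 1–2 trailing bases to a
codon multiple; anything shorter than two codons is rejected as degenerate.

## Strand skew and regime classification

AT skew = (A − T)/(A + T) and GC skew = (G − C)/(G + C), computed exactly
from integer base counts on the stored major strand. A span missing both
bases of a pair has *undefined* skew (an error or NaN, never zero): coercing
it to zero would fabricate a sign.

Windowed profiles advance by `step` (default 50 bp) with window size
`window` (default 300 bp) along the COX1-anchored orientation, so landscapes
are comparable across species; circular genomes wrap past the origin
(⌈L/step⌉ windows), linear genomes truncate the final windows. Both
defaults are configurable — at 300/50 a window holds ~70 G+C bases at the
A+T-rich compositions typical of these genomes, enough to give the skew sign
~90% reliability at amplitude 0.15 while still resolving sub-gene-scale
structure. A per-gene skew mode is provided as an alternative resolution.

The regime classifier reduces a profile to f = the fraction of
sign-carrying windows with positive GC skew: f ≥ 0.75 → globally positive,
f ≤ 0.25 → globally negative, otherwise bimodal. The thresholds (both
flags) separate "predominantly positive", "globally negative", and
"partitioned almost equally" landscapes; under the generator's study
conditions the three regimes produce f ≈ 0.90, 0.10 and 0.53 respectively,
so the bands are wide relative to sampling noise.

## Gene order, breakpoint distance, rearranged segments

A gene order is a circular signed permutation. Orders are canonicalized for
display by rotating the anchor gene (COX1) to the front, reflecting first
(reverse the list, negate all signs) if the anchor lies on the minus strand
— reflecting rather than just rotating because strand choice on a circular
molecule is arbitrary.

Adjacencies are ordered signed pairs (a → b) identified with their
other-strand reading (−b → −a); a circular order of n genes has exactly n.
The breakpoint distance is n − |adj(A) ∩ adj(B)| (n − 1 − |∩| for linear
orders). It is a pseudometric invariant to rotation and reflection, zero iff
the orders coincide up to those symmetries, and each inversion breaks at
most two adjacencies, so k inversions give distance ≤ 2k. Signs participate
in adjacency identity by default, so a strand flip without positional change
counts as rearrangement; a strand-blind mode is exposed for the opposite
convention. Fancier rearrangement measures (inversion distance, DCJ, common
intervals) are deliberately out of scope: the breakpoint count is the
simplest standard statistic that supports the comparisons made here.

Rearranged segments against a reference are computed by cutting the circular
target at every broken adjacency (present in target, absent from reference):
the conserved arc containing the anchor is the backbone, and the maximal
runs of genes outside it are reported as rearranged. This reproduces the
natural readings of the canonical cases — a single inverted block is
reported as exactly that block, and a fully shuffled order as one segment
spanning all non-anchor genes — while remaining well-defined for arbitrary
rearrangements.

## Ancestral gene-order inference

Adjacency presence is propagated from the tips to the ingroup root by
set-valued (Fitch-style) parsimony: each internal node takes the
intersection of its children's adjacency sets when nonempty, else their
union. The tree is rooted on the outgroup tip. The root candidate set is
then assembled greedily into a single circular tour over gene ends (each
gene a head–tail segment, each adjacency an end-to-end join): adjacencies
are tried in priority order — shared with the outgroup first, then higher
ingroup support, ties broken lexicographically — skipping any join that
reuses an end or closes a premature sub-cycle. If the candidates cannot
complete the tour, the outgroup's own adjacencies supplement them and a
fallback flag is set; if a full tour still cannot be closed, reconstruction
fails with an error rather than guessing. When the outgroup genuinely
carries the ancestral arrangement and a minority of ingroup lineages are
rearranged, this procedure recovers the true ancestor exactly (verified
over seeded replicates in the tests).

## tRNA presence and clusters

The presence matrix scores each genome against the 22 canonical tRNAs;
duplicated annotations count once. Truncated tRNAs are treated as present if
annotated — truncation and post-transcriptional editing are not modeled. A
tRNA cluster is a run of ≥ 2 consecutive tRNAs (no intervening PCG or rRNA)
shared — same internal order and signs — by every genome of a group, on the
COX1-anchored orientation with reflection-equivalent readings merged.
Matching is strand-sensitive by default (clusters are written as ordered,
stranded blocks) with an ignore-strand option. Each reported cluster is
maximal and annotated with every group whose members all carry it, so
group-exclusive clusters can be read off directly.

## Codon usage

RSCU is computed from codon counts pooled over all of a genome's extracted
CDSs under NCBI translation table 5 (AGA/AGG → Ser giving an 8-codon serine
family, ATA → Met, TGA → Trp; stops TAA/TAG; 62 sense codons). Stop codons
and codons containing ambiguous bases are excluded from the RSCU input but
tallied separately; the start codon is counted as its table-5 amino acid,
avoiding fragile start-codon heuristics. Codons of unobserved amino acids
are missing, not zero. Within every observed family the values sum to the
family size (mean 1) by construction; that identity is enforced in the
tests as an exact invariant.

The log10 heatmap view masks zeros and missing cells (NaN, never −inf); it
is presentation-only. PCA runs on raw RSCU values with missing cells imputed
by the column mean, columns centered but not variance-scaled (RSCU is
already on a common within-family scale), a full deterministic SVD, and each
component's sign fixed by forcing its largest-magnitude loading positive so
outputs are reproducible run-to-run.

## The synthetic-genome generator

The generator emulates the statistical structure the analyses consume, with
every realized choice recorded as truth:

- **Architecture.** Gene content and arrangement start from a bundled
  37-gene ancestral arthropod-like template; per-genome arrangements apply a
  configurable number of random signed inversions (the anchor gene never
  moves, so generated genomes are born COX1-anchored), and configured tRNAs
  are deleted. Gene lengths are drawn within ±10% of template lengths (PCGs
  snapped to codon multiples), separated by 0–6 bp spacers plus one
  60–180 bp control-region-like spacer; genome length is emergent,
  averaging ~14.6 kb.
- **Composition.** Non-coding and RNA-gene spans are sampled base-by-base at
  the target A+T content (default 0.77) with the regime's G:C imbalance:
  +amplitude everywhere (globally positive), −amplitude (globally negative),
  or +amplitude in the first half of the genome and −amplitude in the second
  (bimodal). Coding spans are sampled codon-by-codon from the genome's codon
  profile with the whole codon distribution tilted by exp(t·(n_G − n_C)), t
  calibrated by bisection so the expected coding-strand skew matches the
  regime target (minus-strand genes are tilted oppositely so the major
  strand is consistent). Coding sequence covers ~75% of these genomes, so
  the regime must be carried by the CDS too — imposing it only on intergenic
  and RNA spans would leave windowed landscapes dominated by unskewed coding
  sequence and the regimes unrecoverable. The tilt needed at amplitude 0.15
  is mild (e^t ≈ 1.2) and acts mostly across families; within-family
  preferences, and hence the RSCU structure that distinguishes group
  profiles, are essentially preserved.
- **Codon profiles.** All profiles are A/T-rich (a per-codon weight
  r^(n_A+n_T) with r calibrated to the A+T target) and favor A/U-ending
  codons. The default (`balanced`) weights A- and U-ending codons equally
  ×2.0 and yields RSCU > 1 for A/U-ending codons in observed families; `A3`
  (×3.5 A-ending) and `U3` (×3.5 U-ending) are two distinguishable planted
  profiles for structure-recovery tests.
- **Two-family design.** `generate_two_family_dataset` draws family A (one
  shared derived inversion set, globally positive regime, a fixed 8-tRNA
  loss set leaving 14, profile A3), family B (ancestral order, bimodal
  regime, 0–4 random losses leaving 18–22, profile U3), and one
  ancestral-order outgroup with a globally negative regime, plus the groups
  table and a star tree with the outgroup.

Determinism is a contract: a given (seed, genome index) reproduces the same
genome byte-for-byte through GenBank output (record dates are pinned).

What the generator does **not** emulate: substitution processes along a
tree (genomes within a group are independent draws, not phylogenetically
correlated), tRNA truncation and editing, duplicated genes, within-genome
variation in A+T content, AT-skew structure (AT skew is a by-product of the
codon profile), and any read-level artifacts. Passing tests therefore
demonstrate the correctness and recovery properties of the analysis
machinery under these idealized conditions, not the biological accuracy of
any inference on real genomes.

## Numerical and formatting choices

Skews are exact rational arithmetic on integer counts (floating division at
the end); no pseudocounts anywhere. Report TSVs use a fixed 4-decimal
format — wider than the 2–3 decimals typical of published tables, so values
survive a round trip. Test and acceptance problem sizes (e.g. 200 genomes
per regime for recovery rates, 10,000 inversion trials for the breakpoint
bound, exhaustive signed permutations up to 5 genes) were chosen to make
sampling noise negligible relative to the margins being tested while
keeping the suite fast.

## Known limitations

Duplicated gene labels are rejected in gene orders (duplication-aware
rearrangement analysis is out of scope). The greedy tour assembly is not an
exact parsimony solver: with deeply conflicting ingroup orders and an
uninformative outgroup it can fail to close a tour, which is reported as an
error rather than resolved arbitrarily. Regime classification presumes the
window/step resolution is fine enough to sample both segments of a bimodal
landscape; pathological step/genome-length combinations could alias it.
Cumulative-skew origin-of-replication inference is intentionally absent.
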