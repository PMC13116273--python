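# mitoremodel

Comparative analysis of mitochondrial genome architecture, built for the
kind of question raised by velvet worms (Onychophora), whose two extant
families differ in strand-skew landscapes, tRNA complements and gene order
while sharing deeply conserved codon usage. The package takes annotated
mitogenomes (GenBank flat files, or FASTA plus a feature-table TSV) and
compares them along four axes:

- **Nucleotide composition and strand skew.** Whole-genome, per-gene and
  sliding-window AT skew = (A − T)/(A + T) and GC skew = (G − C)/(G + C),
  computed on a common COX1-anchored orientation, and classification of each
  genome's GC-skew landscape into a qualitative regime: *globally positive*,
  *globally negative*, or *bimodal* (the genome partitioned into positive
  and negative segments).
- **Gene-order rearrangement.** Gene orders as circular signed permutations;
  the breakpoint distance d(A, B) = n − |adj(A) ∩ adj(B)|, where adj(·) is
  the set of signed adjacencies with (a → b) identified with (−b → −a);
  localization of rearranged segments against a reference; and ancestral
  gene-order inference by adjacency parsimony over a rooted tree with an
  outgroup.
- **tRNA repertoire.** Presence/absence of the 22 canonical mitochondrial
  tRNAs (leucine split into trnL1/CUN and trnL2/UUR, serine into trnS1/AGN
  and trnS2/UCN) and detection of tRNA clusters — runs of ≥ 2 consecutive
  tRNA genes — conserved across every genome of a group.
- **Codon usage.** Relative synonymous codon usage, RSCU_j = x_j / (X_i /
  n_i) for codon j in a synonymous family of size n_i with family total X_i,
  under the invertebrate mitochondrial genetic code (NCBI table 5), plus a
  PCA of the species × codon RSCU matrix.

A synthetic-genome generator (`mitoremodel.synth`) produces annotated
~14.4–14.9 kb circular mitogenomes at ~77% A+T with configurable skew
regime, gene-order inversions, tRNA losses and codon-bias profile, and
records the ground truth of every draw — so the whole pipeline is testable
without any sequence downloads.

## Worked example

Generate a two-family study design (family A: one shared derived gene
order, globally positive GC skew, 14 tRNAs; family B: ancestral gene order,
bimodal skew, 18–22 tRNAs; plus an ancestral-order outgroup), then run the
full comparison:

```sh
mitoremodel synth --out demo_data --seed 7 --two-family --n 8
mitoremodel compare --genbank demo_data/genomes.gb \
    --groups demo_data/groups.tsv --tree demo_data/tree.nwk \
    --outgroup OUT --out demo_report
```

`demo_report/composition.tsv` then contains (abbreviated):

```
id   length_bp  gc_percent  at_skew   gc_skew   n_pcg  n_trna  n_rrna  regime
A1   13967      23.6200     0.0902    0.1622    13     14      2       globally_positive
A2   14389      22.7952     0.0800    0.1555    13     14      2       globally_positive
B1   14472      22.9616     -0.0354   -0.0063   13     19      2       bimodal
B2   14695      22.8989     -0.0385   0.0264    13     22      2       bimodal
OUT  14471      23.0185     -0.0101   -0.1636   13     22      2       globally_negative
```

Each row gives a genome's length, GC percentage, whole-genome skews, gene
counts by class, and the classified GC-skew regime — family A reads as
skew-positive and tRNA-reduced, family B as bimodal with near-complete tRNA
sets, exactly the planted design. `rearrangement.json` reports breakpoint
distance 0 between every family-B genome and the inferred ancestor (their
order *is* ancestral) and a shared distance of 5 for family A, with the
displaced block localized to one segment
(`ND1-ND5-ND2-ND4(−)-ND4L(−)-ND6-CYTB` for this seed).
`trna_clusters.json` lists conserved tRNA runs per family (e.g.
`trnK-trnD` in family A), and `pca_scores.tsv` /
`explained_variance.tsv` show the two families' codon-bias profiles
separated on PC1, which carries 93.7% of the RSCU variance in this run.

The same analyses are available as library functions
(`sliding_window_profile`, `breakpoint_distance`, `infer_ancestral_order`,
`presence_matrix`, `shared_clusters`, `rscu_matrix`, `rscu_pca`, ...); see
the module docstrings and `docs/methods.md`.

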