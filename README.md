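# regulonkit

Comparative-genomics reconstruction of bacterial transcriptional
regulons: ortholog clustering, symmetry-constrained EM motif discovery,
PWM scanning with a training-set-minimum threshold, and cross-genome
consistency filtering — with a seeded synthetic-genome generator that
plants regulons and ground truth for end-to-end benchmarking.

## Who this is for

A *regulon* is the set of operons directly controlled by one
transcription factor (TF) in one genome; the union of a genome's
regulons is its transcriptional regulatory network (TRN).  When a TF
binds a conserved operator motif, regulons can be reconstructed across a
collection of related genomes without new experiments: known binding
sites seed a motif model, every upstream region is scanned, and a
candidate site is trusted only when orthologous operons in several
genomes carry sites for the same TF.  regulonkit packages that workflow
— the approach behind the reference regulon collections for lactic acid
bacteria and other Firmicutes — as a tested Python library for people
who study bacterial gene regulation or who need a transparent baseline
TRN-inference pipeline with planted-truth benchmarks.

## The method

**Orthologs.**  All-vs-all affine-gap Smith–Waterman (BLOSUM62, gap
open 11 / extend 1).  Genes *a*, *b* in different genomes form a
bidirectional best hit (BBH) when each is the other's best-scoring hit,
identity exceeds 50%, and the aligned region covers more than 2/3 of the
shorter protein.  Same-genome paralogs more similar to a member than
that member is to its BBH partner join the cluster, and clusters sharing
genes are merged transitively.  Groups are classed per lineage as
universal (all genomes), conserved (more than half), sporadic (2 to
half), or unique.

**Motifs.**  A binding motif is a position weight matrix (PWM) with
log-odds scoring, `score(w) = Σ_i log2 f_i(w_i) / b(w_i)`, against an
order-0 background estimated from the scanned upstream regions.  Most
bacterial TFs bind as homodimers, so discovery constrains the matrix to
a symmetry class (palindrome, direct or inverted repeat) inside a ZOOPS
expectation–maximization loop: each region holds at most one site on
either strand; the M-step pools expected counts over
symmetry-equivalent cells, which keeps the penalized likelihood
monotone.  The width (and repeat spacer) is chosen by the penalized
marginal likelihood across a search range.

**Scanning and thresholds.**  A profile's detection threshold is the
lowest score observed in its own training sites, so every known site is
recovered by construction and detection extends exactly as far as the
weakest validated member.

**Reconstruction workflows.**  (1a) known regulon with known sites:
build the profile, scan all genomes carrying the TF, add confidently
scoring novel sites to the training set, rebuild the PWM once and
rescan; (1b) known genes, unknown sites: discover the motif in the
pooled upstream regions of the genes and their orthologs, then as 1a;
(2) regulon known only outside the collection: map its genes in through
an ortholog table, then as 1b; (3) ab initio: candidate co-regulated
genes from conserved gene neighborhoods around the TF.  In every case a
candidate interaction is accepted only with orthologous support in at
least `min_support` genomes (default 3) or an explicit
functional-relatedness whitelist entry.

**Comparative layer.**  TF census per family and lineage, motif
conservation categories (I: ≤1 mismatch at high-information positions,
II: 2–4, III: ≥5 or not alignable), regulon-content classes (strictly
conserved / core-plus-periphery / different), local vs global regulons
(fewer vs at least 3 target operons per genome), and non-orthologous
displacement pairs with presence complementarity.

## Worked example

`examples/04_reconstruct_regulon.py` simulates 10 genomes with 3
planted 18-bp palindromic regulons (presence probability 0.8 per member
operon, one near-threshold decoy site per upstream region), seeds each
regulon with the planted sites of three genomes, and reconstructs:

```
genomes: 10   regulons reconstructed: 3
planted interactions: 250   predicted: 266
precision: 0.906  (before consistency filter: 0.791)
recall:    0.964
F1:        0.934
site position-match rate (+-3 bp): 0.956
autoregulated TF fraction: 0.70 (planted 0.73)
TF->TF cascade edges: [('R1', 'R2'), ('R1', 'R3')] (planted [('R1', 'R2')])
```

Reading the numbers: of 266 predicted TF→operon interactions, 90.6%
are planted truth (the consistency filter lifted precision from 79.1%
by discarding decoys and stray hits without orthologous support), and
96.4% of the planted interactions were found, with 95.6% of sites
placed within 3 bp of the planted position.  The extra cascade edge
(R1, R3) is real: a planted R1 site falls in an intergenic region shared
with R3's divergently transcribed TF operon.

The other examples cover simulation (`01`), motif discovery (`02` — the
planted consensus `TGGTGTTAATTAACACCA` is recovered letter-for-letter
at per-column correlation 0.995), ortholog clustering (`03` — planted
families recovered exactly at the 60% identity target), and the
cross-lineage comparisons (`05`).

A thin CLI mirrors the library:
`regulonkit simulate|orthologs|discover|scan|infer|report|evaluate`.

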