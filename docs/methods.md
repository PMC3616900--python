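# Methods

This note records the models, conventions and numerical choices behind
regulonkit, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates, operons, upstream regions

Gene coordinates are 1-based inclusive (GFF3 convention).  Operons are
maximal runs of same-replicon, same-strand adjacent genes with
intergenic gaps of at most `max_intergenic_gap` (default 100 bp, the
standard bacterial heuristic).  Upstream regions are reported on the
coding strand in a window of 300 bp upstream to 25 bp downstream of the
lead gene's translation start — wide enough for bacterial
promoter/operator space while limiting false positives — and are
truncated by default at the 3' boundary of the nearest upstream gene so
neighbouring coding sequence is never scanned.  Divergently transcribed
operons that share an intergenic region each receive the full shared
region, independently.  Only operon lead genes are analyzed; internal
operon genes inherit their operon's regulation.

## Ortholog clustering

Pairwise alignment is local affine-gap Smith–Waterman with BLOSUM62
(gap open 11, extend 1) via `Bio.Align.PairwiseAligner`.  `aligned_length`
counts residue-residue columns only (gaps excluded); identity is
identical pairs over aligned columns.  The BBH thresholds (identity
strictly above 0.50, aligned region strictly longer than 2/3 of the
shorter protein) are read literally.  Paralog attachment compares on
alignment score with identity as tie-break, is applied once per BBH
pair before transitive merging, and best-hit ties break to the
lexicographically smallest gene id so results are deterministic.

Two engineering layers keep all-vs-all tractable without changing the
rules: a k-mer prescreen (pairs sharing fewer than two distinct 5-mers
are never aligned; unrelated proteins essentially never share two,
while 50%-identity homologs share many) and a reporting floor (identity
≥ 0.30, coverage ≥ 1/3, score ≥ 75).  The floor was calibrated on a
seeded null of 1000 random protein pairs: the maximum null score
observed was 72, while homologs at the benchmark identities score
several-fold higher.  An adapter ingests 12-column tabular hits from an
external aligner when one is preferred.

## PWMs and scoring

A PWM stores raw counts; frequencies use background-proportional
pseudocounts, `f = (counts + 4·pc·b) / (n + 4·pc)`, which reduces to
Laplace smoothing (pc per cell) under a uniform background.  Scores are
log-odds base 2 against an order-0 background estimated from the pooled
upstream regions being scanned.  Backgrounds are counted on both
strands, so they are complement-symmetric; this both reflects
double-stranded scanning and makes a palindromic PWM exactly equal to
its reverse complement after smoothing.  Scanning reports the best
strand per position; reverse-strand scores are summed in the column
order of the reverse-complemented word, so an independent
position-by-position rescoring loop reproduces them bit for bit.

Reconstruction profiles scale the pseudocount as `0.25·√n` for n
training sites.  The motivation is the threshold rule below: with small
curated training sets and tiny pseudocounts, the log-frequency of a
rare base can be off by several bits, and the minimum-of-training
threshold inherits that full sampling noise, which lets near-threshold
false sites through.  √n-scaled smoothing shrinks all scores toward the
mean roughly uniformly (rank-preserving) while sharply reducing their
variance, and washes out automatically as the training set grows.

## Threshold and symmetry conventions

A profile's threshold is the lowest score observed in its training set;
every training site is therefore recovered when its own region is
scanned, and adding a weaker validated site lowers the threshold
monotonically.

Symmetry is enforced by projecting count matrices onto the symmetry
class: palindromes average the matrix with its reverse complement;
direct and inverted repeats average two equal-width half-sites, with an
explicit 0–4 bp spacer whose columns are held at background.  The
projection pools counts over symmetry-equivalent cells, which is the
constrained maximum-(penalized-)likelihood estimate — so using it as
the EM M-step preserves the monotonicity guarantee exactly.

## Motif discovery (EM)

The site model is ZOOPS: each region carries at most one site, on
either strand, with prior probability γ = 0.8 and uniform position;
otherwise the region is pure background.  The E-step computes exact
posteriors over (position, strand, no-site); the M-step re-estimates
the symmetric-projected frequency matrix with the Dirichlet
(pseudocount) prior.  The tracked objective is the observed-data
penalized log-likelihood, asserted non-decreasing at every iteration
with tolerance 1e-8.  Convergence: relative change below 1e-6 or 500
iterations.  Initialization seeds the matrix from a random data word
(k-mer seeding) per restart; 20 restarts by default, all randomness
from one seeded generator.

Model selection across widths (default 14–24 by 2; spacers 0–4 for
repeats) maximizes the penalized marginal log-likelihood, which is
comparable across widths because motif columns are scored relative to
background over whole regions and the prior charges uninformative
columns.  Raw total information content was rejected as the selection
objective: it grows monotonically with width, so the widest candidate
always wins even when the extra columns carry only overfit noise.
Ties break to the smallest width, then the lowest restart index.

## Workflows and the consistency filter

Workflow 1a scans with the training profile, accepts
consistency-filtered hits, promotes only *confidently scoring* novel
sites — score at or above the training-set median — into the training
set, rebuilds the PWM once, and rescans.  The median bar stands in for
the expert curation of "true positive" additions in the manual
workflow: without it, borderline hits (decoys included) feed back into
the profile, dilute its information content, drag the minimum-training
threshold down, and admit more junk in the rescan.  Borderline hits
remain candidate interactions; they are only barred from redefining the
profile.  The PWM is rebuilt once, not iterated, to avoid motif drift.

A candidate interaction (genome, operon) passes the consistency filter
when the operon's lead gene belongs to an ortholog group whose members'
operons carry above-threshold sites in at least `min_support` genomes
(default 3, exposed), or the lead gene is on a user-supplied
functional-relatedness whitelist.  Support counts orthologous *targets*
with any above-threshold site; position-conserved ("footprinted") sites
are not required, since operator positions drift.  Separate profiles
are built per lineage when lineages are analyzed separately.

Network analyses read directly off accepted interactions:
autoregulation (a site upstream of the TF's own operon; genomes without
the TF are excluded from the fraction), cascades (TF A targets an
operon containing TF B's gene; self-edges excluded), co-regulation
(operons with accepted sites of ≥2 TFs, tagged double/triple/...).

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
deterministically from (config, seed):

- **Families and proteins** — one ancestral gene order shared by all
  genomes; random ancestor proteins (150–400 aa) copied per genome with
  substitution probability `q = 1 − √t` so two copies have expected
  identity `t` (default 0.60).  Optional terminal truncations exercise
  the coverage rule; indels are off.  Filler families drop out of a
  genome with probability 1 − `family_presence` (default 0.9); TF and
  regulon-member families are always present.
- **Layout** — operon blocks of 1–3 genes with one strand per block,
  short intra-operon gaps (5–60 bp) and long inter-operon gaps
  (150–350 bp), so operon prediction at the 100 bp default reproduces
  the blocks exactly.  Background is order-0 with per-genome GC drawn
  from [0.35, 0.45]; one replicon per genome.
- **Planted regulons** — each regulon gets a synthetic PWM built from a
  random (palindromized) consensus whose per-column consensus weight is
  solved numerically to hit the configured total information content
  (default 18 bp, 16 bits).  The PWM's background is the mean genome
  composition, so generator-side scores and scanner-side scores mean
  the same thing.  Sites are sampled from the PWM **conditioned on
  scoring at least half its information content** — functional sites
  are selected for binding, and unconditioned draws have a heavy
  non-functional tail that would make the minimum-of-training threshold
  meaninglessly low.  Sites are planted in the upstream gap of member
  operons with the configured presence probability, clear of coding
  sequence and inside the default window.  A site falling in the gap
  shared by divergently transcribed operons is recorded as truth for
  both flanking operons, since both upstream regions contain it and a
  dyad-symmetric site there is accessible to either promoter.
- **Autoregulation and cascades** — an autoregulatory site is planted
  upstream of the TF's own operon with probability 0.72 per genome (the
  observed autoregulated fraction in reference reconstructions of this
  clade); cascade edges plant regulator A's site upstream of regulator
  B's operon.
- **Decoys** — `decoy_rate` (default 1 per upstream region) background
  words whose score under the planted profile lies in
  [threshold − 2, threshold), where the threshold is the minimum
  planted-site score; each decoy is built by random-walking point
  mutations toward a target drawn uniformly inside the band, so decoys
  spread over the whole band rather than hugging its top.  Planted-site
  scores strictly dominate decoy scores by construction.

What passing benchmarks on this generator shows: the pipeline's rules
are implemented correctly and are robust to near-threshold confounders
and 20% missing members at desk scale.  What it does not show:
performance on real genomes, where operon predictions err, motifs
deviate from their symmetry class, backgrounds are not order-0,
training sets carry curation errors, and regulons overlap heavily.

## Benchmarks and problem sizes

The standard regulon benchmark uses 10 genomes, 3 planted regulons,
presence 0.8, one decoy per region, training sites taken from 3
genomes, `min_support` 3, over 10 seeds; the motif benchmark uses 20
regions × 200 bp with one planted 18-bp, 16-bit palindromic site each
and 20 EM restarts.  The acceptance script runs the motif benchmark
with the width search restricted to 16–20; the full 14–24 search
selects the same width and motif on test instances and only multiplies
runtime.  Both finish in minutes on one CPU.

## Evaluation conventions

Interactions are (regulon, genome, operon) triples; truth regulons map
to reconstructed models through the ortholog group containing the
planted TF gene.  Precision with an empty prediction set is reported as
0 with an explicit flag.  Site recovery counts planted sites with a
predicted site of the same triple within ±3 bp.  Motif recovery is the
mean per-column Pearson correlation of frequency vectors at the best
gapless alignment (offsets ≤3, both orientations).

## Known limitations

- Operons and upstream windows are heuristic; there is no
  transcription-start or promoter-element model.
- The EM considers one motif per profile; no multi-motif or dinucleotide
  models, and no analytic p-values for scan scores.
- The paralog rule is applied once, before merging; iterating it after
  merges could attach additional paralogs.
- Workflow 3's neighborhood heuristic requires the TF's neighbors to be
  clustered; TFs regulating only distant targets need workflows 1–2.
- The displacement analysis reports complementarity but does not decide
  displacement vs redundancy; that judgement is left to the reader, as
  is pathway ("subsystem") assignment, which is an input.
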