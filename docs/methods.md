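# Methods

`sigmotif` re-implements, as a tested pipeline on synthetic data, the
analysis that asks whether prognostic cancer gene signatures — gene
lists that rarely share members — share *regulatory* structure: common
promoter motifs and common regulating miRNAs.

## The pipeline

For each gene signature (GS) the pipeline takes 1.5 kb repeat-masked
promoter sequences (lowercase/N = masked, never unmasked), discovers
motifs de novo, and then works per cancer type:

1. **Discovery** — per-GS de novo motifs and co-occurring motif
   combinations (below).
2. **Similarity grouping** — motifs from different GSs of one cancer
   type are joined when their PWM comparison E-value is strictly below
   1e-8; groups are the connected components of this graph (edges are
   only drawn between different GSs).
3. **Shared-motif calling** — a group is a shared motif when it spans
   strictly more than 50% of the type's GSs (for six GSs: at least
   four).  The representative is the member best matching a known-motif
   database; a match is an annotation when its E-value is below 1e-5.
   Unannotated shared motifs are retained but flagged, and downstream
   stages consume annotated ones by default.
4. **Target scanning** — every promoter in the scanned universe, both
   strands, is scored with the representative PWM using the max-min
   normalized segment score
   `sum_i(m[i, s_i] - min_j m[i, j]) / sum_i(max_j m[i, j] - min_j m[i, j])`
   (nucleotide order A, C, G, T; uniform columns contribute zero to
   both sums; windows containing masked bases are skipped).  A gene is
   a target when some window scores strictly above 0.9.  A motif
   combination's targets are the intersection of its members' targets.
5. **Enrichment** — combination targets vs cancer-related gene sets by
   the exact binomial upper tail (baseline = set size over universe
   size), with a random-gene-group control; motif targets within each
   GS vs per-miRNA target sets by the exact hypergeometric upper tail.
   No multiple-testing correction enters any call (raw 0.05/0.01
   thresholds follow the study design); Benjamini–Hochberg q-values are
   reported alongside for transparency.
6. **Common miRNAs** — a miRNA regulates a GS when its target set
   overlaps (p < 0.05) the targets of strictly more than half of the
   GS's shared motifs; it is a common regulator of a cancer type when
   it regulates every GS of that type.
7. **Permutation control** — every promoter is independently
   nucleotide-shuffled (composition preserved) and discovery plus
   shared-motif calling re-run; shared motifs on shuffled input measure
   the pipeline's false-positive behaviour.

## De novo discovery

The finder is this package's own construction (transparent and
exhaustively testable rather than a wrapper around an external binary).
Its statistical core is cross-fitting: patterns are *learned* on one
part of the data and *tested* on another, so the reported significance
is not inflated by the search.

* **Seeding.** All unmasked k-mers (k ∈ {8, 9, 10, 12} by default, both
  strands) are enumerated.  Candidate seeds are Hamming-radius-1 ball
  counts screened against an order-2 Markov background fitted on the
  input (binomial tail on ball sequence support; per-length quotas keep
  short noisy words from crowding longer seeds), plus random-projection
  collision buckets (windows hashed on 8 random columns; sites of a
  diffuse motif collide even when no two share an exact word).
* **Refinement.** Every seed is refined at one common width
  k_eval = max(k) + 2 — wide enough that a one-column phase drift keeps
  all informative columns inside the window — by hybrid ZOOPS EM on the
  training folds: two hard rounds (best window per sequence above a
  permissive exact threshold) lock a sharp pattern, soft rounds with
  posterior weights broaden the site set, and a double hard
  re-estimation snaps the final matrix to concrete sites.
* **Testing.** The sequences are split into four folds; each rotation
  trains on three and is evaluated on the held-out fold, where the
  statistic is the sum of per-sequence best-window log-likelihood
  ratios.  Its null distribution is computed exactly: the single-window
  LLR distribution by dynamic programming over PWM columns (order-0
  composition background), the per-sequence maximum as F(x)^n (windows
  treated as independent — conservative, since overlapping windows are
  positively correlated), and the sum by convolution with mass rounded
  upward.  Candidates from different rotations are grouped around
  anchors by PWM similarity (train-side information only) and the
  grouped folds give one convolution p-value.  A motif is reported at
  p ≤ 1e-4 (the per-motif enrichment threshold) with sequence support
  at least s = max(2, ceil(0.05·T)).  Reported PWMs are re-estimated
  from all full-data occurrences with pseudocount 0.25 per cell and
  trimmed of flank columns under 0.15 bits.
* **Combinations.** Motif pairs (and triples) whose joint sequence
  support reaches s and whose overlap passes an exact hypergeometric
  test at 1e-3 are reported as co-occurring motif groups.

Measured behaviour on shuffled inputs: one motif in twelve permuted
40-promoter runs (≈ 0.08 expected false motifs per run), and no shared
motif in any permuted study replicate, because a false shared motif
would need coincident false discoveries in four signatures.

## PWM similarity

Two PWMs are aligned over every ungapped offset with at least
max(6, 0.75·min(k_a, k_b)) overlapping columns, in both orientations.
Each aligned column pair contributes its Pearson correlation; the
reported score is the mean correlation of the best alignment, and the
test statistic is the sum of Fisher-z-transformed correlations, which
accumulates evidence across columns instead of averaging it away.
Correlations are capped at |r| = 0.98 before the transform: sharp
columns sharing a dominant base reach |r| ≈ 1 by chance, and an
uncapped transform would let a few such columns dominate.

E-values come from a Gaussian fitted to the best-alignment statistics
of 2000 seeded random PWM pairs per length pair (Dirichlet(0.45)
columns; fitted by median and 99th percentile because the
best-over-alignments statistic is right-skewed), times the number of
candidate alignments.  The thresholds default to 1e-8 (within-study
similar motifs) and 1e-5 (known-motif annotation).  This E-value scale
is internal to the package's calibration and is not comparable to any
other motif-comparison tool; measured operating characteristics:
independent 15- and 30-site re-estimates of one planted matrix fall
below 1e-8 in 20/20 seeded draws, unrelated homogeneous IC-1.3 pairs
fall below 1e-3 in ~0.5% of draws and below 1e-5 essentially never.

## Synthetic studies

The generator emulates the study design end to end: cancer types with
5–7 signatures of 30–80 genes, pairwise overlap capped at one gene;
1.5 kb order-0 background promoters at GC 0.45 with lowercase masked
runs (~5%); one planted PWM per study (length 12, per-column
information content within 0.1 bit of the target, default 1.3
bits/column) inserted once per carrying promoter at rate 0.6 on a
random strand; a known-motif database of 30-site re-estimates of the
planted matrices among random decoys; cancer gene sets with odds-θ
enrichment for true targets; and per-miRNA target sets where one
designated miRNA per cancer type covers the true targets at rate ρ
(default 0.5) and other genes at a background rate (generator default
0.3; the validation experiments use 0.1).

Design choices worth knowing:

* Every signature carries the planted motif by default.  The designated
  common miRNA must overlap motif targets in *every* signature, which
  is impossible when some signatures carry no sites at all;
  majority-carrier designs (e.g. 4 of 6) are configured explicitly and
  are exactly what the recovery benchmark uses.
* Per-column IC targeting (not just matrix-mean): matrices whose
  columns range from 0.5 to 2 bits make planted sites mutually 3–4
  mismatches apart and are a different, much harder benchmark than a
  fixed-IC motif.
* One site per carrying promoter; shared genes (across signatures)
  share one promoter, so signature promoter sets are views of the
  genome-wide universe.
* What the generator does **not** emulate: genomic base composition
  beyond order-0, real repeat families, correlated gene membership, or
  realistic motif databases.  Passing tests demonstrate the statistics
  of the method under its own assumptions, not false-positive rates on
  real genomic sequence.

## Validation experiments and their sizes

`scripts/acceptance.py` and `tests/test_acceptance.py` regenerate every
input and recompute:

* the worked shared-motif rule (six signatures → four);
* scanning vs an exhaustive per-window oracle (100 seeded PWM/1.5 kb
  pairs) and the exact test tails vs enumeration (universes ≤ 20,
  relative error ≤ 1e-12);
* planted recovery: 6 GSs × 40 promoters × 1.5 kb, IC 1.3, planted in
  4 of 6 signatures at rate 0.6 — the pipeline must call a shared motif
  similar (E < 1e-8) to the planted PWM, and call none in a
  plant-rate-0 twin.  Run at 10 seeds (plus 5 twins) to fit a single
  CPU.  Measured across 28 development seeds the per-seed recovery
  rate is roughly 0.8–0.9 (e.g. 11/12 on one contiguous block, 4/8 and
  8/10 on two strided sets), so this experiment operates at the 90%
  bound itself and individual runs land on either side; twins are
  uniformly clean;
* permutation control at 6–8 study replicates (shared-motif rate ≤ 0.05);
* null calibration of the miRNA overlap test: a study whose miRNA sets
  are drawn independently of the motif's targets, with the motif's
  genome-wide target set tested against ≥ 2000 independent miRNA sets
  over the scanned universe — sizes at which the discrete test's
  attainable levels are dense (measured fraction below 0.05 ≈
  0.032–0.040).  Signature-restricted tests (the configurable default
  universe) are markedly conservative at 40–80-gene signatures
  (attained level ≈ 0.028), which is why the calibration and recovery
  experiments use the scanned universe;
* designated-miRNA recovery at ρ = 0.5 versus background ρ, 12 seeds
  each, using the planted PWM's scanned targets (discovery quality is
  the recovery experiment's subject, not this one's): 6 GSs × 80 genes,
  1200-gene universe, IC 1.6.

## Numerical choices and edge cases

* Coordinates are 0-based half-open; the coordinate table stores
  translational starts; promoters truncated at chromosome edges are
  kept unpadded.
* Strict inequalities throughout: similarity E < 1e-8 and < 1e-5,
  segment score > 0.9, miRNA p < 0.05, "more than 50%" everywhere.
* `s = max(2, ceil(0.05 T))`, rounding by ceiling; support counts
  sequences, not occurrences.
* An all-uniform PWM has no defined segment score and is rejected; a
  uniform column contributes zero to both numerator and denominator.
* The scan cutoff 0.9 admits roughly one mismatch from the consensus
  for near-consensus matrices; for a pure-consensus matrix of length
  k ≤ 10 a single mismatch scores (k−1)/k ≤ 0.9, so the one-mismatch
  reading holds only for estimated, non-degenerate matrices.  Measured
  on planted IC-1.3 12-mers: ~57% of sampled sites clear 0.9 under the
  true matrix.
* Seeds: every stochastic component takes an explicit seed; study
  generation, discovery, and the whole pipeline are byte-reproducible
  given the seed.

## Known limitations

* The discovery stand-in reports honest cross-fitted p-values; its
  power at the recovery benchmark's conditions is roughly 85–90% per
  study seed, slightly below the ≥ 90%-of-seeds recovery bound, so the
  recovery experiment is expected to fail on a substantial fraction of
  seed draws.  Oracle scoring (the true matrix, or a matrix estimated
  from the true sites) passes the same test with orders of magnitude to
  spare in most failing instances: the remaining gap is the search, not
  the statistics.
* The similarity E-value is package-internal; do not compare its scale
  with other tools' E-values.
* The binomial enrichment uses all scanned genes as the universe
  (unrestricted); restricting to the annotated subset would change p
  by the universe ratio.
* Signature-universe miRNA testing at small signatures is conservative
  (attained level ≈ 0.03 at nominal 0.05); use the scanned universe
  when calibration matters.
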