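# Methods

## Overview

`phyrn` implements an alignment-free, profile-based phylogenetic pipeline
of the PHYRN family for protein superfamilies whose paralogous groups are
too divergent (down to ~30% average pairwise identity) for reliable
multiple sequence alignment. Instead of a single MSA, each sequence's
conserved domain seeds a position-specific scoring matrix (PSSM); every
full-length sequence is then locally aligned against every profile, and
the resulting matrix of composite scores — not the alignments themselves —
carries the phylogenetic signal:

1. **Profiles.** For each of the N input sequences, the domain region
   (given by an external boundary table) seeds one PSSM, enriched against
   a target database of putative homologs.
2. **Scoring.** Each full-length query is aligned against each of the M
   profiles (local, affine gaps). The composite score of a query-profile
   pair is `percent identity x percent coverage`, range 0–10000, displayed
   on a log10 scale 0–4.
3. **Distances.** Per query, only the top-scoring 75% of profiles are
   reported (the rest are stored as zero). Euclidean distances between the
   N rows of the N x M matrix give an N x N distance matrix.
4. **Tree.** Saitou–Nei Neighbor-Joining on the unscaled distances. The
   0–1 rescaling of distances is applied only for display.
5. **Support.** Jackknife: each replicate subsamples 80% of the M matrix
   columns without replacement, recomputes distances, and reruns NJ;
   branch support is the percentage of replicates containing the
   bipartition, summarized by strict majority-rule consensus (branches
   under the display threshold render as `-`).
6. **Signal-to-noise.** The Difference Ratio (DR) per matrix coordinate:
   each query is shuffled (uniform permutation of its residues, preserving
   length and composition), re-scored against all profiles over many
   replicates, and `DR = (composite_wt − mean_random) / SD_random` — a
   z-score of the observed composite against its own permutation null.

## Profile construction

Profile search tools normally supply the PSSM machinery; here it is
implemented natively so that the pipeline is self-contained and every
threshold is explicit.

* **Iterative enrichment.** Iteration 1 scores the seed through its
  BLOSUM62 rows (half-bit units). Database sequences whose optimal local
  alignment against the current profile is significant at the E-value
  threshold are included; residues aligned to seed columns form the
  profile's observation matrix (the seed itself is always included, so
  every column is defined). Later iterations re-search with the updated
  profile. Default 3 iterations.
* **E-values.** Empirical: maximal local-alignment scores of
  residue-shuffled database sequences (decoys, default 200 per
  calibration) are fitted with a Gumbel distribution by the method of
  moments; `E(s) = n_db · (1 − exp(−exp(−λ(s−μ))))`. A fresh-decoy
  Monte-Carlo check in the test suite verifies that P(p ≤ 0.01) ≈ 0.01.
  The default inclusion threshold is 7e-13; E-value scales are relative
  to database size, so this is the appropriate analogue of 1e-6 against a
  comprehensive database when the target database is small and
  family-specific.
* **Column model.** Henikoff position-based sequence weights; PSI-BLAST
  style pseudocounts mixing observed weighted frequencies `f` with the
  substitution-prior expectation `g_a = Σ_j f_j P(a|j)` at weight β
  (default 10) against α = (mean distinct residues per column) − 1; scores
  are half-bit log-odds against the background.
* **Background.** Recovered from the rounded BLOSUM62 half-bit matrix
  itself by solving `M p = 1` with `M = 2^(S/2)`, then renormalizing the
  implied joint `q_ab = p_a p_b M_ab`. This makes the triple (background,
  joint, conditional) exactly self-consistent, so a column whose observed
  frequencies equal the background scores exactly zero — a property the
  test suite asserts.

## Alignment and statistics

The optimal local alignment is computed by Biopython's C `PairwiseAligner`
(Gotoh three-state affine recursion). A length-L profile is presented to
the aligner as a sequence over L private symbols with a square
substitution matrix whose (column, residue) block holds the
position-specific scores, reducing sequence-vs-profile alignment to
sequence-vs-sequence alignment over a larger alphabet. A gap of length g
costs `open + (g−1)·extend` (defaults 11/1, half-bit units). Among
co-optimal alignments the one with the smallest (query start, profile
start), then the fewest columns, is selected (enumerated up to a fixed
cap of 64; ties beyond the cap are resolved by the aligner's own
deterministic order). The DP optimum is validated against brute-force
enumeration of all gapped local alignments on small instances.

* **Identity** is measured against the profile's stored seed sequence,
  over all alignment columns including gap columns (BLAST convention).
* **Coverage** is the fraction of distinct profile positions included in
  the alignment, relative to profile length L by default — the score asks
  how much of the conserved domain is matched, while queries are
  full-length. A `coverage_ref="query"` switch is provided.
* The ambiguity code X scores a constant −1 against every column and
  never counts as identical.

## Matrix, distances, trees

* **Retention** is per-query (row-wise): exactly `ceil(0.75·M)` cells are
  kept (ties to the smaller profile index); unreported cells are stored as
  zero, and by default enter the Euclidean sum as zero (`masked="drop"`
  restricts each pair to columns retained in both rows). The rule is a
  library-scale reporting limit: with M in the hundreds it suppresses the
  long tail of noise cells. **At desk scale (M ≈ 12, a single family where
  every profile is a true homolog) it instead zeroes informative cells and
  degrades the tree, so the end-to-end recovery experiments below run with
  `b_fraction = 1.0`.** The retention rule itself is tested separately.
* **NJ** is the standard Saitou–Nei agglomeration. Two under-determined
  choices are fixed: Q-ties resolve toward the lexicographically smallest
  pair of cluster representatives (a cluster is represented by its
  smallest leaf label), and negative estimated branch lengths are clamped
  to zero without redistribution. The Q criterion is evaluated on
  unordered pairs only — the usual vectorized matrix expression is
  asymmetric at the ulp level, which would make tie detection depend on
  which triangle is searched. Correctness is checked against additive
  matrices (exact topology and branch-length recovery) and, on 5-taxon
  instances, against exhaustive minimum-evolution search with OLS branch
  lengths.
* **Consensus** uses the strict majority rule (> 50%); an extended-greedy
  mode is available behind a flag. Supports are rounded to one decimal.
  Jackknife subsampling operates on whole PSSM columns (the M dimension):
  deleting individual matrix cells would leave pairwise distances
  undefined, whereas column subsampling keeps every replicate a coherent
  distance recomputation.

## Difference Ratio

One shuffle per query per replicate (not per query-profile pair), each
aligned against all M profiles; 100 replicates by default. The population
(n-divisor) SD is used (configurable); the replicate moments are
accumulated with Welford's algorithm so that a shuffle-invariant query
(e.g. a homopolymer) yields exactly zero variance and DR = 0. Degenerate
coordinates with zero SD but `wt ≠ mean` receive a signed sentinel
(default 1e4). Retention is not applied inside the randomization: both
wild-type and null scores are raw composites. Calibration: for shuffled
decoy queries scored as wild type, coordinate-wise DR is approximately
standard-normal-scaled (|mean| < 0.5, SD within [0.5, 2] at 100
replicates); informative (self) coordinates in simulated families sit at
DR ≈ 25–35.

## Synthetic family generator

The simulator provides ground truth for end-to-end validation:

* **Topology** by a Yule process (uniformly random lineage splitting),
  with leaf labels randomly permuted — tip positions in construction order
  are not exchangeable, the permutation makes them so.
* **Branch lengths** uniform on [0.5, 1.5] x mean (default mean 0.10).
  A strictly positive lower bound keeps every internal edge identifiable;
  heavy-near-zero draws (e.g. exponential) routinely produce edges with
  less than one expected substitution over the whole domain, which no
  method can recover, and controlled-divergence benchmark families fix
  per-branch divergence for the same reason.
* **Substitutions** are F81-style over 20 states with the package
  background as the stationary distribution: along a branch of length t
  each site is hit with probability `1 − exp(−μt)` and redraws from the
  background (possibly unchanged). Two sequences at total path length t
  then have expected identity `e^(−μt) + (1 − e^(−μt))·Σ π_a²`, the closed
  form used for calibration (the Σπ² ≈ 0.059 term is the
  random-coincidence floor). Defaults: μ = 1 per site per unit length,
  root domain 200 residues (recA/RAD51 core domains are ~200–270 aa).
* **Indels**: Poisson events along branches (default 0.005 per site per
  unit length), geometric lengths (mean 3), split evenly between
  insertions and deletions so expected length is stable.
* **Flanks**: 40 unrelated residues on each side of the evolved core, so
  full-length queries genuinely exercise the coverage statistic and the
  domain-extraction step.

Calibrated divergence regimes at 12 leaves (measured once and fixed):
branch mean 0.10 → ~58% mean pairwise identity (within-group
conservation), 0.24 → ~30% (the between-group regime), 0.65 → ~10%
(beyond the method's working range).

What passing tests on simulated data do **not** show: robustness to
among-site rate variation, compositional bias, long-branch attraction,
domain shuffling/fusion, or database contamination — none of which the
generator models.

## Problem sizes used in the test suite

The printed defaults (5000 jackknife replicates, 100 DR replicates,
3 profile iterations) are the production settings; the test suite scales
them down as its own design choice, since the statistical checks it makes
are already stable at the smaller sizes: jackknife properties use 20–30
replicates on 6-leaf families; DR calibration uses 100 replicates on a
6 x 6 library with 18 decoy queries; end-to-end recovery uses 20 runs of
12-leaf families per divergence level. Measured outcomes at those sizes:
tree recovery RF = 0 in 16/20 runs at ~58% identity and 17/20 at ~30%,
with mean RF rising to ~6 at ~10% identity.

## Numerical choices

* Half-bit log-odds throughout; gap open 11 / extend 1.
* Gumbel fit by method of moments; a degenerate (zero-variance) decoy
  distribution is an error rather than a silent fallback.
* Composite scores are exact products of two percentages; `log_scale`
  maps `[0, 10000] → [0, 4]` via `log10(max(c, 1))`.
* DR degenerate coordinates: tolerance `1e-9·max(1, |wt|)` separates
  "equal to the null mean" from the sentinel case.
* Newick serialization keeps 10 significant digits; underscores in labels
  are preserved literally.

## Known limitations

* The composite-score distance is not additive in expected substitutions;
  NJ on it is a heuristic whose accuracy is established empirically (the
  recovery experiments), not by a consistency theorem.
* Empirical E-values extrapolate a Gumbel tail from a few hundred decoys;
  p-values far below ~1/n_decoys rely on that extrapolation.
* Identity against the seed sequence makes each profile's scores mildly
  seed-centric; rpsBLAST-style tools behave the same way.
* All-vs-all exact DP scales as N·M·L·|query|; the implementation is
  desk-scale by design (hundreds of sequences), with no heuristic seeding.
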