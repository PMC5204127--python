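# Methods

`confeax` discovers short conserved features (SLiMs and small domains) de novo
in a divergent protein family, then asks how those features were partitioned
between paralogues after gene duplication.  The pipeline has three stages —
gapless EM motif discovery, iterative profile-HMM refinement, and
phylogenetic-profile coevolution clustering — plus a synthetic family
generator that provides exact ground truth for every stage.

## 1. Motif discovery (EM on position weight matrices)

**Model.**  Every width-`w` window of every sequence independently either
starts a motif occurrence (probability `site_prior`) or is background.  This
"any number of repeats" site model places no bound on occurrences per
sequence, which matters for features that occur in repeat arrays.  A motif is
a `w x 21` column-stochastic PWM over the 20 canonical residues plus `X`;
the `X` entry of every column is pinned to the background frequency of `X`,
so ambiguous residues score exactly 0 bits everywhere.

**EM.**  The E-step computes per-window posterior site probabilities; the
M-step re-estimates the PWM from posterior-weighted counts with a Dirichlet
pseudocount (0.01 per letter per column) and re-estimates `site_prior` as the
mean posterior, clamped to `[1e-8, 0.05]`.  Because the M-step maximizes the
pseudocount-penalized objective, the quantity reported by `em_step` is the
window-mixture log likelihood *plus* that penalty: it is this MAP objective
that carries the EM monotonicity guarantee (the clamp is a constrained
M-step and preserves it).  Convergence: `|delta| < 1e-6` or 200 iterations.

The 0.05 prior cap encodes that a short feature occupies a small fraction of
a multidomain protein.  It is also a safeguard: without it, EM on null data
can drift into a degenerate mode where the prior inflates until half of all
windows count as weak "sites".

**Seeding.**  Candidate starts are the distinct windows of the data, each
converted to a PWM with probability 0.7 on the observed letter.  For speed
the distinct windows are deterministically subsampled (evenly spaced in
sorted order) to at most `max_seed_candidates` (default 1000) before a
one-step EM screen; the best `n_refine` (default 50) are refined to
convergence.  Exhaustive seeding is quadratic in family size and buys
nothing once the planted/real motif is within the screened set.

**Hits.**  Sites with posterior >= 0.5 are accepted greedily without overlap
(descending posterior, leftmost-start tie-break).  With the prior capped at
0.05 every accepted site has non-negative log-odds, so the summed
training-site LLR is >= 0.

**Significance.**  Empirical: each sequence is residue-shuffled
(composition preserved), the *same* seeding/refinement protocol is re-run on
the shuffled data at the same width, and the dataset-level log likelihood
ratio (mixture vs background-only) is compared with the observed one.
Significance is the fraction of `n_shuffles` (default 20) shuffles reaching
the observed statistic; a motif is accepted when it is strictly below
`sig_threshold` (default 0.05).  Two points matter here:

* the null search must use the identical protocol, otherwise the observed
  side wins by optimization strength alone and background motifs appear
  significant;
* the comparison statistic is the dataset-level likelihood ratio, not the
  summed per-site LLR.  The sum rewards diffuse overfits — on shuffled data
  EM finds clusters of many weak sites whose total out-sums one genuine
  motif — whereas the likelihood ratio charges every claimed occurrence the
  prior's `log(1/site_prior)` toll.

Under pure background the observed dataset and its shuffles are
exchangeable, so the false-accept rate is bounded by `1/(n_shuffles+1)`
(about 1/21 at defaults); we measured 0/30 false accepts on fresh null
families.

**Width.**  Discovery runs at each width in `width_range` and keeps, per
motif, the width with the best (significance, LLR).  The widths actually
searched are a user choice; the benchmark tests use the planted width, the
pipeline default is 6–14.

**Masking.**  Accepted sites are masked (windows overlapping them are
excluded, and they are replaced by `X` for the significance shuffles) before
the next motif is sought, so training sites of successive motifs never
overlap.  Up to `max_motifs` (default 50) motifs are reported; discovery
stops at the first non-significant candidate.

## 2. Hit extension, instance alignment, logos

Significant hits are extended by 5 residues on both sides (clamped at
sequence ends) to recover context the strict gapless windows lose.  Extended
instances are aligned with an internal progressive aligner: all pairwise
global alignments (BLOSUM62, affine gap open 11 / extend 1, via Biopython's
pairwise engine) give `1 - identity` distances, a UPGMA guide tree orders
the merges, and profiles are merged by affine-gap dynamic programming with
expected-BLOSUM62 column scores.  Instances are short (tens of columns), a
regime where progressive alignment is adequate; no consistency-based or
iterative refinement is attempted.

Column occupancy filtering keeps columns whose non-gap fraction is >= the
threshold (inclusive — a 4/5 column survives at 0.8).  Logo matrices report
per-column frequencies over non-gap residues and information content
`log2(20) - H` in bits, with no small-sample correction by default (a config
flag enables it nowhere downstream; gaps reduce column weight but are never
drawn as letters).

## 3. Profile HMMs and the iteration

**Build.**  Alignment columns with occupancy >= 0.5 become match states;
others become inserts.  Henikoff position-based sequence weights (mean 1)
and Laplace +1 pseudocounts give match emissions and per-node transitions
over {M->M, M->I, M->D, I->M, I->I, D->M, D->D}.  Insert states emit
background.  The default null/background is uniform over the 20 canonical
residues: deriving it from the instances themselves would assign near-zero
background to letters the motif happens to lack and make them score
positive anywhere in a target.

**Scoring.**  Local alignment: a path enters at any match state (uniform
1/L), traverses core states, exits from any match state (uniform 1/L).
Unaligned flanks emit background in model and null alike and cancel, so the
score of a path is its log2 odds ratio.  Viterbi (best path, with
traceback for hit intervals) and forward (log-sum over all paths) are exact
dynamic programs over the M/I/D lattice (numba-compiled); both are verified
against exhaustive path enumeration on small models, and forward >= viterbi
always.

**Calibration.**  Viterbi scores of `n_calibrate` (default 200) random
sequences drawn from the background composition, lengths resampled from the
target set, are fitted with a maximum-likelihood Gumbel;
`E(S) = n_targets * exp(-lambda (S - mu))`, clipped to `[0, n_targets]`.

**Search.**  Per sequence, best-hit-then-mask: the best local hit is taken,
then the flanking segments are searched recursively, yielding all
non-overlapping hits above threshold.

**Iteration.**  `confeax_iterate` loops {extend -> align -> build ->
calibrate -> search} from an EM seed motif.  Design choices that emerged
from instability analysis on degenerate motifs (conservation 0.7, 60%
carriers):

* flank extension applies to the seed hits only; re-extending every round
  grows the model by two flanks per iteration without bound;
* search threshold during iteration and final acceptance both default to
  E <= 1 (one expected false hit per family).  A looser iteration threshold
  (E <= 10) floods each training alignment with ~10 background windows,
  diluting the match emissions until weak true sites drop out; a stricter
  final one (E <= 0.01) is so far beyond the EM posterior gate that the
  iteration's sensitivity gain is erased;
* calibration is seeded once per run — re-randomizing it each round makes
  borderline E-values flicker across the threshold;
* convergence: identical hit set (Jaccard 1), Jaccard >= 0.99 twice in a
  row, or revisiting any earlier hit set (the update is deterministic, so a
  revisit proves a limit cycle); hard cap 20 rounds.

On the degenerate benchmark this configuration matches or beats EM-only
site recall in 9/10 paired seeds and always converges within the cap.

## 4. Coevolution profiling

Presence/absence of each feature across the duplicated gene copies (entry 1
iff >= `min_hits` accepted hits; unduplicated proteins excluded by default)
gives the binary profile matrix.  Pearson `r` between feature columns,
distance `d = 1 - r`, UPGMA clustering with merge height = average
distance / 2 and lexicographic tie-breaks, and a `k = 2` cut produce the
co-segregation report: per cluster, the mean presence per paralogue class.
Constant profile columns have undefined `r`; they are excluded from
correlation and clustering and reported separately — coercing them would
fabricate signal.  UPGMA is implemented directly (Lance–Williams updates)
and verified against a naive re-averaging reference; it is deliberately not
delegated to a library so the oracle comparison stays two-route.

## 5. Synthetic families and what they do(n't) show

The generator plants features on i.i.d. background residues with a
per-column conservation parameter `c` (consensus letter with probability
`c`, otherwise background-proportional), assigns each feature's retention to
MAD / BUB / both, and flips retention bits with probability `flip_noise`.
Duplicated species contribute a MAD and a BUB copy; carrier fractions below
1 are realised through the flip channel (presence probability
`1 - flip_noise` on a "both" retention).  Named configurations:

* `planted_motif_config` — 40 proteins, lengths 250–350, one 10-mer at a
  chosen conservation in a chosen fraction of proteins (the discovery and
  iteration benchmarks);
* `subfunctionalization_config` — 16 duplicated pairs, five MAD-retained and
  five BUB-retained 8-mers, 5% flips (the coevolution benchmark);
* `default_benchmark_config` — 24 species / 16 duplications, lengths
  300–1200, ten features including a symmetric three-feature cassette (two
  flanking motifs co-retained with a central one).

Deliberate simplifications: no shared mutational history between copies (no
tree-structured evolution), no indels inside planted sites, per-column
independence (no covariation).  Passing the benchmarks therefore shows the
algorithms recover what they model — positionally conserved, gaplessly
plantable features and their retention pattern — not that they handle
alignment-shifting indel evolution or phylogenetic autocorrelation; with
real families the paralogue labels must also come from an upstream
phylogenetic analysis rather than the generator.

Benchmark problem sizes (family sizes, 5–20 repeat seeds, seed-screen sizes
of 250–400 with 6–10 refinements) were chosen so the full verification runs
in minutes while every stage still operates in its intended regime.

## 6. Numerical conventions

Coordinates are 0-based half-open everywhere.  Scores are bits (log2).
Ties: equal-posterior EM sites and equal-scoring overlapping HMM hits go to
the leftmost start; UPGMA ties to the lexicographically smallest member
tuple.  All randomness flows from explicit integer seeds through numpy
`SeedSequence`; identical seed and input give byte-identical motif JSON,
model JSON and pipeline output checksums.  Degenerate inputs raise: empty
FASTA, residues outside the 21-letter alphabet (with id and offset),
sub-minimum sequence sets, all-columns-filtered alignments, zero match
columns, degenerate calibration score variance, and a hit set collapsing
below 2 during iteration ("feature lost").

## 7. Known limitations

* The empirical significance gate costs `n_shuffles` extra EM searches per
  candidate motif; for large families screen sizes should be kept modest.
* E-values depend on an empirical Gumbel fit; with `n_calibrate = 200` the
  tail beyond ~1e-4 is extrapolation.
* The progressive aligner has no iterative refinement; pathological
  instance sets (many near-duplicates plus one outlier) can lock in early
  gap choices.
* Feature identity across pipelines is positional (motif ids `m1, m2, ...`);
  mapping to named biological motifs is the user's interpretation step.
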