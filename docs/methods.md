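# Methods

## Model

A binding motif of length `L_m` is modelled as a position weight
matrix over either the 4 bases (*mono*, `L_m` columns) or the 16
overlapping di-nucleotides (*di*, `L_m − 1` columns). Weights are
smoothed log-odds against a position-averaged promoter background:

    odds_b(i) = (n_b(i) / n) / e_b
    s_b(i)    = 0, if odds_b(i) > 0.01 · (1/K) / e_b
              = 0.01 · (1/K) / e_b, otherwise
    w_b(i)    = ln(odds_b(i) + s_b(i)) + c_i

with `n` the number of aligned sites, `K` the alphabet size (4 or 16)
and `c_i` chosen so every column maximum is exactly 0. The smoothing
term is a rare-symbol pseudo-count — it only enters when a symbol's
odds fall at or below one percent of the uniform-symbol odds, and in
particular prevents `ln 0`. Scores of words are additive over
columns, hence ≤ 0, and a score *cutoff* defines a hit. Because the
term under the logarithm mixes a frequency with a background
probability in the source formulation, this package fixes the odds
reading `(n_b/n)/e_b`; back-solving a single background from the
published GATA-3 weight blocks is consistent with that reading and
with a GC-rich promoter background (≈ A 0.21, C 0.29, G 0.29, T 0.20),
which the test suite verifies to ±0.05 on the first weight column.

Background frequencies are averaged over all positions of all
promoters (the promoter window is −(L−101)..+100 with the TSS at 0
for L-bp records). Zero frequencies are floored at 1e−4 and the
vector renormalised so weight construction is total.

## Scanning and positional statistics

Promoters are scanned on both strands; a window is a hit when its
forward or reverse-complement score reaches the cutoff, and
minus-strand hits are reported at the forward-strand start. Per
sequence, `L − L_m` start positions are scanned — the window flush
with the 3′ end is excluded, which makes the negative-set arithmetic
for 600-bp promoters and a 6-base matrix exactly 594 windows per
sequence; `include_last_start=True` selects the `L − L_m + 1`
convention.

The expectation for positional statistics comes from fragment
shuffling: each sequence is cut left-to-right into fragments of
uniformly random length (default 1–10 bp; the final fragment may be
shorter) and the fragments are permuted. This preserves each
sequence's base multiset exactly. `rounds_per_sequence` successive
passes mix a sequence; `replicates` independent copies of the whole
database are averaged into the expected per-position hit count. The
per-position z-score is computed on counts,

    z_i = (n_obs,i − n_exp,i) / sqrt(n_exp,i),

a Poisson standardisation that grows with the square root of the
database size at fixed occurrence frequencies. Positions with zero
expectation yield z = 0 when nothing was observed and +inf otherwise
(flagged, never silently dropped). Maximal runs with z at or above a
threshold (default 3), optionally bridged across `merge_gap`
sub-threshold positions, are reported as functional windows.

A caveat the shuffling model makes explicit: one fragmentation pass
disturbs only fragment junctions (≈ 1/E[fragment] of adjacencies), so
first-order structure such as CpG content is largely preserved; with
many passes the adjacency survival probability `(1 − 1/E[f])^rounds`
vanishes and di-nucleotide content converges to the product of the
marginal base frequencies. `composition_report` (base frequencies,
mean CpG per sequence, CpG observed/expected) quantifies that drift;
the CpG-preservation test is therefore run at one pass, and a
companion test demonstrates the convergence to independence at many
passes. Di-nucleotide-exact shuffling is deliberately out of scope.

## Refinement loop

The refinement state is a set of window sites identified by
(promoter, start, strand). Each cycle: (1) the matrix built from the
previous cycle's sites sweeps a cutoff grid (default −4.0..−0.5, step
0.1, stringent end first; ties go to the more stringent cutoff). At
each cutoff the matrix extracts sites from the functional window; with
`TP` the extractions identical to the previous set, `FP = N_new − TP`,
`FN = N_prev − TP` and `TN = l_w·N_s − TP − FP − FN`, the Matthews
coefficient is maximised (the four counts partition the `l_w × N_s`
candidate windows, asserted every cycle; the zero-denominator MCC
convention returns 0). (2) Holding the optimal cutoff, the site set
is extended or trimmed by one column per end — flanking bases taken
from the source promoters in binding orientation — and a new length is
kept only when it strictly improves CC. Convergence is FP = FN = 0:
the extraction reproduces its parent set, a fixed point (re-optimizing
a converged matrix changes nothing, which the tests assert).
(3) Window boundaries are hill-climbed by ±1 bp moves in the fixed
order extend-left, extend-right, shrink-left, shrink-right, each
variant re-converged from the initial matrix. The winner maximises
sensitivity on the experimental sites subject to a shuffled-set OF_r
no worse than the initial matrix's, ties resolved toward lower OF_r.

The initial cutoff, when the starting matrix carries none, maximises
MCC of the experimental sites (positives) against every window of the
shuffled database (negatives, `(L − L_m) × N_s`, hit on either
strand), scanning the grid from the stringent end.

Two bookkeeping choices are worth noting. Site identity is positional
— (promoter, start, strand) — not sequence identity, the stricter
reading. During a length trial the two strands shift start
coordinates differently (a binding-orientation left extension moves a
plus-strand start by −1 but a minus-strand start's forward coordinate
by 0); candidate starts are mapped back to the reference frame per
strand before the TP test. After a length change is accepted the
window is interpreted in the new matrix's start frame, a one-base-pair
approximation the ±1 bp window search itself absorbs.

## Evaluation

Sensitivity is the fraction of (pre-oriented) experimental sites
scoring at or above the cutoff. The false-positive level OF_r is the
number of predictions in a shuffled database divided by
`N · (L − L_m)`; both strands count, so a position passing on both
contributes 2 and the saturation value is 2.0. Bound/unbound sets are
classified per sequence (any hit anywhere = positive); sequences
shorter than the motif are warned about and counted as negatives. The
sensitivity-vs-OF_r curve is emitted over the optimizer's cutoff grid
by default; both coordinates are non-decreasing as the cutoff relaxes
(a property test).

## Synthetic data

The generator emulates the statistical shape of TSS-aligned human
promoter collections, not their sequence content: GC-rich base
composition (default A 0.20, C 0.32, G 0.30, T 0.18), an optional
first-order chain whose C→G transition is multiplied by `cpg_boost`
(note the renormalisation dampens the realised CpG enrichment below
the nominal boost), at most one motif plant per promoter drawn from a
PFM at a uniform position inside a TSS-relative window, and
strand-symmetric planting (minus-strand probability 0.5, matching
orientation-independent binding of GATA factors). All generators are
pure functions of (spec, seed) and return exact ground truth. What
passing tests on this model do *not* show: robustness to alignment
error in the site collection, promoter length heterogeneity,
repeat-induced composition structure, or multiple sites per promoter
(the per-promoter binary occurrence counting assumes at most one
relevant site per position anyway).

## Benchmark problem sizes and identifiability

The test suite's system benchmarks use sizes chosen as the smallest
that make the certified property statistically unambiguous:

- *Functional-window recovery*: 100 runs of N_s = 1000 promoters of
  200 bp, occupancy 0.3 in [−7, 0], planted from the refined GATA-3
  mono frequencies; matrix from a 63-site sample, cutoff −2.5;
  shuffled expectation from 3 replicates × 3 mixing passes (peak
  detection is insensitive to deeper mixing). Success = a z ≥ 3
  window overlapping the plant; observed ≥ 95/100.
- *Refinement recovery*: N_s = 2000, occupancy 0.4, initial window
  [−3, −1], 300 training sites, sweep floor −6.0, planted model an
  8-bp PFM with one dominant base (0.9) per column.

The recovery benchmark's motif model is deliberately
bounded-degeneracy, and that choice encodes a genuine limitation of
cutoff-thresholded site extraction: the refinement fixed point can
only contain words whose rebuilt-matrix scores clear the sweep floor.
With a sharply peaked planted model, words carrying a base absent
from the current site pool receive the rare-symbol penalty
(≈ ln(0.01/K·e⁻¹) − c, around −6 per such base) and can never re-enter
the pool — the published GATA-3 frequency profile, whose rare column
entries have expected counts near zero in a 68-site pool, is for that
reason *not* recoverable to tight total-variation tolerance by any
cutoff-based extractor, regardless of implementation. With one
dominant base p = 0.9 per column the captured pool is the {0,1}-
mismatch mass and the systematic column distortion is
`q²(L−1)/(p + Lq) ≈ 0.04` (q = 1−p), well inside the benchmark's 0.1
tolerance; the measured total variation is 0.06–0.07 across seeds.

## Numerical choices

- Matrices store full-precision floats; published-table comparisons
  round half-to-even at 2 decimals.
- Column normalisation subtracts the column maximum, so the maximum is
  exactly 0.0 in floating point, and all scores are exactly ≤ 0.
- The cutoff grid is generated by integer stepping
  (`min + k·step`, rounded at 1e−6) to avoid float-accumulation drift.
- A cutoff so relaxed that strand-mismatched identities break the
  TN ≥ 0 partition is skipped in the sweep (it can never win).
- One RNG (`numpy.random.default_rng`) per entry point, seeded
  explicitly; no global state. Replicate identity is encoded in
  sequence ids (`/rep{k}`).
- Degenerate consensus: bases at or above the inclusion threshold,
  descending by frequency, bracketed when plural; if none qualifies
  the single most frequent base is emitted. The threshold is exposed
  because no single value reproduces all published degenerate rows.

## Known limitations

- The refinement loop is a local, greedy search (per-cycle CC
  maximisation plus ±1 bp hill climbing); it converges to a
  self-consistent site pool near the initial extraction, not to a
  global optimum, and its outcome depends on the initial cutoff.
- OF_r treats every shuffled-window prediction as a false positive;
  real promoters contain unannotated true sites, so OF_r is an upper
  bound on the false-positive rate only under the shuffled null.
- Fragment shuffling preserves first-order structure only
  approximately (quantified above); conclusions about di-nucleotide-
  sensitive statistics under deep mixing should use the composition
  report to check the null.
- Promoter partitioning by TATA/CpG/Inr class is out of scope; run the
  profiling on pre-partitioned FASTA files instead.
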