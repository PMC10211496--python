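# Methods

## The model

A tandem repeat (TR) of period n is modelled by an n-row position weight
matrix (PWM): row i scores the i-th position of the repeat unit against each
symbol. The matrix is aligned to a window of sequence *wrap-around*: a
Smith–Waterman-style local alignment in which the row (phase) index advances
cyclically, so one matrix spans any number of adjacent repeat copies. The
optimal score F_max is the detection statistic's raw material.

Two symbol alphabets are supported:

* **mono** (n×4): single bases, the classical RPWM scoring;
* **di** (n×16): adjacent base pairs, column index `s(j-1) + 4·(s(j)-1)`
  with bases coded A=1, T=2, C=3, G=4 (column order AA, TA, CA, GA, AT, …,
  GG). Dinucleotide columns capture the neighbour correlation that
  mononucleotide frequencies cannot: a sequence assembled from the blocks
  ATCG/TAGC/CCAA/GGTT has perfectly flat per-phase base frequencies (its
  M(4,4) count matrix is uniform) yet a strongly structured M(4,16), and
  only the di-mode scan sees its period-4 structure.

### Normalisation

Every matrix in a run is affinely transformed so that two sums are shared
constants: Σ pwm(i,j)·p1(i)·p2(j) = 0 and Σ pwm(i,j)² = n·K, where p1 is
uniform over phases and p2 holds the window's symbol frequencies (base
frequencies in mono mode; dinucleotide frequencies, counts/(L−1), in di
mode). Centring under the background makes the expected per-position score
zero for an unrelated sequence of the same composition; fixing the total
squared weight puts all matrices of a run on one scale. The specific
constants (0 and n·K) are a free choice — only their being shared matters —
and n·K gives unit root-mean-square weights, a convenient scale for gap
penalties.

### Alignment

The DP grid is (sequence position j, phase r) with affine gaps:
insertions consume a base without advancing the phase, deletions advance
the phase without consuming a base; the cyclic deletion recursion is
resolved with a second sweep over phases, covering deletions that wrap the
period boundary. Cell floor at 0 (local alignment). In di mode the first
window position has no predecessor pair and is unscorable, so alignments
start at j ≥ 2. Ties are broken deterministically (first-encountered
optimum; diagonal moves preferred in traceback).

Gap penalties are not dictated by the model; they were calibrated once on
the two worked-example constructions (period-10 and period-21 divergent
arrays, below) so that the pipeline reproduces their reference Z values,
giving defaults gap_open = 10.0, gap_extend = 2.5 in normalised-score
units. Both remain configurable.

## Optimisation

For one (window, period) pair a genetic algorithm maximises F_max over a
population of 500 normalised random PWMs (cells initialised U[−10,10], the
same range used by mutation): per generation, rank fitness; point-mutate
one random cell in each of 10 randomly selected non-elite matrices; breed
one descendant by uniform cell-wise crossover of two uniformly chosen
parents; drop the worst matrix; re-align only what changed. The elite is
protected from mutation and replacement, so the best fitness V(1) is
non-decreasing. The loop stops when V(1) has not improved for
`stall_generations` (default 100) or after `max_generations` (default
5000).

**Profile re-estimation (polish).** The GA's one-cell-at-a-time moves
converge extremely slowly on the ~n·K coordinated weights a divergent
repeat requires. The package therefore interleaves an EM-style
hill-climbing step on the same objective: take a matrix, read off the phase
assignment v(j) of its current alignment, accumulate the n×K count matrix
M (adding a background-proportional pseudocount, weight 0.5 of the total
count, which damps self-fit on sparse cells), normalise it into a PWM, and
accept it only if F_max improves. Every `polish_every` (default 10)
generations this is applied alternately to the elite (exploitation) and to
a freshly drawn random matrix (exploration — each restart probes a new
phase basin), and once to the final best matrix. This is the same move used
by iterative profile-refinement multiple aligners; because acceptance is
score-gated, all GA invariants (monotone V(1), fixed population size)
hold. It can be disabled (`polish=False`), which recovers the pure GA —
the mono-mode baseline pipeline runs that way.

## Significance

Z(n) = (V(1) − mean) / sd over a Monte-Carlo null: the window is shuffled
(preserving mononucleotide composition exactly) `replicates` (default 50)
times and the *fixed* optimised matrix is scored against each shuffle — the
GA is not re-run per shuffle, which would be computationally prohibitive.
When the optimisation used polish, each null shuffle grants the fixed
matrix the same polish opportunity; otherwise the re-estimation step's
self-fit gain (which is available on any sequence, structured or not)
would inflate Z far above its calibrated scale. The residual selection
bias of the GA itself is absorbed by the empirically calibrated threshold
Z₀: on pure-noise sequences the pipeline measures Z ≈ 0–3, comfortably
below the default Z₀ = 6.

Period selection: the di-mode (mRPWM-style) pipeline scans n over a range
and keeps argmax_n Z(n); the mono-mode (RPWM-style) baseline ranks periods
by raw V(1) instead, which is cheaper but biased towards long periods and
harmonics — the di/Z ranking exists precisely to fix that.

On a strong repeat the Z profile plateaus across the whole harmonic family
(a period-4 repeat is also periodic at 8, 12, …), so the raw argmax can
degenerate into a tie broken by Monte-Carlo estimator noise (the sampling
noise of a Z estimated from R shuffles is roughly Z/√(2R)).
`PeriodScanResult.fundamental_period()` resolves such ties to the family's
fundamental: the smallest divisor of the argmax period whose Z lies within
a noise margin (default 2·Z_max/√R) of the maximum. Divisors below the
plateau — candidate sub-periods without genuine support — are not taken.

A genome scan slides a 1,200 b window with a fine step (default 10 b),
computes Z₁(k) = Z(n_max(k)) per window start k, and keeps local maxima:
Z₁(k) > Z₀ and Z₁(k) dominating every neighbour within ±60 positions
(left-strict on ties, so a plateau reports its leftmost point). Regions
inherit coordinates from the winning window's alignment; same-period hits
from adjacent windows overlapping with C > 0.5 are merged. Regions with
fewer than 4 repeat copies are dropped. Thresholds are calibrated by the
false discovery rate FDR(Z₀) = N_random/N_real, counting hits on the real
sequence and on its composition-preserving shuffle over a Z₀ grid.

## Synthetic benchmarks

`make_st` builds the divergent-repeat benchmark St(x): a random 10 b unit
multiplied 120× (1,200 b), degraded by a given number of substitution
events and 20 single-base indels. Substitution events pick positions with
replacement and always change the base; the divergence label is
x = 2·substitutions/L, the mean number of substitutions separating two
copies (each event moves one copy away from all others, contributing twice
to a pairwise comparison). The standard grid 0, 100, 500, 1000, 1500,
1800, 2200, 2400 events maps to x = 0, 0.17, 0.83, 1.67, 2.5, 3.0, 3.67,
4.0.

`make_harmonic_example` regenerates the two worked-example constructions:
`period10` = {ATCGATTCGG}×120 with 1,200 substitution events, and
`period21` = a 21-base unit (ATCG×5 + G, so a period-4 repeat nests inside
the 21-base period) ×57 with 1,200 substitution events. Both are fresh
synthetic constructions following the published recipes, not the original
supplementary files; the period-21 unit is a reconstruction — the printed
unit is 19 bases long, inconsistent with its stated period (21) and length
(~1,200 b), so the package restores the two dropped bases in the way that
preserves the described nested structure.

What the generators do **not** emulate: real genomic background (GC
heterogeneity, transposons, low-complexity tracts), multi-scale repeat
nesting, or indel length distributions beyond single bases. Passing the
synthetic benchmarks therefore demonstrates the detector's behaviour under
controlled divergence, not its false-positive profile on real chromatin.

## Clustering of period matrices

Two matrices describing the same repeat family can differ by a cyclic
rotation of their rows (the repeat can be read starting at any phase), so
the distance is min over the n row rotations of the Euclidean distance
(squared differences; a signed-difference variant is available behind a
flag but can cancel terms and is not a metric). Matrices are clustered by
complete linkage (scipy) and a dendrogram cut at a user-supplied level
defines classes. Class significance uses a cell-shuffle null: permute the
cells within every matrix, recluster, repeat (default 100×), and
standardise each observed class size (and the class count) against the
pooled null statistics. The published class statistics are ambiguous about
whether "N" is a class size or a class count, so both are computed.

## Problem sizes and numerical choices

* Detection-limit runs use 5 seeds per divergence level, GA stall 300 /
  cap 3000 generations, 40 Monte-Carlo replicates; a full 1,200 b
  (window, period-10) optimisation takes ~1–3 s with the numba DP kernel.
* Whole-range period scans (n = 2–50) on a 1,200 b sequence take ~1–3 min
  per mode.
* The planted-repeat scan test uses a 20 kb chromosome, 400 b window step
  and a restricted period range; these are test-scale choices, the scanner
  itself has no such limits.
* Degenerate inputs raise: constant matrices cannot be normalised,
  zero-variance nulls are an error rather than an infinite Z, windows
  containing N are skipped (and counted), and FDR at zero real hits is
  reported as missing rather than 0/0.
* All randomness flows through numpy Generators seeded explicitly; every
  public operation is deterministic given its seed.

## Known limitations

* The detection limit measured for the di-mode pipeline on St(x) under the
  matched-polish null is x ≈ 2.2–2.6, not the ≈3.6 reported for the
  original implementation. The gap traces to the significance accounting:
  granting the null the same re-estimation opportunity as the real
  sequence (necessary to keep Z calibrated at a fixed Z₀) also absorbs
  genuine-but-weak signal at x ≥ 2.5, where the optimum reachable from the
  true phase is only marginally above the null's re-estimation optimum.
  Disabling the null polish inflates Z on pure noise to ≈12, which would
  invalidate the fixed Z₀ = 6 threshold altogether.
* The mono-mode baseline's raw-fitness period ranking drifts towards the
  longest harmonic available in the scan range; this bias is inherent to
  ranking unstandardised maxima across different matrix dimensions and is
  the motivation for the Z-based ranking.
* One strand only; no reverse-complement search.
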