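# Methods

## Model and assumptions

The package implements consensus clustering by signed evidence
accumulation.  Given n elements observed through one or more sources,
each source contributes an ensemble of K-means partitions (single
random initialisation per run, Lloyd iteration cap 100, k drawn
uniformly per run).  Votes are pair counts: a positive source adds one
co-occurrence vote per partition that puts a pair together; a negative
source adds one separation vote per partition that puts a pair apart.
Normalised positive evidence lies in [0, 1] with unit diagonal,
negative evidence in [−1, 0] with zero diagonal, and the combined
matrix G\* = G⁺ + G⁻ in [−1, 1].  Counts are accumulated as integers
and normalised exactly once at combination time, so the per-strategy
denominators (q for a single source; (d·q)+b when positive sources are
pooled; d·q and o when polarities are mixed) are applied exactly.

The method assumes that each source's K-means partitions, however
individually poor, are statistically informative about the pair
relation under that source — positive sources about "belongs
together", negative sources about "belongs apart".  Negative evidence
is only meaningful combined with positive evidence; the estimator
rejects source sets with no positive member.  Polarity is a user
decision: no automatic criterion for it is attempted.

## Consensus extraction

G\* is treated as a similarity matrix.  Two dissimilarity readings are
provided:

* `rows` (default): Euclidean distance between rows of G\*.  Two
  elements are close when they accumulated the same vote profile
  against the whole data set.  This matches the behaviour of applying
  a stock linkage routine directly to the matrix, and is considerably
  more robust to vote noise because pair contrasts aggregate over all
  n coordinates.
* `shift`: max(G\*) − G\*, the classic one-minus-similarity reading,
  shifted so it stays non-negative when negative evidence drives
  entries below zero.

Average-link (UPGMA) agglomeration is delegated to
`scipy.cluster.hierarchy.linkage`; fixed-k cuts use `cut_tree`
(equivalent to undoing the last k−1 merges).  Automatic model order
uses the lifetime criterion: lifetime(k) is the height difference
between the merge reducing k to k−1 clusters and the merge reducing
k+1 to k, defined for k in 2..n−1; the argmax is selected, ties broken
toward the smallest k (parsimony), and k = 1 is excluded because its
lifetime is unbounded above.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| k range per partition | [⌈√n/2⌉, ⌊√n⌋], clamped ≥ 2 | granularity of each ensemble run |
| partitions per source q | 100 | vote resolution ≈ 1/q |
| negative fraction | 1/3 | o = d·q·f/(1−f), i.e. o = d·q/2 |
| K-means iteration cap | 100 | standard Lloyd budget |
| standardisation | per-source z-scoring on | sources mix scales (coefficients vs. seconds) |
| dissimilarity | rows | see above |
| final k | lifetime | or any fixed integer ≥ 2 |

Per-source z-scoring leaves constant columns at zero (relevant for R2,
which is identically zero in an all-regular rhythm).

## ECG feature extraction

A 200 ms window (round(0.2·fs) samples) is cut symmetrically around
each annotated beat sample, zero-padded at record edges, and
baseline-corrected by subtracting the window mean.  The window is
projected on N = 16 orthonormal Hermite functions φ_n(t; σ)
(physicists' Hermite polynomial × Gaussian envelope, each sampled
column renormalised to unit discrete norm); σ is selected from a grid
of 2–40 ms in 1 ms steps by least-squares reconstruction error, ties
to the smaller σ.  Rhythm features are R1 (previous RR interval) and
R2 (Heaviside-clipped second difference of R1).  Boundary handling:
R1 of the first beat copies the second's; α — hence R2 — is zero at
the first two and the last beats.  Windows are not
amplitude-normalised: coefficients carry amplitude, which is itself
discriminative.

Numerical caveats, both verified empirically:

* Discrete orthonormality of the sampled basis holds to 1e-6 only up
  to σ ≈ 12 ms for N = 16 at a 200 ms window: the order-15 function
  has effective support ≈ √31·σ and overruns the half-window above
  that.  For larger σ the least-squares projection (pseudoinverse)
  remains exact even though the Gram matrix departs from identity.
  Below ≈ 3 samples per σ the envelope aliases; a warning is issued.
* σ is sharply identified only for windows with substantial
  high-order Hermite energy (sharp, multiphasic QRS shapes).  For
  smooth low-order morphologies the 16-dimensional fit absorbs most
  of the signal at many σ values and the estimate can wander several
  grid steps under noise.

## Synthetic data

`toy_gaussians` generates the six-cluster demonstration: three 2-D
blob pairs (centres (0,0), (4,0), (2,3.5); within-pair offset 0.7;
spread 0.5) whose halves are separated only by a third feature with
means ∓1 and spread 0.5, 100 points per cluster.  Only the element
count, the six-Gaussian structure and the ±1 means of the third
feature are externally fixed; the remaining geometry was chosen once
so that the three demonstration contrasts (3 / 2 / 6 clusters for
joint-positive / split-positive / positive+negative routing) hold
robustly, then frozen.

The demonstration pipeline (`run_toy_contrast`) likewise freezes its
own configuration: 300 partitions per contrast (joint: 300; split and
negative: 100 from features 1–2 plus 200 from feature 3, the two cases
differing only in the polarity of the feature-3 source), `rows`
dissimilarity, and a consensus k-bounds override of (2, 6).  The small
k-bounds matter: under the √n rule (13–24 at n = 600) each K-means run
chops the one-dimensional third feature into ~18 slivers, leaving
same-mode co-occurrence around 0.13, which erases the six-block
structure the negative-evidence contrast demonstrates.  With k bounded
by the granularity of the structure being voted on, all three
contrasts reproduce in ≥ 90% of seeded runs (in practice ~100%).  The
√n rule remains the library default for real data, where n per
recording is large and cluster counts are unknown.

`synthetic_beats` builds multilead beat series from per-class Hermite
templates (a normal class, a wide "ventricular" class with σ = 30 ms,
and a premature class morphologically identical to normal), a base
rhythm of 0.8 s with 10 ms jitter, a premature-interval factor of 0.6
followed by a compensatory pause, and additive white noise (default
0.02 of template amplitude).  It emulates the statistical structure
the method needs — class-specific morphology and prematurity — and
nothing physiological: no P or T waves, no baseline wander, no
realistic noise spectra.  Passing tests on it therefore show that the
pipeline separates morphology- and rhythm-defined classes under its
own assumptions, not that it attains any particular accuracy on real
recordings.

## Evaluation

Clusters are typed by their majority annotation symbol (ties to the
lexicographically first symbol, deterministically); members with other
symbols count as errors.  Confusion matrices are assigned-type ×
true-type with column-normalised sensitivity and row-normalised
positive predictivity; classes never assigned render "-" for P+.  The
AAMI EC57 collapse (N, S, V, F, Q) ships as an editable mapping; the
placement of '!' (ventricular flutter wave) is not standard across
studies and defaults to Q.

## Problem sizes in the test suite

The suite runs the toy contrasts at full n = 600 with the frozen
300-partition budgets over 50 seeds (~2 minutes), oracle-equivalence
checks on 200 random ensembles (n ≤ 30) and 100 random linkage
instances (n ≤ 12), and ECG end-to-end properties at 80–150 beats with
reduced ensemble budgets (q = 8–25).  Full-database runs (tens of
thousands of beats, q = 100 per lead) are supported through the WFDB
path but take hours of CPU and require external downloads, so they are
not part of the suite.

## Known limitations

* The WFDB support is a minimal subset (formats 212 and 16, MIT
  annotation files, single-segment records, one `.dat` per record).
* Lifetime selection is known to proliferate clusters on noisy real
  recordings; fixed-k cutting is provided for that reason.
* No QRS detection: annotations are taken as given.
* No parallel execution; ensembles are embarrassingly parallel but are
  generated sequentially from one seeded generator for exact
  reproducibility.
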