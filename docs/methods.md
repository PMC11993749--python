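# Methods

## Problem setting

Direct RNA sequencing (DRS) on nanopores reads native RNA, so chemically
modified nucleosides (m⁶A, m⁵C, pseudouridine Ψ) leave signatures in the raw
current. A large family of computational methods turns those signatures into
site-level *stoichiometry* calls: for each reference position, the fraction of
reads carrying the modification. Comparing such methods fairly requires (a)
datasets where the per-position stoichiometry is known by construction, and
(b) an agreed metric suite and exchange format. `stoichbench` implements that
benchmarking layer: challenge-style reference design, dataset simulation with
known truth, the bedRMod exchange format, and the metric suite.

## Reference design

Nanopore current depends on the k-mer occupying the pore, so a reference that
contains every k-mer with the target base at the centre exercises a caller in
all sequence contexts. `enumerate_central_kmers(base, k)` emits all 4^(k−1)
k-mers with the fixed central base (256 for k = 5), ordered lexicographically
by flanking bases; `build_reference` concatenates them gap-free (1280 nt core
for k = 5), each block contributing one expected modified position at its
centre (positions `|flank5| + k·i + (k−1)/2`). The order can be seed-shuffled;
no attempt is made to optimise signal separability or to compress overlaps
(a de Bruijn construction would break the one-modification-per-block layout).
References are DNA-alphabet (T, not U), matching how such templates are
designed and how aligners consume them.

## Packaged challenge profiles

Three profiles mirror the published challenge layouts on a 2438-nt reference
with 243 target positions:

| profile | modification | central base | target-rate range |
|---|---|---|---|
| challenge1 | m5C | C | 0.12 – 0.33 |
| challenge2 | m6A | A | 0.01 – 0.10 |
| challenge3 | psi (Ψ) | T | 0.31 – 0.50 |

The 2438/243 layout does not follow from the naive 1280/256 core and its
origin is not documented for the real constructs; we reproduce it as
configuration: seeded random flanks (579 + 579 nt) pad the core to 2438 nt,
and a seeded subset of 243 of the 256 block centres carries target rates.
Rates are drawn uniformly from the profile's range; with
`anchor_endpoints=True` two seeded positions receive exactly the range
endpoints, so the profile's extreme rates equal the declared range bounds —
used when the recovered extremes are compared against the declared ranges.

## Simulation

Two generators, both bit-reproducible under a fixed seed:

* **Controlled-rate mode** (`simulate_controlled`): per position, the modified
  read count is Binomial(coverage, rate), with uniform coverage. This is the
  calibration mode for the rate estimator: errors must obey the binomial
  standard error √(p(1−p)/n).
* **Transcript-mixture mode** (`simulate_transcript_mixture`): reads from a
  fully modified pool and an unmodified pool are generated over the reference,
  each carrying its origin and aligned span. DRS sequences 3'→5', so
  incomplete reads lose 5' sequence: the 5' start offset is geometric with a
  configurable mean (default 0 = full-length), the 3' end always complete.
  This makes the emergent per-position mixing ratio vary along the reference.
  The cause of the per-position rate variation in the real challenge data is
  not documented; the truncation model is a plausible stand-in, not a claim
  about the data.

Simulation operates at the read/alignment abstraction (origin + span). It does
not emulate raw current, basecalling errors, alignment errors, poly(A)
tailing, or coverage biases beyond 5' truncation — so passing tests show the
*scoring and estimation machinery* is correct, not that any caller will
perform comparably on real signal data.

`split_reads` partitions a read table 80/20 (configurable) by seeded shuffle,
with |train| = round-half-away-from-zero(frac·n). `perturb_truth` degrades a
truth site list into method-like predictions (seeded dropout, ±1-base jitter,
clipped Gaussian frequency noise, spurious sites at unmodified positions) to
exercise the evaluator away from the identity case.

## Rate estimation

With reads separately attributable to the two pools, the ground-truth
stoichiometry at position p is the fraction of covering reads that are
modified: `rate[p] = n_mod[p] / (n_mod[p] + n_unmod[p])` over half-open
spans. The ratio is not stated as a formula in descriptions of this
procedure; we commit to the mod fraction because target frequencies are
fractions in [0, 1] (an odds ratio mod/unmod could exceed 1). Zero-coverage
positions yield *no* rate (NaN) rather than 0 — "unobserved" is not
"unmodified". Export to bedRMod applies a minimum-coverage gate (default 10
reads) so that ratios resting on a handful of reads are suppressed.

## Metric suite

Given truth and prediction site lists over one reference of N positions:

* **Error metrics over all N positions** — RMSE, MAE, and median absolute
  error of Ŷ−Y, with Y = 0 at unmodified positions and Ŷ = 0 where no site was
  predicted, paired strictly by position (no window). The median is the lower
  median for even N, so the reported value is always an observed error.
* **Deviation range** — max and min |Y−Ŷ| restricted to modified positions
  (Y > 0), giving the error range on the predicted frequencies.
* **Classification under tolerance** — a predicted site is a true positive if
  it lies within ±1 base (`pos_window`) of a truth site *and* its frequency is
  within Y ± 0.6·Y (`freq_tol_factor`), clipped to [0, 1]. An unmodified
  position is a true negative when nothing (or an exactly-zero frequency) is
  predicted there. Accuracy = (TP+TN)/N, F1 = 2TP/(2TP+FP+FN).

Design choices the tolerance prose leaves open, fixed here:

* **Matching is one-to-one and TP-maximizing.** The ±1-base window can put one
  prediction inside the window of two truth sites; double counting would
  inflate TP. We solve a linear assignment on the bipartite tolerance graph
  (infeasible pairs get a prohibitive cost), which maximizes match count and,
  among maximal matchings, minimizes total positional offset. Verified against
  exhaustive enumeration on small instances.
* **FP counting.** An unmatched prediction with frequency > 0 at a position
  without a truth site is a false positive; unmatched predictions *at* truth
  positions are already accounted for by the FN at that site.
* **Degenerate F1.** F1 is 0/0 when TP = FP = FN = 0 (empty truth matched by
  empty prediction after TN accounting); we define it as 1. With TP = 0 and
  FP+FN > 0 it is 0.
* **Tolerance applies only to classification.** Error metrics use strict
  positional pairing; widening the tolerance therefore never changes RMSE/MAE
  but never decreases TP (a tested monotonicity).

Whether RMSE/MAE should run over all N positions or only the modified ones
is a genuine convention choice; we compute them over all N (consistent with
very small minimum deviations being meaningful only when reported separately
on the modified subset) and restrict the deviation range to the modified
positions.

## Numerical and interface choices

* Coordinates are 0-based half-open everywhere (BED convention).
* bedRMod dialect: `#key=value` header (required keys `fileformat`,
  `modification_type`, `assembly`), then 11 tab-separated columns
  (BED9 + coverage + frequency); `score = round(1000·frequency)` mirrors the
  frequency for BED-only consumers. Frequencies are serialized with
  shortest-round-trip float representation so parse∘write∘parse is the
  identity; records are written coordinate-sorted.
* All randomness flows through `numpy.random.default_rng(seed)`; every CLI
  subcommand takes `--seed` (default 42) and identical invocations produce
  identical files.
* Validation returns issue lists (severity, line, message) instead of raising,
  so a file's problems are reported exhaustively; writers refuse records that
  violate invariants.

## Scale of the shipped checks

The acceptance run simulates each challenge profile at coverage 20 000 per
position over 2438 positions (243 modified) — deep enough that the binomial
standard error at the range endpoints (≈0.002–0.004) is far below the range
widths, so the recovered rate extremes identify the declared endpoints. The
randomized evaluator check uses 1000 fixtures of up to ~6 sites, the scale at
which exhaustive matching enumeration is exact and fast.

## Known limitations

* No raw-signal or basecalling-error modelling; results say nothing about any
  specific caller's accuracy on real data.
* The bedRMod dialect implements the documented column semantics, not the
  full external v1.8 specification field-for-field.
* Multiple modification types per file are parsed but the evaluator scores a
  single reference namespace at a time.
* The published method-level leaderboard values require the original raw
  challenge data and participants' prediction files and are not reproducible
  here; the toolkit reproduces the design-level quantities instead.
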