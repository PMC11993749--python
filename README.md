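# stoichbench

Benchmarking toolkit for **site-level RNA modification stoichiometry
prediction** from direct RNA sequencing (DRS).

Methods that call m⁶A, m⁵C or pseudouridine (Ψ) from nanopore signal are hard
to compare: each one reports sites in its own format, and "correct" is fuzzy
when both the position and the modified fraction of reads carry error.
`stoichbench` provides the benchmarking layer around such methods, for method
developers and benchmark organisers:

* **Reference design** — synthetic constructs containing every k-mer with a
  fixed central target base (256 five-mers, 1280-nt gap-free core), so a
  caller is exercised in all sequence contexts.
* **Dataset simulation** — mixtures of a fully modified and an unmodified
  read pool with known per-position stoichiometry, a controlled binomial mode
  for estimator calibration, seeded train/test splits, and a truth-perturber
  that produces method-like prediction files. Three packaged profiles mirror
  published challenge layouts (2438-nt reference, 243 target positions,
  rate ranges 0.12–0.33 for m5C, 0.01–0.1 for m6A, 0.31–0.5 for Ψ).
* **bedRMod I/O** — parser, writer and validator for the BED-derived
  site-level exchange format (`#key=value` header + BED9 rows extended with
  coverage and frequency, `score = round(1000·frequency)`).
* **Rate estimation** — ground-truth stoichiometry from two separately
  attributable read pools: `rate = n_mod / (n_mod + n_unmod)` per position.
* **Metric suite** — for a truth/prediction pair over N reference positions:

  * RMSE, MAE and median absolute error of Ŷ−Y over all N positions
    (Y = 0 where unmodified, Ŷ = 0 where nothing predicted);
  * max/min deviation |Y−Ŷ| over the modified positions;
  * accuracy (TP+TN)/N and F1 = 2TP/(2TP+FP+FN) under a tolerant matching
    rule: a prediction is a true positive if within ±1 base of a truth site
    and its frequency lies in Y ± 0.6·Y. Matching is one-to-one and
    TP-maximizing, so one prediction never satisfies two truth sites.

See `docs/methods.md` for the model, conventions and design choices.

## Worked example

Simulate the m5C challenge profile, split the reads, degrade the truth into a
method-like prediction file, and score it:

```sh
stoichbench simulate --profile challenge1 --seed 7 \
    --n-mod 3000 --n-unmod 7000 --truncation-mean 400 \
    --reads-out reads.tsv --truth-out truth.bedrmod --fasta-out ref.fa
# challenge1: 10000 reads over 2438 nt, 243 truth sites at the 243 target positions

stoichbench split --reads reads.tsv --train-out train.tsv --test-out test.tsv
# 8000 train / 2000 test reads

stoichbench perturb --truth truth.bedrmod --ref-length 2438 \
    --pos-jitter-prob 0.1 --freq-noise-sd 0.03 --fp-rate 0.002 --fn-rate 0.05 \
    --seed 9 --out pred.bedrmod
# 243 truth sites -> 236 predicted sites

stoichbench evaluate --truth truth.bedrmod --pred pred.bedrmod \
    --ref ref.fa --out report.json
```

prints

```json
{
  "rmse": 0.044406041107410074,
  "mae": 0.008242869542481069,
  "median_ae": 0.0,
  "max_deviation": 0.3024183174684847,
  "min_deviation": 9.740619179676724e-05,
  "accuracy": 0.9963084495488105,
  "f1": 0.9812108559498957
}
```

Reading the numbers: the simulated "method" recovers most sites (F1 0.98 —
12 of 243 sites were dropped or jittered/perturbed outside the tolerance,
plus a few spurious calls), its typical frequency error is small (MAE 0.008;
the median absolute error is 0 because most of the 2438 positions are
unmodified and correctly left empty), but its worst site is off by 0.30
(max deviation — a site whose frequency noise landed far from the truth).
Evaluating a truth file against itself returns RMSE = MAE = 0 and
accuracy = F1 = 1.

The same pipeline is available as library functions
(`stoichbench.build_challenge`, `simulate_transcript_mixture`, `pileup`,
`compute_rates`, `evaluate`, …).

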