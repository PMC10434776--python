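# hudopt

Surrogate-assisted genetic optimization of augmented-reality head-up
display (AR-HUD) interface designs for professional drivers.

An AR-HUD interface is described here by nine categorical choices —
main color, module arrangement, frame shape, information font (four
options each) and five binary module variants — encoded as a 26-bit
one-hot chromosome (4+4+4+4+2+2+2+2+2 bits, option *k* of a group
setting bit *k*). The package:

* learns a **cognitive-load surrogate**: a feedforward network
  (26 → 15 → 15 → 15 → 1, log-sigmoid units) trained by
  Levenberg–Marquardt on 240 rated prototypes, predicting the NASA-TLX
  workload score ŷ(c) of a design code c;
* searches the 4⁴·2⁵ = 8192-design space with an **elitist genetic
  algorithm** (roulette selection, single-point crossover at rate 0.8,
  bit-flip mutation annealed within [0.01, 0.1], one-hot repair),
  maximizing fitness F(c) = 21 − ŷ(c);
* trains a small **fully-convolutional pixel-importance predictor**
  (FCN-16s-style: five stride-2 stages, a stride-16 skip, bilinear
  upsampling) with the real-valued sigmoid cross-entropy loss
  L(θ) = −(1/N) Σᵢ [Qᵢ log Pᵢ + (1−Qᵢ) log(1−Pᵢ)], Pᵢ = σ(fᵢ(θ)),
  and evaluates predictions with KL(P,Q) = Σᵢ Qᵢ(log Qᵢ − log Pᵢ) and
  the Pearson cross-correlation CC(P,Q) ∈ [−1, 1];
* runs a **two-objective (NSGA-II) variant** trading predicted load
  against the fraction of predicted attention mass inside the six
  display modules, returning per-generation Pareto fronts;
* ships the study's printed tables (240 eye-movement records, 240
  (code, NASA-TLX) training pairs, the 15-rater Cooper-Harper
  comparison) as validated fixtures, plus seeded synthetic generators
  for hotspot scenes and load datasets with known ground truth.

The intended users are human-factors and HCI researchers prototyping
display layouts against workload and attention criteria.

## Worked example

Decode the first training row and optimize a design from the packaged
table:

```sh
$ hudopt codec decode 00101000010010000101011001
{"GM": 3, "GL": 1, "GF_frame": 2, "GA": 1, "GB": 2, "GC": 2, "GD": 2, "GE": 1, "GF_gear": 2}

$ hudopt optimize --seed 1 --out ga_run
best predicted NASA-TLX 3.846 (generation 6, code 10000001000100011010010110)

$ hudopt stats --out stats_run
CH comparison: 11/15 (73.3%) prefer the first method
```

The decode output names the option index chosen for each design
variable (e.g. GM=3 is the green main color). `optimize` retrains the
surrogate on the 240 printed pairs with the given seed, runs the GA and
reports the lowest predicted workload score it found together with the
winning chromosome; the full per-generation trace lands in
`ga_run/history.csv`. `stats` reproduces the Cooper-Harper preference
share from the packaged comparison table.

The same pipelines are available as library calls
(`hudopt.surrogate.train`, `hudopt.run_ga`, `hudopt.run_moo_ga`,
`hudopt.train_ivpm`) returning fitted estimator objects.

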