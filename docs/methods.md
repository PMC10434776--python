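# Methods

## Design encoding

A design is nine categorical choices: GM (main color), GL
(arrangement), GF_frame (frame shape), GA (font) with four options
each, and five binary module variants GB, GC, GD, GE, GF_gear. The
chromosome is the concatenation of one one-hot group per variable in
that fixed order, 26 bits total; option *k* sets bit *k* of its group.
The two variables the source material both calls "GF" (frame shape and
gear status) are disambiguated as `GF_frame` and `GF_gear`.

For the genetic machinery's continuous view, each one-hot pattern is
identified with a unit interval on a [0, arity] axis (`1000`→[0,1],
…, `0001`→[3,4]; `10`→[0,1], `01`→[1,2]). The representative value of
an interval is its midpoint — the mapping is symmetric and exactly
invertible — and the inverse lookup uses left-closed/right-open
intervals with the last interval closed, so it is total on [0, arity]
and unambiguous at boundaries.

Strict decoding requires every group to be one-hot and names the first
offending group otherwise. Permissive decoding resolves a broken group
by the same uniform repair rule the GA uses and flags it. The packaged
rating table is used in raw-bit form (26 binary features) because most
of its printed codes are not group-wise one-hot; only strictly valid
codes enter the search space itself.

## Cognitive-load surrogate

`CognitiveLoadRegressor` is a fully-connected network
26 → 15 → 15 → 15 → 1 with log-sigmoid activations at every layer,
fitted by damped least squares (Levenberg–Marquardt): solve
(JᵀJ + μI)δ = Jᵀr on the full training batch, accept a step only if it
reduces the training SSE, shrinking μ by 10 on acceptance and growing
it by 10 otherwise (initial μ = 1e−3, giving up above 1e10). The
accepted-step training error is therefore non-increasing by
construction. A plain gradient-descent optimizer (step size
`learning_rate`, default 0.1) is available as a fallback; the LM path
controls its own damping and ignores the learning rate.

Because the output unit saturates in (0, 1), raw NASA-TLX targets are
min-max scaled into [0.05, 0.95] before training and predictions are
inverse-scaled, which also bounds predictions to a margin around the
observed target range. Data are split 70/15/15 into
train/validation/test with seed-controlled shuffling; the validation
part drives early stopping (stop after 6 consecutive validation-error
increases, the common toolbox default) and the weights of the best
validation epoch are retained. An optional absolute training-MSE goal
(`goal`) can stop training early; it is disabled by default because no
defensible value exists on the scaled targets.

A practical note on the packaged rating table: many of its 240 rows
repeat the same 26-bit code with different NASA-TLX scores, so any
predictor that is a function of the code faces an irreducible
validation error equal to the within-code spread of the ratings. Our
training reliably reaches that regime (the training error flattens at
the table's within-code variance), so reported validation MSE reflects
rating noise, not underfitting.

## Genetic algorithm

Fitness is `upper_bound − ŷ(c)` with `upper_bound = 21`, the
conventional top of the NASA-TLX scale, making fitness non-negative
and strictly decreasing in predicted load. Selection is roulette
(fitness-proportional, uniform fallback with a warning if all fitness
is zero); crossover is single-point on the flat 26-bit string at rate
0.8 (a group-aligned variant is available behind a flag); mutation
flips each bit independently, with the rate annealed linearly from
0.10 to 0.01 across generations — the study states the range but not a
value, and annealing keeps early exploration inside the stated bounds.
Every offspring is repaired to one-hot form: a group with several set
bits keeps a uniformly chosen one, an empty group gets a uniformly
chosen bit, and valid groups are untouched, so repair is the identity
on valid chromosomes and every individual in every generation is
strictly decodable.

Elitism (carrying the single best individual unchanged) is on by
default; it makes the per-generation maximum fitness monotone
non-decreasing, matching the reported convergence behaviour.
Termination is at 300 generations or 50 stalled generations by
default; the population defaults to 240, the size of the rating table,
and can be seeded from the table's (repaired) codes or drawn uniformly
from the valid space. With a population of 240 over a space of 8192
designs the GA in practice attains the exhaustively enumerated global
optimum of the fitted surrogate; tests verify this against the
brute-force oracle.

## Importance predictor (IVPM)

`ImportancePredictor` maps a grayscale layout image to per-pixel
importance in (0, 1). Encoder: five 3×3 stride-2 convolutions with
ReLU (default channels 8, 12, 16, 16, 16), so the deepest features sit
at stride 32. A 1×1 score head reads the deepest stage; its output is
upsampled 2×, summed with a 1×1 score head on the stride-16 stage (the
skip connection), and the fused score is upsampled 16× to input
resolution. Upsampling uses fixed bilinear (or nearest) interpolation
matrices; their adjoints are exact transposes, which keeps the
hand-derived gradients simple and is the standard initialization for
learned FCN upsampling anyway. Training minimizes the real-valued
sigmoid cross-entropy loss with Adam (default 30 epochs, batch 8, lr
0.01); predictions are clipped into [1e−7, 1−1e−7] inside the loss
only. Backpropagation through the im2col convolutions and the
interpolation operators is verified against finite differences in the
test suite.

This is a deliberately tiny from-scratch network intended for the
synthetic scenes below; it does not use pretrained weights and makes
no claim about natural images or real eye-tracking corpora.

## Metrics

KL divergence: both maps are shifted by 1e−8, normalized to sum 1, and
scored as Σᵢ Qᵢ(log Qᵢ − log Pᵢ) — the divergence of the prediction P
from the reference Q, zero iff the normalized maps coincide.
Cross-correlation is the Pearson coefficient over pixels; constant
maps raise a degenerate-map error rather than returning NaN. Both
implementations are checked against independent per-pixel formula
evaluations on tiny maps at 1e−12.

## Synthetic data

The load-dataset generator draws valid chromosomes uniformly and
scores them with a documented additive truth function over option
indices (base 4.0; per-step weights 1.0, 0.8, 0.6, 0.4 for the 4-ary
groups and 0.5, 0.4, 0.3, 0.2, 0.2 for the binary groups; optional
+0.8 interaction when GM=2 and GL=3), spanning [4, 14] like the
printed ratings, plus Gaussian rating noise (default sd 0.5). It
exists so recovery error can be measured against a known truth.

Scenes emulate eye-tracking hotspot maps: the six module boxes sit on
a 2×3 grid scaled to the canvas; importance is a normalized sum of
isotropic Gaussian blobs (σ = 0.25 × the box's short edge) centered
uniformly inside chosen boxes over a 0.05 background floor, peak
exactly 1; the paired image draws box outlines with fill intensity
increasing in the attention weight a box received, so the map is
predictable from the image. What passing tests show is that the
pipeline learns this synthetic image→attention relationship end to
end; they say nothing about human gaze on real displays, whose
heatmaps were never deposited.

## Rendering bridge and the two-objective search

Nothing in the source material specifies how a chromosome becomes an
image, so the bridge is an explicit artifact construction behind a
narrow interface: a deterministic schematic renderer (fill intensity
from the main color's luminance, four fixed arrangement permutations,
four border styles, per-module line/dot textures) and an attention
objective equal to the fraction of predicted importance mass inside
the six module boxes. Alternative objectives can be swapped in.

The multi-objective loop minimizes (predicted load, −coverage) with
the standard generational Pareto GA: parents and offspring pooled,
fast non-dominated sorting, crowding-distance truncation, binary
tournament on (rank, −crowding); variation operators and repair are
shared with the single-objective GA. The default run is 40
generations. Per-design objectives are memoized (the valid space has
8192 members). Front snapshots are taken every generation; tests
verify non-domination by brute force.

## Evaluation statistics

Shapiro–Wilk wraps the Royston algorithm (3 ≤ n ≤ 5000, constant
samples rejected). The paired t-test is implemented directly —
t = mean(d)/(sd(d)/√n), two-sided p on n−1 df, 95% CI of the mean
difference — and cross-checked against an independent implementation
at 1e−10; identical samples return the conventional null result
(t = 0, p = 1). Note the standard reading: small Shapiro–Wilk p
*rejects* normality. The Cooper-Harper comparison takes the printed
per-category sums as authoritative (the packaged table's third-column
rows disagree with its printed sum; the loader flags this) and reports
the share of raters preferring the first method.

## Problem sizes and numerical choices

Default runs used throughout the tests and the acceptance script: GA
population 240 with up to 120 generations for the load optimization;
surrogate re-trained per seed (10 seeds for the GA study, 5 for the
validation-error study); IVPM trained on 200 synthetic 64×64 scenes
for 30 epochs with an 80–20 split; the two-objective demonstration
uses smaller populations at 64×64. Constants: loss clipping 1e−7, KL
normalization shift 1e−8, LM damping [1e−20, 1e10] with factor 10,
target scaling [0.05, 0.95], fitness bound 21.

## Limitations

The surrogate is a function of the 26 raw bits only; it cannot resolve
differing ratings of identical codes, and its extrapolation to codes
unlike the training rows (in particular the strictly one-hot search
space, which most printed rows are not) is uncontrolled — the GA's
optimum is the optimum of the fitted surrogate, not of human workload.
The importance predictor and the rendering bridge are synthetic-scale
constructions; coverage differences between designs are small because
the renderer changes fills and textures, not geometry. The statistics
module implements the tests as conventionally defined, which includes
interpreting normality p-values in the standard direction.
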