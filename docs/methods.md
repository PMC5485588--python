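# Methods

## Pairwise rank representation

A pathway P = (g₁, …, g_m) maps each sample to a bit vector over the
m(m−1)/2 ordered gene pairs, enumerated lexicographically in the
pathway's given gene order: bit(i, j) = 1 iff expression(gᵢ) <
expression(gⱼ). The representation is exactly the ranking of the m genes
with ties resolved, so it is invariant under any strictly increasing
per-sample transform. Only exact equality counts as a tie (no epsilon);
in real data exact ties arise almost exclusively among unexpressed
genes. A tie draws a fair coin from the caller's seeded generator; with
no generator supplied the package runs in a *deterministic mode* (ties →
0, and template probabilities of exactly 0.5 round to 1) intended for
bit-exact regression tests. Tie bits are re-drawn on every binarization
call from the supplied source, never cached.

## Templates and distances

The probability template T_P is the entrywise mean of the reference
collection's bit vectors; the binary template T_B its rounding. The
distance of a sample with bits B from a template is

D = (1/S) · Σ w(T_P) · |T_B − B|,  S = Σ w(T_P),

with two built-in weight functions: quadratic w(x) = (x − 0.5)², which
down-weights pairs whose ordering is biologically variable in the
reference, and constant w ≡ 1, under which D reduces to the plain
reversal proportion. Weight functions are pluggable (any nonnegative
callable on [0, 1]).

Degenerate templates — all T_P = 0.5 under the quadratic weight, so
S = 0 — carry no evidence of deviation: the distance is defined as 0
with a RuntimeWarning and the pathway is flagged unusable for scoring
(scoring drops it; the single-reversal floor raises instead, since a
calibration cannot exist).

## Pathway scores

Per pathway, each reference sample's distance to the template (built
from all reference samples, including itself; a leave-one-out mode
exists but is not the default) yields θ = median and δ₀ = IQR. The score
of a new sample at distance d is 0 if d ≤ θ, else (d − θ)/δ with
δ = max(δ₀, w(0.75)/S) — the floor is the distance contributed by a
single reversal of a pair with template probability 0.75, which keeps
the score finite when the reference distances are (near-)constant.
Quantiles use linear interpolation (type 7) and the even-n median is the
mean of the central pair; the upstream definition does not fix either
convention, so these are package choices, documented here because they
affect third decimal places of δ₀.

## Classification

Nearest-template assignment with three methods: weighted rank distance,
uniform rank distance, and a pathway-centroid baseline (per-gene mean
vector, Euclidean distance) representing absolute-expression templates.
Exact distance ties go to the lexicographically first class label and
are flagged, trading a small bias for determinism.

Cross-validation is stratified k-fold (sklearn `StratifiedKFold`,
shuffled), repeated; defaults are 10 repeats of 5 folds. Templates are
rebuilt from each training fold; tie bits and 0.5-roundings are drawn
from a fold-specific child seed (numpy `SeedSequence` spawning), so
repeats are independent yet the whole protocol replays bit-exactly from
one integer seed. Multi-dataset designs with two datasets per tissue are
evaluated over all 2^t train/test splits that place one dataset per
tissue on each side, after optionally balancing classes by seeded
subsampling without replacement.

## Batch-effect statistics

For two datasets sharing a gene set:

* **ARDE** — fraction of genes with two-sided t-test p < 0.01 across the
  datasets; computed on matrices as given (ARDE-N) or after per-sample
  standardization of each full profile (ARDE-S).
* **RRDE** — fraction of gene pairs whose ordering proportions differ at
  p < 0.01. The test of two binomial proportions is implemented as
  two-sided Fisher's exact test on the 2×2 (ordering × dataset) table;
  it is the standard exact choice, and the p-value routine is a single
  function so a different exact test can be substituted. Exhaustive pair
  testing is quadratic, so RRDE is estimated by averaging over random
  gene draws (library defaults 10 draws × 200 genes, sd reported over
  draws); an exhaustive variant exists for small gene sets and is used
  as the oracle in tests. Identical tables are testing-cached, since
  only (n_a+1)(n_b+1) distinct tables exist.
* **Hetero/homo ratio** — mean rate over different-tissue dataset pairs
  divided by mean rate over same-tissue pairs, per metric: same-tissue
  pairs isolate batch effects, so the ratio is a signal-to-noise measure
  of the representation.
* **DOM** — per gene, the number of significantly differentially ordered
  pairs (p ≤ 0.01) containing it, divided by the gene-average count, so
  DOM has mean 1 whenever any pair is significant; with no significant
  pairs DOM is reported as undefined (NaN) with a warning.

t-tests default to Welch (unequal variances) with a pooled option; the
threshold comparisons are strict (<) for ARDE/RRDE and non-strict (≤)
for DOM, matching their definitions. Gene pairs with zero ordering
variance and identical proportions in both datasets get p = 1 from the
exact test, hence are never significant. Bonferroni adjustment for
differential pathway analysis is min(1, p·m) over the m pathways tested;
pathways with zero variance in both groups and equal means record p = 1
rather than erroring.

## Synthetic cohorts

The generator emulates ordering structure, not count distributions. Each
class has a consensus permutation; a sample's base value for a gene is
its consensus rank plus iid Gaussian jitter. The jitter sd is calibrated
from `flip_noise` so that a pair *adjacent* in the consensus flips with
exactly that probability (sd = 1/(√2 · Φ⁻¹(1 − flip_noise)),
flip_noise < 0.5); pairs further apart flip less, which matches the rank
stability of real profiles. Batches add gene-specific additive shifts
(drawn once per batch, scale `shift_sd` in rank units) and apply a
per-sample strictly increasing distortion from {identity, positive-slope
affine, exponential, power}, chosen to exercise — not merely assume —
the monotone-invariance property. `tie_rate` zeroes genes to emulate the
unexpressed regime where exact ties occur. Everything derives from one
mandatory seed via `SeedSequence` spawning: identical configs give
bit-identical cohorts.

What the generator does **not** emulate: mean–variance relationships,
library-size effects, count noise, correlated gene modules, or
non-monotone batch distortions. Tests passing on these cohorts therefore
demonstrate correctness of the rank machinery and its invariances, not
performance on any particular real platform.

## Problem sizes and numerical choices

The demonstration/acceptance script uses scaled study conditions chosen
to make each effect unambiguous at desk scale: null-calibration ARDE on
2000 genes × 40 samples per side; RRDE draws of 40 genes (780 pairs),
3–5 draws; batch-shift cohorts of 300 genes × 60 samples with gene-shift
sd 0.5 against jitter from flip_noise 0.1; classification cohorts of
15–20 genes × 20–35 samples per class with 2 repeats of 3–5-fold CV. The
null RRDE check uses a high-variability ordering (flip_noise 0.45) so
that pair tables are non-degenerate; because Fisher's test is exact and
conservative, the null rate sits at or below the nominal threshold —
the check is one of calibration-or-conservatism, never
anti-conservatism. Library defaults keep the full-size conventions
(10×5-fold CV, 10 draws × 200 genes).

Floating-point policy: distances are exact rational arithmetic up to one
dot product, and the constant-weight distance agrees with the reversal
proportion to < 1e-12; template serialization writes `repr` floats so
round trips are exact. Sample standardization uses the population sd
(divide by n) — a fixed convention for bit-exact tests that rank methods
are indifferent to.

## Known limitations

Pair count grows quadratically in pathway size; the intended working
range is roughly 10–250 genes per pathway (size filtering is built in).
Exact Fisher p-values on large sample counts are the RRDE bottleneck;
caching by table makes it linear in distinct tables rather than pairs.
Gene identifiers match by exact string equality — identifier translation
is out of scope. No missing-value handling: matrices must be complete,
and rejection happens at load.
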