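# Methods

## Prediction setup

All modeling is lagged regression on time-series expression: the
expression of target gene g at timepoint tᵢ₊₁ is predicted from TF
expression at tᵢ.  Pairs never cross batch boundaries, and timepoint
spacing is ignored — adjacency is ordinal, on the reasoning that
transcription-factor action takes at least one sampling interval to reach
the target.  A TF that merely co-varies with a target at the same
timepoint therefore earns no credit; only lagged association does.

Expression enters the models as per-gene z-scores of TPM,
z = (TPM − μ)/σ.  σ is the population standard deviation (divide-by-N),
so tests asserting exact values are unambiguous.  By default μ and σ are
fit on training-partition samples only, which keeps held-out information
out of the transform; `fit_partition="all"` reproduces the simpler
convention of normalizing over every sample, and a per-batch option
normalizes each batch independently.  Genes constant on the fit partition
(σ = 0) are excluded from the usable gene set and reported.

### Train/test split

The tail of every batch is reserved for testing.  With last timepoint
index n: n < 5 reserves only tₙ (input tₙ₋₁); 5 ≤ n < 10 reserves tₙ₋₁ and
tₙ; n ≥ 10 reserves the final three timepoints.  A pair is labelled by the
timepoint it predicts, so the input timepoint of the first test pair may
itself have served as a training target — inputs are not held out, only
predicted values are.

## Models and error vectors

Two estimator families sit behind one contract: random forests
(scikit-learn, 100 trees, unlimited depth, impurity-based importances,
seeded) and ridge regression (α = 1.0 on z-scored inputs; importance =
|coefficient|).  A gene never predicts itself: the target is dropped from
its own feature set, and a sole self-feature is an error.

The significance machinery needs a *per-pair* training error vector.
In-sample forest errors are near zero and would make the gate vacuous, so
by default the per-pair errors are estimated out-of-bag for forests (each
training pair's prediction averages only the trees whose bootstrap missed
it; the rare pair present in every bootstrap falls back to the in-sample
prediction) and by 5-fold cross-validation for ridge.  A strict in-sample
mode (`error_mode="insample"`) is available for comparison.  Error vectors
hold absolute errors per pair — a paired test needs per-observation
values — while RMSE is the reported summary.

## The minimal-set search

Starting from a fitted model on candidate set F, the search repeatedly
keeps the top ⌊|F|/2⌋ TFs (minimum 1) by the *current* model's importance
ranking (ties break by ascending TF id), refits, and compares the
candidate's paired per-pair errors against the baseline error vector with
a one-sided Wilcoxon signed-rank test ("candidate worse", α = 0.05).  The
baseline is fixed once — either supplied by the caller or taken from the
first fitted model — and never re-estimated inside the loop.  The search
stops at the first rejection (returning the last accepted set; rejection
of the very first halving returns the full input) or when the set reaches
size 1.

The disjoint-set search fixes E_all, the all-TF model's error vector, as
the common baseline.  After extracting S₁, it loops: fit a model on the
remaining TFs; if that model is significantly worse than E_all the search
ends (`remainder_significantly_worse`), otherwise the next minimal set is
extracted from the remainder.  Running out of TFs ends with `exhausted`;
an optional per-target cap (off by default) guards pathological runtimes
on large TF universes.  Every returned set's final model is, by
construction, not significantly worse than E_all at α = 0.05.

## Statistics

The paired comparison between two models evaluated on identical
observations is the Wilcoxon signed-rank test on their error differences.
Zero differences are dropped (Wilcoxon's original treatment, which keeps
the exact null available); the exact distribution is used below 25
non-zero differences, the normal approximation with continuity correction
above.  All-zero differences return p = 1 with a flag.

Confidence intervals on mean error differences are percentile bootstrap
(10,000 resamples, seeded).  Pairwise comparison tables pool one
observation per (target, test pair) by default — a per-target-RMSE mode
exists — and mark the "star set": the lowest-mean-RMSE method together
with every method not significantly different from it (two-sided,
α = 0.05).  No multiple-testing correction is applied across the matrix;
the table is descriptive.  CI cells are antisymmetric by construction,
CI(i,j) = −CI(j,i) reversed.

## Synthetic data

The generator emulates a multi-batch bulk time course with planted
regulatory programs.  TF trajectories are stationary AR(1) with N(0,1)
marginals (autocorrelation 0.5 by default — temporal structure that is
learnable but not trivial).  A programmed target's value at t+1 applies
its link to its primary drivers' values at t plus Gaussian noise:
linear (Σcⱼxⱼ), product (Πcⱼxⱼ, a non-linear interaction no linear model
can fit), or threshold (±1 by the sign of Σcⱼxⱼ).  Unprogrammed targets
are AR(1) noise.  Redundant driver sets are planted by per-driver signal
duplication: each TF of a redundant set copies its counterpart in the
primary set plus independent jitter (sd 0.05), so either set alone
predicts the target.  Output is in z-score space by default; a pseudo-TPM
mode (exp(z)) exercises the normalization entry point.

Default study conditions are four batches of 38 timepoints (≈136 training
pairs and 12 held-out pairs after the tail split), matching the scale of
aggregated public time-course compendia, which run to roughly 70–200
training samples per organism.  Sizes this large matter: the significance
gate's power — and therefore where the halving stops — depends directly
on the number of training pairs.

What the generator does *not* emulate: count-level noise (negative
binomial sampling, library-size variation), unequal timepoint spacing,
missing samples, systematic batch shifts (batches differ only by
realization, not by distribution), and single-cell sparsity.  Passing
tests therefore demonstrate algorithmic correctness and statistical
calibration under a favorable, well-specified generative model — not
performance on real RNA-seq.

## Benchmark conventions

All six methods are evaluated per target on identical test pairs; targets
without at least one usable gold-standard regulator are excluded from the
whole report so the comparison stays paired.  When a target's GS in-degree
k_g exceeds the TF universe, k is clamped with a warning.  The ensemble
comparison reuses the first discovered disjoint set's model as the
minimal-set method, so a target with a single disjoint set makes the two
methods coincide exactly.  One root seed fans out deterministically per
(target, method, stage) via a CRC-based hash, so any subset of the
benchmark is reproducible in isolation.

The batch-effect harness restricts each batch's comparison to that batch's
high-variance targets — the top 25% by training-partition variance, a
configurable stand-in for the selection of visibly dynamic genes — and
skips batches with no eligible target or too few pairs, reporting the
skips.

## Known limitations

Importance-based halving is blind to feature grouping.  When a driver is
planted in several near-identical copies, the copies split that driver's
importance evenly, so the ranking orders TFs driver-by-driver rather than
program-by-program; halving a small survivor set can then retain two
copies of one driver and no copy of another, which the gate correctly
rejects, leaving a single set that spans all redundant copies.  In that
regime the disjoint-set search often returns one merged set where a human
would count two redundant programs.  This is a structural property of the
greedy halving path, not of the significance gate; recovery of redundant
pairs is reliable mainly when copies are distinguishable enough for the
ranking to separate whole programs.

The gate's sharpness scales with training size.  With very few pairs the
search over-shrinks (dropping true drivers goes undetected); with many
pairs even scientifically negligible error differences (e.g. the slight
denoising advantage of duplicated features) become significant and stop
the search early.  α = 0.05 is a convention, not a tuned quantity.

Forest importances are impurity-based and carry that estimator's known
biases; the ranking is the search's only use of them.  Ridge importances
assume standardized inputs, which the z-score transform provides.
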