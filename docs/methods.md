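# Methods

This note documents the models, procedures, and numerical choices behind
`revis`, and what its synthetic study conditions do and do not establish.

## Stimulus manipulations

**Design.** One control plus 16 manipulations: 2 clutter levels, 4 blob
conditions, 4 deletion conditions, 4 aperture conditions (each: 40% "low"
or 80% "high" severity × many-small or few-large disks), and 2 phase-
scrambling bands — 17 conditions, each presentable with or without a
backward mask (34 cells).

**Equalisation.** In-mask mean luminance and RMS contrast (the standard
deviation of in-mask luminance) are matched by an affine transform to the
reference (mean 0.5, RMS 0.1 on a [0,1] scale).  Clipping to [0,1] happens
only after matching; if clipping moves either moment by more than 1e-3 the
affine match is re-applied once.  The synthetic textures are tanh-bounded,
so in practice no clipping occurs and the moments hold to 1e-6.

**Disk placement.** Centres are drawn uniformly in the object mask's
bounding box, radii uniformly in the regime band — 8–16 px ("small") or
60–110 px ("large") at the 700-px frame, scaled proportionally at other
sizes.  Placement is greedy: disks accumulate until coverage reaches the
target band; a disk that would overshoot has its radius shrunk by bisection
(48 steps) to land inside the band, and centres that cannot land there are
resampled.  The tolerance is ±0.01 of covered object fraction (integer
pixel bounds use ceil/floor so the band is never exceeded by rounding).
Pixel membership is centre distance ≤ radius on integer pixel centres,
row-major 0-based.  The radius bands are a package choice: the values make
the two regimes visually distinct (a few large vs hundreds of small disks
at 80% coverage) while keeping both targets feasible; they are arguments,
not constants.

**Aperture inversion.** For apertures the placement target is the *visible*
fraction (1 − hidden), the frame is set to the occluder colour (black) and
disks reveal the underlying image; the hidden object fraction then equals
the nominal severity.  Black was chosen as the occluder/blob colour so the
aperture and blob conditions share the dark-pixel statistics that make
these conditions behaviourally distinctive.

**Phase scrambling.** Random phases are obtained as the phase spectrum of
a white-noise image, which is automatically Hermitian-antisymmetric and
real-consistent at DC/Nyquist bins, so reconstruction is exactly real and
amplitudes are untouched (preserved to float precision, well below the
1e-6 contract).  The DC phase is always kept.  Band scrambling computes
radial frequency in cycles/degree as cycles-per-image ÷ visual angle
(default 10°, threshold 1.5 cpd).  *Band semantics:* the "low-pass"
condition retains phases at or below threshold and scrambles above
(preserving coarse structure); "high-pass" is the converse.  The two
scrambled bands partition all non-DC frequencies at any threshold.  The
naming is configurable because the underlying convention is not fixed by
the experimental description itself.

**Clutter index.** Contrast energy (CE) and spatial coherence (SC) are the
scale and shape of a two-parameter Weibull fit (`scipy.stats.weibull_min`,
location fixed at 0) to local gradient magnitudes from Gaussian-derivative
filters at scale 1.5 px, deterministically subsampled to ≤20k values.
Backgrounds are chosen as the extremes of a composite rank,
rank(CE) + rank(−SC): higher contrast energy and a heavier-tailed gradient
distribution both read as more cluttered.  Only the extremal ordering is
behaviourally meaningful, and any monotone-equivalent index would pick the
same extremes; ties resolve to the lowest input index.

## Model zoo

Fifteen variants in three families; one timestep is a full input→output
pass, and recurrent state/top-down signals always come from the previous
pass (T = 5 by default; the first pass has zero state and zero top-down
input, so it exactly equals the model's feedforward skeleton).  The final
timestep's logits are the decision output.

* **C family** (V1/V2/V4/IT + global-average-pool linear decoder, 224 px,
  channel plan 64/128/256/512): `C` is conv–ReLU–maxpool per area; `CL`
  adds an additive lateral convolution of the previous output before group
  norm + ReLU; `CT`/`CLT` implement the concatenative top-down scheme
  (equations in the README) with distinct θ_ff, θ_td, θ_rr, θ_out per
  block, group normalisation (32 groups capped at the channel count), and
  top-down input aggregated from *all* higher areas, nearest first; the
  top area has no higher input and hence no TD branch.  `C-V1V1` and
  `C-ITIT` restrict the lateral block to the named area.  `CS` is the
  bottleneck-residual recipe with weight-shared internal passes
  (times 1/2/4/2) and per-pass batch norms, reimplemented from its public
  description and validated structurally, not against released weights.
* **B family** (v1/v2/v4/it, 128 px, plan 64/64/128/128): 3×3 convolution
  + batch norm + ReLU + 2×2 pooling per layer; lateral connections are
  dedicated 3×3 convolutions on the previous pre-pool output, top-down
  connections are transposed convolutions (kernel 4, stride 2) from the
  adjacent higher layer's previous output; all terms combine additively
  before the nonlinearity.
* **VGG**: VGG16 with the classical two-4096-unit head; VGG11 is a custom
  10-conv + single-linear-head control (11 trainable layers).

**Depth-matched controls.** `BD` appends two extra conv blocks per layer
(no input pooling); `CD` prepends three conv+batch-norm+ReLU blocks per
area, with pooling retained only in the original block.  The controls
exist to match the parameter counts of `BLT` and `CS` respectively, and
the per-layer channel plans of the custom variants are design freedom.
For `CD`, appended blocks at the area's own width would add only ~9M
parameters against CS's ~53M, so the appended blocks use an internal width
of 3.5× the area's output channels (widen–process–narrow, leaving the
original block untouched); this lands CD within 4% of CS.  For the B
family, the 4-layer plan (64, 64, 128, 128) with 3×3 laterals and k4
transposed-conv top-downs puts BD within 8% of BLT.  Both matches are
verified as acceptance properties.

**Backend.** Models run on `revis.nn`, a compact reverse-mode autodiff over
NumPy (im2col convolution, transposed convolution, group/batch norm,
max/adaptive-average pooling, Adam, cross-entropy), float64 throughout.
All primitives are finite-difference-checked in the test suite; blocks are
additionally checked against naive-loop oracles.  Weight initialisation is
He fan-in normal with zero norm biases, seeded per-module from the model
seed.

## Fine-tuning

3 cycles × 9 epochs (6 head-only + 3 full) by default; the "head" phase
trains the decoder plus the last convolutional layer before it, resolved
per architecture as the final block's final convolution (recorded on each
block class).  Optimiser Adam, loss cross-entropy.  The learning-rate
policy is a pluggable callable queried once per cycle; the default halves
a base rate each cycle, standing in for a learning-rate-finder + one-cycle
schedule whose internals none of the statistics depend on.  During
head-only phases the frozen lower blocks run without graph taping, which
changes no gradient that is actually applied.  Freeze integrity (bit-
identical frozen parameters) and full-loop seed determinism are tested.
The full-scale 20-seed design is exercised at S = 3 seeds in tests and
S = 2 in the demo pipeline.

The fine-tune set layout follows the background split (half original
background, half neutral grey, equal cells); at desk scale the pipeline is
greyscale, so the colour/greyscale halves of the full design coincide.

## Simulated observers

The observer is parametric: per-condition probability correct δ_c
(unmasked), masking susceptibility μ_c ≥ 0 (accuracy under masking is
δ_c − μ_c), error responses drawn from the off-diagonal-renormalised row
of a symmetric category-similarity kernel, and RTs from a lognormal with
median rt_base + rt_slope·(1 − δ_c) (0.5 s, 0.8 s/unit, log-SD 0.15 —
positive-skew RTs with interpretable location/scale).  The default δ
profile encodes the structure the analyses assume: nine easy conditions
above 0.9, eight hard below, μ negligible (0.015) in easy conditions and
proportional to difficulty (0.5·(0.95 − δ)) in hard ones, so masking
effects concentrate in hard conditions and covary with RT.  The kernel
clusters animate categories, large rigid objects, and vertical outdoor
items.

What passing tests show: the analytics recover exactly the structure the
generator injects (δ to binomial error; μ at r > 0.9 with 500 trials/cell;
kernel off-diagonals at r > 0.8).  What they do not show: anything about
real human data — no sequential effects, no per-subject difficulty
variation beyond independent sampling, no lapses, no RT–accuracy tradeoff.
The generator validates the machinery, not the psychology.

## Analytics

Pearson correlations use the product–moment formula with the t-transform
p-value; conditions with missing cells are flagged NaN and dropped
pairwise.  The easy/hard boundary is strict (> 0.9 is easy); participant
exclusion is strict (< 0.7 excluded, exactly 0.7 retained).  Confusion
matrices are correlated over the 56 off-diagonal cells after row-
normalising to response proportions, making human and model tables with
different trial counts comparable (raw-count mode available; the diagonal
never influences the statistic).  Split-half reliability averages the
between-half correlation over random subject partitions (100 iterations by
default).  The size/architecture comparison is OLS of per-model accuracy
on log10(parameters) and a recurrence indicator: with one observation per
model a richer random-effects structure is unidentifiable, and OLS carries
the same fixed-effect contrast; size enters on a log scale.  Model
summaries aggregate per fine-tuning seed (mean and percentile 95% CI over
seeds, never over trials).

## Pipeline and problem sizes

Every stage seed derives from the master seed via SHA-256 of
`"{seed}:{stage}"` (below 2^31), so stages re-run independently without
perturbing each other's randomness; a digest manifest skips unchanged
stages, and identical configs reproduce identical CSV bytes.  The demo
configuration runs 2 categories × 2 exemplars at 128 px across all 17
conditions, 6 simulated subjects × 20 trials/cell, and two small variants
(B at 32 px, CLT at 64 px, width scale 0.125, T = 2, one 2-cycle schedule
of 6 epochs) × 2 seeds — sizes chosen so a complete benchmark report
builds in about a minute on one CPU while still exercising every stage.
The acceptance script measures coverage on 80 image–seed pairs per
manipulation (20 derived seeds × both regimes × 2 silhouettes cycled from
the 80-image set), each measured from output pixels rather than placement
bookkeeping.

## Known limitations

* Nothing here is trained on ImageNet; zoo weights are seeded
  initialisations (plus desk-scale fine-tuning), so absolute model
  accuracies are not comparable to published full-scale results — the
  package reproduces the apparatus and its structural guarantees, not the
  headline behavioural numbers.
* The NumPy backend is single-threaded and float64; it is built for
  transparency and testability at desk scale, not throughput.
* CS follows the public architectural description; numerical equivalence
  to released checkpoints is out of scope.
* Exact per-layer channel plans of the custom variants (CD/BD widths,
  B-family plan) are package choices made to satisfy the stated
  parameter-matching design intent, as documented above.
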