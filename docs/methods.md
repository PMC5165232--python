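# Methods

This note records the model, the numerical conventions, and the design
choices that were genuinely open, so that results produced with the
toolkit can be interpreted precisely.

## Texture features

Images are quantized to G uniform bins over [0, 255] before any
second-order statistic; G = 8 by default. The choice keeps co-occurrence
matrices dense on small regions of interest and follows common practice
for Haralick-style features; it is configurable everywhere.

**Run-length matrices.** A run is a maximal sequence of equal-valued
pixels along one of the four principal directions. At 45°/135° runs are
enumerated along every diagonal, so all pixels are scanned in every
direction and the conservation identity Σ j·p(i,j) = n_pixels holds for
all four. Eleven descriptors are implemented (SRE, LRE, LGRE, HGRE,
SRLGE, SRHGE, LRLGE, LRHGE, GLNU, RLNU, RPC); the feature vector uses the
six emphasis descriptors. Conventions:

- Indices inside formulas are 1-based (gray index i = bin + 1, run length
  j = length). The low-gray-emphasis terms divide by i², which would be
  undefined for a 0-based first bin.
- The gray-level and run-length non-uniformities square the *inner* sums:
  GLNU = (1/nr) Σ_i (Σ_j p)², RLNU = (1/nr) Σ_j (Σ_i p)² — the standard
  reading of formulas that are typeset ambiguously in the literature.
- The run-percentage coefficient is defined here as RPC = nr / n_pixels
  (runs per scanned pixel, in (0, 1]); the literature formula for this
  descriptor is not a well-formed scalar, so this substitute is a
  documented deviation. RPC is not part of the 12-feature vector.

**Co-occurrence matrices.** Pair counting is delegated to
`skimage.feature.graycomatrix`; the angle mapping is chosen so that 45°
means the up-right displacement (−d, d), the usual texture convention.
Matrices are symmetric by default (both displacements counted) and
normalized to sum to 1. Measures follow the classical definitions with
these conventions:

- entropy = −Σ p ln p with 0·ln 0 = 0 (natural log);
- homogeneity = Σ p / (1 + |i−j|);
- variance = ½ Σ [(i−μ_i)² + (j−μ_j)²] p with per-axis marginal means
  (identical for symmetric matrices); exactly 0 for a uniform image;
- correlation = Σ (i−μ_i)(j−μ_j) p / (σ_i σ_j), defined as 0 when a
  marginal is degenerate (constant image), avoiding 0/0;
- inverse difference moment sums off-diagonal p/|i−j|^k (k = 2 default)
  as printed in its source; homogeneity is the bounded variant used in
  the feature vector;
- cluster tendency = Σ (i + j − μ_i − μ_j)² p.

The GLCM distance defaults to d = 1: the fine/coarse contrast the
features are meant to capture presumes a displacement small relative to
the texture element size.

## Segmentation

The region extractor is deliberately minimal: threshold (strictly
greater-than; Otsu's method when no threshold is given), opening then
closing with a disk structuring element (radius 2 default), then the
largest 8-connected component. Opening removes bright speckle smaller
than the disk — including the corners of rectangular regions, which is
visible in exact pixel counts — and closing fills comparable gaps.
There is no lung-field extraction or vessel suppression; the extractor
assumes a single dominant bright region.

Whether features are computed on the whole image or on the segmented
region's bounding box is configurable (`feature_scope`); the default is
the segmented region, falling back to the whole image when the extractor
returns nothing.

## Real-coded genetic algorithm

Chromosomes are real vectors in [−5, 5] per gene (configurable); fitness
is the quantity minimized (training MSE). Defaults: population 30, 100
generations, crossover probability 0.1 per selected pair, mutation
probability 0.01 per gene, BLX μ = 0.5, mutation shape q = 2.

- **Selection**: roulette wheel on weights s_i = 1/(f_i + ε), ε = 1e−12.
  The wheel is proportional to the transformed fitness, so lower MSE gets
  wider slots; all-zero weights degrade to a uniform draw.
- **Crossover** (BLX-μ): offspring gene uniform on [v₁ − μΔ, v₂ + μΔ]
  with Δ = v₂ − v₁ after ordering; draws outside the gene bounds are
  resampled (capped at 100, then clamped). μ = 0.5 is reported to work
  best for this operator and is the default.
- **Mutation** (nonuniform): with a fair coin λ, the gene moves toward
  the upper (λ=0) or lower (λ=1) bound by Δ(n, y) = y(1 − β^{(1−n/N)^q}),
  β ~ U(0,1). The λ draw precedes the β draw, fixing the stream order for
  reproducibility. Steps span the range early and anneal to zero as
  n → N; Δ(n, y) ≤ y keeps every gene in bounds. The operator's published
  description swaps "upper" and "lower" in prose; the implementation
  moves toward the bound named in each branch, the formula's evident
  intent.
- **Survivor rule**: after crossover/mutation the offspring replaces its
  first parent only if its fitness is not worse — the greedy competition
  the operator description prescribes. One elite (the best-ever
  chromosome) is copied into each generation, which makes the best-ever
  trace non-increasing by construction.
- **Restarts**: the reported protocol runs 30 independent trials of the
  whole flow; `RCGAConfig.restarts` exposes this (default 1), stopping
  early once `target_fitness` is reached. The optimization benchmark in
  the acceptance tests uses the 30-trial protocol.

Integer-coded biases appear in one description of this algorithm family;
all genes here are continuous, since the gradient phase updates biases
continuously and a mixed encoding would be internally inconsistent.

## Gaussian-activation network

Topology 12-3-5 by default (inputs = features, one output per class).
Both layers apply g(x) = exp(−(x/σ)²) with spread σ = 3; the derivative
used in backpropagation is the true one, g′(x) = −(2x/σ²)g(x). The
network is *not* a centre-based radial basis expansion: hidden units
compute weighted sums plus bias, and the Gaussian is applied to the sum.
An alternative centre-based output form exists in the source literature
but is not what the detailed training algorithm updates, so it is not
implemented.

Training is per-pattern (online) gradient descent with momentum
(learning rate 1, momentum 0.2, both configurable), with a seeded
shuffle of the presentation order each epoch. Weights initialize
uniformly in [−0.5, 0.5]. The per-sample loss behind the error terms is
E = ½ Σ_k (t_k − y_k)²; the reported MSE is the mean over samples and
output units of (t_k − y_k)².

**Hybrid loop.** After each epoch the epoch MSE is compared with the
previous one; if the relative improvement stays below 1e−4 for 10
consecutive epochs (`stall_patience`), the RCGA is invoked: the current
best parameters are encoded as one chromosome (clamped to the gene
bounds), the rest of the population is uniform in bounds, fitness is the
training-set MSE of the decoded network, and the evolved best replaces
the parameters only if it improves the best MSE ever observed. Momentum
state resets after an adopted GA solution. Training stops at `target_mse`
(default 1e−3) or after `max_iterations` gradient epochs (default 100,
matching the reported iteration budget; GA generations are counted by
their own budget, since the two iteration notions are distinct).
The function always returns the best-ever parameters, so the best-MSE
sequence is non-increasing even across GA phases.

Prediction takes the argmax of the five outputs, ties broken toward the
lowest class index. One-hot targets with Gaussian outputs in (0, 1] make
the zero-error target exactly representable only in the limit, so
`target_mse` is a practical floor, not an attainable zero.

## Synthetic data

The texture generator tiles an image with constant blocks whose gray
levels are i.i.d. draws from a per-class distribution, then resamples
each pixel with a small probability (default 0.05). Block size 1 yields
fine texture (short runs), large blocks coarse texture (long runs) —
exactly the contrast the run-length features measure. The five default
archetypes use block sizes 1, 2, 4, 8, 16 with gray-level distributions
peaked at different levels, standing in for four nodule types plus
healthy tissue; the mapping to clinical classes is arbitrary and no
anatomical realism is claimed. The nodule phantom is truncated-normal
background noise (clipped to [0, 255]) plus a brighter disk with an
exact mask.

What passing tests on these data do and do not show: they demonstrate
that the feature extractor separates texture statistics it is designed
to separate, that the hybrid optimizer can fit the classifier to
separable data, and that the whole pipeline is deterministic under
seeds. They do not demonstrate clinical performance: real CT nodules
differ from block textures in noise spectrum, partial-volume effects,
anatomy and class overlap, and no claim about accuracy on clinical data
follows from the synthetic benchmarks.

## Evaluation

Sensitivity, specificity and accuracy are reported in percent. For two
classes the usual positive-class (label 1) definitions apply; for more
classes, one-vs-rest values are macro-averaged over the classes present
in the truth vector (absent classes are excluded with a warning). AUROC
is the macro-averaged one-vs-rest area computed from raw scores by the
rank statistic — invariant under monotone score transforms; binary areas
come from scikit-learn, the macro reduction is done here because
scikit-learn's multiclass interface requires probability rows that sum
to 1, which raw Gaussian outputs are not. Cross-validation is stratified
round-robin k-fold or leave-one-out (`n_splits=None`); each fold trains
from scratch with a fold-derived seed and min-max feature scaling fitted
on the training fold only (raw descriptor ranges span orders of
magnitude and would saturate the Gaussian units).

## Problem sizes

The shipped benchmarks use sizes chosen for a desk-scale, fully
synthetic study: 32×32 texture images, 30 samples per class (150 total),
5-fold cross-validation, 20-seed repetitions for stochastic claims, and
the 5-dimensional sphere for the optimizer benchmark. All are arguments,
not constants.

## Known limitations

- The feature set is fixed to second-order statistics; no first-order,
  wavelet or LBP features.
- The segmenter has no anatomical priors and will happily return any
  bright blob.
- Roulette selection with the 1/(f+ε) transform is scale-sensitive when
  all fitnesses are nearly equal (weak selection pressure); this is
  inherent to fitness-proportionate selection.
- With the reported operator probabilities (0.1 crossover, 0.01
  mutation) a single GA run explores slowly; the 30-trial restart
  protocol is the intended remedy and is what the optimization benchmark
  uses.
- LOOCV retrains the full hybrid per sample and is quadratic-ish in
  dataset size; prefer k-fold for datasets beyond a few hundred samples.
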