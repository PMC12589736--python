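# Methods

## Enhancement

The enhancement operator is linear filter fusion: `out = clip(mean5×5(I) −
∇²I, 0, 1)`, applied per channel for RGB tiles. The box mean replaces each
pixel by the average of its 25 neighbours; the Laplacian is the fixed
4-neighbour stencil `[0,1,0; 1,−4,1; 0,1,0]`, whose response is *not*
clipped (it is a signed derivative). Subtracting the negative-centre
Laplacian adds the edge response onto the smoothed image, the classic
sharpening construction. Borders use edge-including reflection for both
filters — constant-zero padding would create dark halos on bright
histology tiles. The subtraction can leave [0, 1]; the result is clipped
rather than renormalised so that the global contrast scale is preserved.
Note that this construction amplifies pixel noise (the Laplacian of i.i.d.
noise has ≈ √20 × its standard deviation), which is why the segmenter
smooths its driving image (below).

## Segmentation

Segmentation is a two-phase region-based active contour: the lesion
boundary is the zero level set of φ (inside ≡ φ > 0) and evolves by
gradient descent on

    G = Σ_outside (I − m₁)² + Σ_inside (I − m₂)² + β·length(C).

Descent velocity: `δ_ε(φ)·[β·κ + (I − m₁)² − (I − m₂)²]` with κ the
curvature of the level lines and δ_ε the smoothed Dirac mollifier
(ε = 1 px). An optional edge-stopping factor `1/(1+|∇I|²)` on the data
force is available but off by default, since the energy above contains no
edge term.

Numerical choices, each of which matters in practice:

- **Contour length by marching squares on the sign partition.** The length
  term then depends only on which pixels are inside, so the energy is
  invariant under re-initialisation of φ and the trace is comparable
  across steps. (A smoothed-Heaviside gradient integral — the other
  standard estimator — changes value when φ is reshaped at a fixed
  contour.)
- **Velocity normalisation.** The raw mollified velocity moves the contour
  sub-pixel per step; each step is scaled so the fastest point advances
  `dt` pixels (CFL-style), with `dt = 0.5` by default.
- **Backtracking.** A step that would raise the energy is retried with
  halved `dt` (≤ 8 times) and rejected if still ascending, so the energy
  trace is non-increasing by construction and `final ≤ initial` holds on
  every run.
- **Pre-smoothing.** The image driving the evolution is Gaussian-smoothed
  (σ = 1 px by default). Strict monotone descent on a noisy image freezes
  in single-pixel local minima — a flip set that helps collectively is
  rejected because its first pixel ascends; smoothing removes those
  traps. Reported region means (m₁, m₂) are always computed exactly on the
  *input* image.
- **Re-initialisation and stopping.** φ is rebuilt as a signed distance
  every 20 iterations (accumulated updates flatten it near the contour and
  freeze the evolution). Convergence requires the relative energy change
  to stay below `tol = 1e-4` for 25 consecutive steps — longer than the
  re-initialisation interval, so a stalled contour is always given fresh
  dynamics before the run is declared converged. Cap: 300 iterations.
- **Initialisation** is a centred circle of radius 0.4·min(H, W) (signed
  distance); a checkerboard initialiser is available.
- **Polarity.** The side of the contour whose mean lies farther from the
  image median is labelled foreground ("lesion"); on H&E-like material the
  nucleus-dense lesion is the atypical-intensity side. A constant image is
  rejected as degenerate rather than silently returning a full or empty
  mask.

Masks are post-processed by removing components below 0.5 % of the image
area, filling holes, and keeping components at least half the largest
component's area. The ROI export keeps the original (pre-enhancement) RGB
pixels under the mask and zeros elsewhere; in the pipeline, segmentation
runs on the enhanced grayscale tile and masking applies to the original.

## Features and fusion

Extractors are pluggable: anything mapping an image to an H×W×C spatial
feature map behind `ExtractorSpec` (a deterministic contract with a
declared channel count). Pooling operators are the square-window forms:
max/average pooling with window k and stride p (output `⌊(H−k)/p⌋+1`
square), and global average pooling collapsing a map to its per-channel
spatial mean. Feature matrices carry sample ids, labels, and a provenance
list of (extractor, width) pairs whose widths must sum to the matrix width
— fusion is row-wise end-to-end concatenation in the given order, which is
associative and order-preserving. No column normalisation is applied by
default. The shipped stand-in extractors (below) declare the documented
widths 1024/1664/2048 for the "resnet50"/"densenet169"/"mobilenet"
presets; real pretrained backbones can be wired behind the same contract.

## Ant-colony feature selection

Subset construction draws `subset_size` distinct features sequentially
without replacement with probability ∝ τ_j^α · η_j^γ, realised with the
Gumbel-top-k equivalence. τ starts uniform at τ₀; η is the per-feature
one-way ANOVA F statistic against the class label (zero-variance features
score 0). Because the rule is multiplicative, a feature with η = 0 would
otherwise be unreachable forever even though a marginally-useless feature
can matter jointly; construction therefore adds an exploration floor of
`0.1 × mean(η)` to η. The objective is mean stratified 3-fold accuracy of
a depth-8 decision tree on the subset's columns (the final model is
trained separately and deeper). After each iteration all trails evaporate
by (1−ρ) and the iteration-best subset deposits `Q·score` on its features
(elitist deposit sharpens convergence); τ is floored at 1e-12. The run
stops at `max_iters` or when `1 − best_score ≤ error_threshold`. Defaults:
20 ants, ρ = 0.1, τ₀ = 0.1, α = γ = 1, Q = 1, 100 iterations, error
threshold 0.01. A `greedy` flag replaces sampling by top-k weights (the
"always follow the strongest trail" reading of the construction rule).
Published per-combination subset sizes are kept as defaults in printed
order: ResNet50+DenseNet169 → 625, DenseNet169+MobileNet → 690,
ResNet50+MobileNet → 720, triple fusion → 810.

## Partitioning, augmentation, classifiers

The split reserves 40 % of each class for testing and divides the
remaining 60 % pool 90:10 into train/validation, flooring at each stage
(5,000 per class → exactly 2,700/300/2,000); members are shuffled with the
split seed first. Augmentation applies only to training images: each
yields itself plus `copies_per_image` (default 5) warps with rotation
±15°, x/y shift ±10 %, shear factor ±0.10, zoom ±5 %, horizontal flip
p = 0.5, drawn from one seeded stream and warped with reflect boundary
fill; a pass-through mode covers feature-only pipelines (the default
pipeline extracts features from originals only). The decision tree uses
Gini impurity with unbounded depth; the random forest bags 200 trees with
√D feature subsampling and majority voting, all seeded. Probability scores
are leaf class frequencies (DT) or tree-vote fractions (RF).

## Evaluation and comparison

Per-class metrics are one-vs-rest percentages from the confusion matrix
(rows = true): sensitivity TP/(TP+FN), precision TP/(TP+FP), specificity
TN/(TN+FP), accuracy (TP+TN)/total, F1 the harmonic mean of precision and
sensitivity. Macro values are unweighted means over classes; overall top-1
accuracy is reported additionally. A zero-denominator metric is reported
as None (undefined), never silently 0. AUC is the trapezoidal one-vs-rest
ROC area (equal to the tie-corrected Mann–Whitney statistic), macro AUC
its mean over classes. Two models evaluated on the same test split are
compared by a one-sided paired t-test over per-class F1 (H₁: the first
model is higher), df = n−1 with the sample (n−1) standard deviation,
α = 0.05; zero-variance differences yield a flagged ±∞ t (or a flagged
no-difference result when Δ = 0). Reports print one decimal for per-class
metrics, two for macro rows.

## Synthetic data

The tile generator emulates the pipeline's assumed structure, not real
histology: a bright stroma background (intensity 0.85), one smooth lesion
blob per tile (a radially perturbed disk at an area fraction drawn from
[0.25, 0.45]), dark "nuclei" disks (intensity 0.20) Poisson-placed inside
the lesion, Gaussian pixel noise (σ = 0.05), and an eosin-like RGB tint.
Classes differ in three texture cues, as tissue types differ under H&E:
nucleus density (1.5/10/4.5/7/12 expected per 1,000 lesion pixels),
nucleus radius range, and lesion stain uptake (0.52–0.72); the densities
and radii were chosen so that total nucleus coverage stays below
saturation, keeping density informative. Nuclei are darker than stroma so
segmentation polarity matches real hematoxylin contrast. Every generator
is a pure function of (spec, seed); tiles default to 256×256.

What passing tests show — and don't: the synthetic classes are separable
from local texture statistics by design, so end-to-end results certify
that the pipeline's stages compose correctly and losslessly enough to
carry a texture signal, not that any particular accuracy transfers to real
stained tissue (no stain variability, no nuclear pleomorphism, no tissue
architecture). The noisy-disk benchmark (64×64, foreground 0.8 /
background 0.2, σ = 0.05) isolates the segmenter.

The stand-in extractor satisfies the backbone contract deterministically:
the grayscale image is resized, an n×n grid (4/8/6 cells for the three
presets) of 8 local statistics (mean, std, gradient mean/std, two
dark-pixel fractions, mean |second difference|, non-black fraction) is
computed, and a fixed seeded random projection maps the statistics to the
declared channel count through tanh. It carries class-discriminative
texture information without trained weights; it is not a CNN and makes no
claim to CNN-like invariances.

The planted-feature generator produces labelled Gaussian matrices in which
k known columns get class-dependent means spaced by the effect size (noise
σ = 1) and the rest are pure noise, with shuffled column order and the
truth recorded — the ground-truth harness for the selection search.

## Pipeline

One YAML-able config drives enhance → segment/ROI → extract (per
extractor) → fuse → split → ant-colony selection (fitted on training rows
only, so the search never sees test data) → train DT/RF → evaluate →
compare. Every stage writes artifacts plus a manifest with sha256 hashes,
per-stage seeds (derived from the global seed by a stage-name CRC) and
timings; with `resume=True` existing artifacts are reused, so deleting a
downstream artifact recomputes only downstream stages. A tile whose
segmentation degenerates falls back to the whole-tile mask rather than
aborting the run. The desk-scale benchmark configuration uses 5 classes ×
40 tiles of 128×128 with 10 ants × 10 iterations of selection — sizes
chosen so the whole benchmark, including two full runs for the
reproducibility check, completes in minutes on one CPU; trees are trained
on the training partition only (validation is reserved for tunable
models; trees here have nothing to tune).

## Known limitations

- The level-set is two-phase: one lesion region per tile, no
  multi-lesion/multi-phase support (post-processing can keep several
  near-equal components, but they share one intensity model).
- Monotone-descent segmentation can under-segment when the true boundary
  requires a transiently energy-increasing move that pre-smoothing does
  not resolve.
- The ANOVA heuristic scores features marginally; interactions guide the
  search only through the pheromone feedback.
- The synthetic benchmark is a composition check, not a claim about real
  tissue (above).
- The F1 paired t-test over five class scores has n = 5 pairs; its power
  and normality assumptions are accordingly weak.
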