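# Methods

## Problem and approach

`localcount` implements local-count regression for counting dense, non-rigid
objects — wheat spikes at heading stage are the motivating case — from images
annotated with one dot per object. Instead of detecting instances or
regressing a per-pixel density, the model maps each local window of the image
to the number of annotation dots inside it. Local counts tolerate the severe
occlusion and size/pose variation of field imagery because they never require
resolving individual instances, only window-level mass.

The central design idea is *context*: the network's input region (its 94×94
receptive field) is deliberately larger than the 64×64 window whose count it
regresses. The 15-pixel annulus around the window is visible to the network
but its objects are not counted. Objects straddling a window border are
locally ambiguous — the visible fragment does not reveal on which side the
centroid lies — and the context resolves much of that ambiguity. Two
ablations probe this: training on bare 64×64 patches (no context), and
regressing the count of the whole 94×94 receptive field (no margin —
"del-c").

## Architecture as data

Networks are declared as an ordered list of layer descriptions (kernel,
stride, padding, channels), from which everything else is derived: the
runnable model, the receptive-field geometry, multiplication FLOPs and
parameter counts. The canonical fully convolutional stack is

    conv1 3×3×3→16 pad 1 · pool 2×2/2 · conv2 3×3×16→32 pad 1 · pool 2×2/2 ·
    conv3 3×3×32→64 pad 1 · conv4 3×3×64→64 pad 1 · conv5 3×3×64→64 pad 1 ·
    pool 2×2/2 · conv6 8×8×64→128 /2 · conv7 1×1×128→128 · conv8 1×1×128→1

Geometry follows the standard recursions r_l = r_{l−1} + (k_l−1)·j_{l−1},
j_l = j_{l−1}·s_l, p_l = p_{l−1} + pad_l·j_{l−1}: receptive field 94, output
stride 2⁴ = 16, and the per-layer paddings of conv1–conv5 accumulate to
exactly 15 zero pixels per border, so the output grid on an H×W image is
⌊(H+30−94)/16⌋+1 per axis (54×73 at 912×1216). Weight-only parameters total
638,000; biases and batch-norm affine terms are counted separately because
the headline capacity figure conventionally excludes them. FLOPs count
single-precision multiplications only (k_h·k_w·C_in·C_out·H_out·W_out per
conv; pooling costs none), in exact integer arithmetic, rounded to three
significant digits only for display. Patch-mode accounting takes a
caller-supplied patch count because dense-sampling patch grids are a
sampling choice, not a property of the network.

The patch variants share kernels and channel widths with the fully
convolutional stack (identical weight counts): the no-context network keeps
per-layer padding and consumes 64×64 patches; the context network removes
all padding and consumes 94×94 patches. Removing padding converts wasted
(zero-filled) receptive field into real context without adding capacity.

## Ground truth

Each dot becomes a unit-mass Gaussian kernel (σ = 4 px, truncated at 4σ,
evaluated at pixel centers). Every kernel is renormalized to unit mass
*after* truncation and border clipping, so the density integral equals the
dot count exactly regardless of where dots sit; this insulates the targets
from the classic inaccuracy of clipped border kernels. Local-count targets
integrate the density (via a summed-area table, so each entry is exact) over
the stride-16 lattice of windows. The lattice is defined by the network
geometry: cell (i,j) owns the receptive field at 16·(i,j) − 15 on the padded
canvas and its target is the count inside the central 64×64 square, which
starts at 16·(i,j) in image coordinates. The del-c target instead integrates
the full 94×94 field (window 94, context 0, same grid). Coordinates are
0-based pixel centers, x = column; windows are half-open.

## Training

Batch normalization follows every convolution except the final 1×1 count
layer; ReLU follows each batch norm. Weights use He ("improved Xavier")
initialization; optimization is plain SGD from learning rate 0.1, reduced
×0.1 when validation image-level MAE fails to improve for a configurable
patience (default 10 epochs; the desk benchmarks use 4–5). The loss is mean
absolute deviation of local counts (ℓ1; ℓ2 is available) — robust to the
heavy-tailed window counts of clustered scenes. Inputs are scaled to [0,1]
and per-channel means of the training split are subtracted; no augmentation
is applied. Negative outputs are clamped to zero at inference only, so
training gradients are never gated. Patch-mode training samples the dense
stride-16 patch lattice of each padded image — the same supervision the
fully convolutional mode sees. Best-validation weights are retained. All
randomness (split, initialization, shuffling) flows from explicit seeds;
runs are bit-reproducible. The networks are built on a small NumPy layer
engine (im2col/GEMM convolutions with reverse-mode gradients) whose
gradients are verified against central differences in the test suite.

## Inference and count maps

A whole image passes through the network once; every stride-16 window's
count appears in one forward pass (identical, to ≤1e-4, to cropping each
94×94 receptive field and forwarding it separately — an equivalence the
tests enforce on interior cells). Because adjacent windows overlap 16-fold,
the raw grid is merged: each window's count is spread uniformly over its
footprint (c/4096 per pixel, footprints clipped to the canvas), and each
pixel is divided by its coverage multiplicity, computed after clipping so
border pixels are not under-weighted. The integral of the merged map is the
image count. On interior regions the merge is exactly a mass-conserving
triangular smoothing of the window grid (per-axis weights (4−|d|)/4,
|d| ≤ 3) — the tests assert this closed form — and ground-truth grids
re-integrate to the true count within 1% when all object mass lies at least
one window from the borders. Pixels near the canvas border have reduced
coverage; windows carrying mass into that ring bias the integral upward,
which is why the conservation guarantee is stated for interior mass.

## Synthetic scenes

The generator exists to exercise the pipeline end to end with exact ground
truth: elongated objects (length 15–60 px, aspect 2–5, uniform orientation)
composited back to front over a low-frequency canopy texture, with global
gain/gamma jitter and optional Gaussian blur (σ ≤ 3). Object centers follow
a Thomas-style cluster process (Poisson parents, multinomial offspring
assignment, isotropic scatter) conditioned on the per-image count, which is
drawn uniformly from the configured range (defaults 0–1462 on a 912×1216
canvas, matching in-field spike statistics). The annotation dot is exactly
the rendered centroid.

Object bodies are flat-topped super-Gaussians (exp(−½·r^{2s}), default
sharpness s = 3) rather than soft Gaussian blobs. This matters for the
context ablations: with a pure Gaussian profile, an object's pixel mass is
distributed around its centroid exactly like the σ-smoothed dot mass, so
window brightness becomes a sufficient statistic for the local count and
context cannot help; solid bodies with hard edges reproduce the boundary
ambiguity (visible fragment, invisible centroid) that makes context
informative for real spikes. Setting sharpness 1 recovers the soft blob.

What the generator does **not** emulate: real spike morphology and texture,
perspective scaling, correlated lighting fields, background clutter that
mimics objects, and annotation noise. Passing tests therefore demonstrate
the correctness and internal consistency of the pipeline and the
*direction* of the context effects, not field-level error magnitudes.

## Desk-scale benchmark conditions

The ablation benchmarks are sized for a single CPU: the fully convolutional
pair (central-window target vs full-field target) trains on 30 scenes of
160×160 px with 40–100 objects for 25 epochs (validation split 0.2) and
tests on 12 scenes; the patch pair (context vs no context) trains on 20
scenes of 128×128 px with 30–80 objects for 28 epochs (validation split
0.2) and tests on 20 scenes — the context network converges more slowly
than the context-free one but to a better optimum, so the patch pair gets
the longer epoch budget. Counts per area sit at or above the field
dataset's density so occlusion and border traffic are plentiful. Because a
single training of these small models on small data is noisy relative to
the effect, each benchmark trains every variant twice with
paired run seeds — both variants of a pair share scenes, initialization
and schedule within each repeat — and compares test MAE averaged over the
repeats. Absolute MAEs at this scale are not comparable to field-scale
results; only orderings are interpreted.

A subtlety of the full-field ablation: its 94-px windows overhang the image
border (offset −15), and the aggregation convention deposits c/window² per
covered pixel, so overhanging windows contribute only their in-canvas
share. This mildly deflates the full-field variant's image integrals — an
intrinsic property of pairing a full-receptive-field target with this
normalization, and one ingredient of its worse image-level error.

## Numerical choices and edge cases

- Integer arithmetic throughout the cost/geometry calculators; no floats
  until display.
- Summed-area tables for window integration; cumulative-sum round-off is
  guarded by clamping tiny negatives to zero.
- Max pooling is non-overlapping 2×2/2; odd trailing rows/columns are
  dropped (floor arithmetic), matching the shape calculator.
- Ties in max pooling route the gradient to the first maximum.
- Images too small for one output cell raise a geometry error naming the
  offending layer; mismatched target/output grids are detected before the
  first optimization step.
- A patch of the wrong size is rejected unless the caller explicitly allows
  the mismatch (the information-asymmetry probe of evaluating a
  context-free model on context-sized patches).
- Relative counting accuracy, 100·(1 − MAE/mean true count), is undefined
  and an error when the mean true count is zero.

## Known limitations

- The merge's conservation guarantee degrades when a large fraction of
  object mass lies within one window of the border (small canvases).
- Patch-mode training materializes the full patch lattice in memory;
  appropriate at desk scale, wasteful for large images (the fully
  convolutional path is the intended route there).
- The NumPy engine is single-threaded BLAS-bound; no GPU path.
- Batch-norm statistics with very small batches are noisy; benchmarks use
  batch sizes ≥ 4 images / 32 patches.
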