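# Methods

This note documents the models, numerical choices and open design
decisions behind `wmh3d`, and what the desk-scale tests do and do not
demonstrate.

## Problem setting

White matter hyperintensities (WMH) appear as bright, high-contrast
lesions against darker brain tissue on FLAIR MRI. The package implements
a two-stage pipeline: pixel-level binary segmentation of each 2D slice by
a convolutional encoder/decoder, followed by surface reconstruction of
the segmented slice stack into a triangle mesh for visualization and
volumetry. All coordinates follow one convention: voxel index order is
(slice, row, col), voxel centers at integer coordinates, and meshes are
emitted in millimetres with x = col·pixel_spacing, y = row·pixel_spacing,
z = slice·slice_spacing.

## Segmentation network

A symmetric U-shaped network of depth 4: four encoder stages joined by
2×2 max-pooling, a bottleneck, and four decoder stages that upsample with
2×2 transposed convolutions (stride 2) and concatenate the matching
encoder feature map. Stage widths double per level (64→128→256→512, 1024
bottleneck at production defaults). The head is a 1×1 convolution with a
sigmoid giving a per-pixel lesion probability.

Each stage is a double 3×3 convolution block, `conv → BN → ReLU → conv →
BN`, closed by a ReLU. With `use_residual` an identity shortcut (1×1
projection + BN when widths change) is added before the closing ReLU.
With `use_cbam` a CBAM attention block follows every encoder and decoder
stage: first a per-channel gate computed by pushing the global
average-pooled and global max-pooled channel descriptors through a shared
two-layer MLP (hidden width C/r, ReLU in between, no biases) and summing
before the sigmoid; then a per-pixel gate from a 7×7 convolution over the
stacked channel-mean and channel-max maps. Both gates lie strictly in
(0, 1) and multiply the features they were computed from.

Choices the network description leaves open, and how they were fixed:

- **Channel widths** 64·2^i with a 1024 bottleneck — the standard U-Net
  progression.
- **Reduction ratio** r = 16 by default, the conventional CBAM value;
  every gated stage width must be divisible by r.
- **MLP hidden activation** ReLU, following the original CBAM design.
- **Head** single sigmoid channel: the task is binary.
- **Batch normalization** is not part of the textbook description but is
  essential here: without it a 4-level network saturates its output
  sigmoid already at initialization (observed logit magnitudes > 50) and
  the Dice loss cannot recover. Every convolution in a stage block is
  therefore batch-normalized, the standard recipe for this family.
- **Attention initialization is neutral**: the second MLP layer and the
  7×7 spatial kernel start at zero, so every gate is exactly 0.5 (a
  constant scaling the next BN absorbs) until attention has learned
  something. Without this, randomly initialized gates act as structured
  noise that measurably slows convergence in short training budgets.
  Gradients reach the zero-initialized layers immediately (their inputs
  are nonzero), so nothing is permanently dead; the "no dead branches"
  test randomizes these layers before checking gradient flow.
- **Ablation pairing**: the convolutional trunk and the attention blocks
  draw their initial weights from two generator streams spawned from the
  same seed, so U-Net / ResU-Net / Attention-U-Net at equal seed share
  identical trunk initializations and differ only in the toggled
  component.

### Loss and metrics

Training minimizes the soft Dice loss 1 − (2Σpt + ε)/(Σp + Σt + ε) with
ε = 1.0 in numerator and denominator; ε stabilizes batches with empty
masks and makes the loss exactly 0 when prediction and target agree
(including the all-empty case). Evaluation binarizes probabilities at
0.5 and reports the Dice overlap (defined as 1.0 when both masks are
empty) and the mean pixel accuracy over the two classes (background,
lesion); a class with no pixels is excluded with a warning.

### Optimization

Adam at the initial learning rate 0.001 (no schedule), 30 epochs at the
production input size 512×512 with batch size 4. At the 64×64 desk scale
used throughout the tests, training runs 15 epochs with batch size 2:
with only 32 training slices, larger batches leave too few gradient
updates (15 epochs × 2 updates at batch 16 demonstrably cannot converge),
while batch 2 gives 240 updates and converges reliably. After the last
epoch the batch-norm running statistics are replaced by exact moments
over the training set (precise recalibration); with only a few hundred
updates the exponential running estimates otherwise lag far enough behind
to shift inference-time probabilities visibly.

Test-time augmentation averages the probability maps of inverse-mapped
predictions over identity, horizontal flip, vertical flip and 180°
rotation — a minimal set of exactly invertible transforms.
Cross-validation trains one fresh model per fold and reports mean ± sd
of Dice and MPA.

### Data handling

Splits are assigned at the **patient** level (8:2 train:test by item
count, greedily balanced over shuffled patients), because adjacent slices
of one patient are near-duplicates and slice-level splitting would leak.
The five cross-validation folds partition the training patients; the test
split is never touched by CV. Histogram equalization is the classic
global per-slice remap onto 256 gray levels through the cumulative
distribution; it is monotone, idempotent up to one gray level, and leaves
constant slices unchanged. It enhances real FLAIR lesion contrast but
*amplifies noise on the synthetic phantoms* (their contrast is already
high), so the phantom experiments run without it.

## Phantom generator

The generator emulates the features of FLAIR lesion imaging that the
pipeline actually exercises: a dark elliptical "brain" (intensity 0.30,
semi-axes 0.42 of the image size) on a near-black field (0.02), smoothed
Gaussian tissue texture (sd 0.03), and n ellipsoidal lesions with
in-plane semi-axes drawn from 3–7 px, through-plane semi-axes about half
that, intensity +0.35, Gaussian-softened rims (σ = 1 voxel) and i.i.d.
noise (sd 0.05), clipped to [0, 1]. The ground-truth mask thresholds the
*unsmoothed* ellipsoids, so it is voxel-exact by construction, and each
lesion spans a contiguous slice run (its 3D component is connected).
Texture, lesion geometry and noise come from three independent generator
streams spawned from one seed, so equal seeds give bit-identical phantoms
and the lesion geometry is reproducible independently of the noise
settings. Default test-scale images are 64×64×16; the production input
size 512×512 remains configurable.

What the phantom does **not** model: anatomy (gyri, ventricles, skull),
MR physics (bias fields, partial-volume effects, Rician noise), lesion
texture heterogeneity, or inter-scanner variation. Passing the phantom
tests therefore shows that the pipeline's mechanics are correct and that
the architecture can learn high-contrast blob segmentation from ~30
slices; it does not certify clinical performance on hospital FLAIR data,
which requires the real dataset and full-scale training.

The analytic sphere field r − |p − c| provides a closed-form isosurface
(area 4πr², volume 4/3πr³) for mesh validation. Tests place the center
at half-integer coordinates so no voxel value ever equals the iso level
exactly (no degenerate crossings by a parity argument).

## Surface reconstruction

Within each cell of 8 voxel samples the field is the trilinear
interpolant f(x,y,z) = a₀ + a₁x + a₂y + a₃z + a₄xy + a₅yz + a₆zx +
a₇xyz; the coefficients are the closed-form finite differences of the
corner values (the 8×8 corner system is invertible, and fitting then
evaluating reproduces every corner exactly). A vertex with value ≥ iso
classifies as *inside* — ties are inside by convention; the interpolation
parameter then degenerates to an edge endpoint and the resulting
zero-area triangles are dropped in a post-pass.

Extraction uses **marching tetrahedra**: each cell splits into 5
tetrahedra (1 central + 4 corner). Because the 5-split is not mirror
symmetric, cells alternate between the two mirror-image splits in a
checkerboard ((i+j+k) mod 2) pattern, which makes face-adjacent cells
induce the same face diagonal — the necessary and sufficient condition
for a crack-free surface (verified by an explicit shared-face test). A
tetrahedron has 2⁴ = 16 sign cases: 0 or 4 vertices inside produce
nothing, 1 or 3 produce one triangle, 2 produce a planar quadrilateral
split into two triangles. Crossing vertices are placed by linear
interpolation t = (iso − v₁)/(v₂ − v₁) along the edge, always evaluated
in canonical (ascending grid index) edge order so shared crossings are
bit-identical; vertices are welded by exact edge key (grid-vertex pair),
never by coordinate tolerance. Triangle orientation (normals toward the
lower-valued, outside region) is resolved per (parity, tetrahedron, sign
case) at table-construction time — cell geometry is identical everywhere,
so the flip decision is a compile-time constant. The whole pipeline is
vectorized over active cells; a 64³ volume reconstructs in well under a
second.

The classic marching-cubes state counts are verified independently:
enumerating all 256 corner sign assignments and grouping them under value
inversion gives 128 classes, under the 24 proper cube rotations 23
classes (cross-checked against Burnside's lemma), and under rotations
combined with inversion 15 classes. Marching cubes itself is *not* used
for extraction — its facial ambiguity is the reason the tetrahedral
method exists.

Mesh quality at desk scale: for a radius-20 sphere sampled on a 64³ grid
the extracted mesh is watertight (every edge in exactly two triangles,
Euler characteristic 2) with area within 0.1% and enclosed volume
(divergence theorem) within 0.2% of the closed forms, and both errors
shrink monotonically when resolution doubles. Binary masks are extracted
at iso = 0.5; an optional Gaussian pre-smoothing (off by default)
improves visual quality at the cost of voxel-exact geometry.

Mesh serialization (binary STL, ASCII OBJ, ASCII PLY) goes through
trimesh. STL is a triangle soup, so read-back preserves triangle count
and geometry but not shared-vertex indexing; OBJ and PLY round-trip the
full indexed topology.

## Desk-scale problem sizes

The test suite runs everything at sizes a laptop CPU handles in minutes:
64×64 slices, 32 training slices (two 16-slice phantoms), 15 epochs,
depth-4 networks at base width 8 with r = 4, and 32³/64³ reconstruction
grids. At these sizes the ablation ordering (mean held-out Dice of
Attention-U-Net ≥ ResU-Net ≥ plain U-Net over three seeds) reproduces
qualitatively; the absolute Dice values of full-scale training on
clinical data are outside what synthetic desk-scale runs can or should
match.

## Known limitations

- The autodiff engine is float64 and single-threaded numpy; it is sized
  for desk-scale experiments, not 512×512 production training.
- Histogram equalization is global per slice (no CLAHE).
- DICOM support covers plain single-frame series with standard position
  metadata; no PACS, no multi-frame, no orientation resampling.
- Fields with voxel values exactly at the iso level can produce dropped
  degenerate triangles adjacent to unpaired edges; watertightness is
  guaranteed only for tie-free fields (binary masks at iso 0.5 are always
  tie-free).
- No mesh decimation or smoothing beyond degenerate-triangle removal.
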