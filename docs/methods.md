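# Methods

This note records the models, numerical choices and limitations behind
the package, in the order data flows through the pipeline.

## Phantom model

A phantom is a stack of 16 nested closed surfaces on a cubic DOI
(default 0.24 m, centered at the origin; voxel-centered sampling, arrays
indexed `[ix, iy, iz]`, linear indices x-fastest). Each surface is a
radial map ρ(θ, φ) stored on a 13 × 24 control grid and evaluated with a
bicubic spline (φ padded periodically; polar rows averaged so the map is
single-valued at the poles). The base geometry is a superellipsoid
(semi-axis ratios 1 : 0.85 : 0.8, exponent 2.5, mean outer radius
75 mm — small enough that every antenna stays outside the brain for all
admissible scalings and deformations) with a small seeded smooth
perturbation per tissue. Surface radii follow square-root spacing from
1.0 to 0.15 of the outer radius: shells thicken toward the center, where
the voxel lattice is sparsest, so all 16 regions survive coarse grids
(every region is non-empty at 24³ across seeds; an empty region raises an
error naming the tissue). Tissues are assigned outer-to-inner from a
16-row table of brain-plausible 300 MHz properties (εr ∈ [5.5, 72],
σ ∈ [0.10, 2.22] S/m; the table is a documented stand-in and is fully
overridable — no dispersion model is applied).

The dataset strategy transforms the base phantom per sample:

* **Scaling** — a factor uniform on {0.8, 0.9, 1.0, 1.1, 1.2} scales the
  geometry about the DOI center *and* multiplies each tissue's εr and σ
  (εr floored at 1). The same factor is used for both; an independent
  draw would decouple anatomy from contrast and is not implemented as a
  default because the strategy treats "size and electrical properties"
  as one scale.
* **Boundary deformation** — per tissue, in a seeded random order, every
  control point receives an i.i.d. Normal(0, σ_d²) displacement in x, y,
  z; its radial component moves the control radius and the surface is
  re-interpolated. σ_d defaults to 2 mm (the distribution is specified
  as normal without a scale; 2 mm is a few percent of the head radius
  and below the coarse-grid voxel size, i.e. visible but anatomy-
  preserving). Displacements are clipped so that nesting is preserved
  with a 0.1 mm minimum clearance; a band degenerate to float precision
  pins the surface in place, and a genuinely inverted band raises.
* **Anomaly insertion** — a sphere with radius ∈ {4, 7, 10} mm,
  εr ∈ {90, 120, 150}, σ ∈ {1.038, 1.384, 1.73} S/m; the center is drawn
  uniformly in a ball of radius 0.03 × factor, which keeps the sphere
  inside the deep brain for every admissible deformation. Voxels whose
  centers fall inside the sphere are relabeled; a sub-voxel sphere still
  claims the voxel containing its center.

All draws derive from explicit integer seeds; every operation is a pure
function of its inputs and seed.

## Forward model

Fields use the exp(+jωt) convention; the background is free space
(a matching fluid is available via the background permittivity option).
Transceivers are z-oriented point electric dipoles whose incident field
is the full analytic near+far dyadic expression E = k₀² G(r, r_tx) ẑ,
with G the free-space dyadic Green's function. The same kernel radiates
the induced polarization to the receivers, which makes Lorentz
reciprocity exact in the discrete model.

The volume integral equation is discretized on the phantom grid:

* **Born mode** replaces the internal total field by the incident field;
  it is exactly linear in the contrast χ = ε̃r − 1 and is the default for
  dataset generation (one matrix product per phantom once the
  antenna–voxel Green blocks are cached).
* **Full mode** is a coupled-dipole solve of
  (1 + χ/3) E − K ∗ (χE) = E_inc, with a quasi-static depolarization
  self-term (L = 1/3 for a cubic cell) and the off-diagonal interactions
  applied as an FFT convolution on the doubled grid (the kernel is
  block-Toeplitz). BiCGStab iterates to the requested residual; failure
  raises an error carrying the final residual. The mode is guarded to
  grids ≤ 48³ by default. On ≤ 12³ grids the iterative solution matches
  a dense direct solve of the same discretized operator to better than
  1e-8.

The Born model is physically crude at brain contrast (|χ| up to ~80);
here it serves as a deterministic, well-conditioned measurement operator
for the learning study, with the full mode available for solver-accuracy
checks and small-scale experiments. Data-misfit evaluation reuses the
identical forward code path, optionally on a 1.5× finer grid
(`eval_grid_factor`) to avoid the inverse crime.

**Measurements.** Each of the 60 transceivers transmits in turn; the
other 59 receive three Cartesian components (10,620 raw values). The
network input sums fields per (receiver, component) over transmitters:
M = 180 complex values stored as 360 reals (first all real parts, then
all imaginary parts). Relative noise of level L dB adds complex circular
white Gaussian noise with total power 10^(L/10) × total signal power over
the raw measurement array, before aggregation (noise enters per
measurement, which is the physical reading of receiver noise); the
aggregation is then recomputed. With a fixed seed the realization at two
levels is the same white vector rescaled, so a noise sweep is paired —
this isolates the level effect and keeps sweeps monotone up to model
behavior rather than realization luck.

## Reconstruction network

Each block sub-model maps the (2 × 180) input to a (2, block) volume:

* Encoder: eight 1-D convolutions, channels 32, 32, 64, 64, 128, 128,
  256, 256, kernel sizes 2, 2, 2, 2, 2, 2, 4, 1, down-sampling strides
  2, 4, 2, 4 at layers 1, 3, 5, 7; each followed by batch normalization
  (stabilizing constant χ = 0.001) and ReLU. The fixed kernel/stride
  menu cannot close the shape arithmetic for an arbitrary input length
  on its own, so the builder
  solves the padding of the final strided layer and the final
  length-adapting kernel so the encoder output reshapes exactly to a
  2×2×2×256 feature cube; the full shape trace is attached to the model
  and any impossible configuration raises with the trace.
* Decoder: three 3-D transposed convolutions (128, 64, 32 kernels) with
  per-axis strides solved to approach the block size, ReLU activations.
* Head: one transposed convolution to 2 channels with a kernel solved to
  hit the block shape exactly. The head is linear: batch normalization
  on the regression output demonstrably stalls MSE convergence
  (memorization plateaus at ~5e-3 instead of <1e-3), and the physical
  clamp (εr ≥ 1, σ ≥ 0) is applied after denormalization instead.

There are no fully connected layers; the default model holds ~2.9 M
parameters regardless of how many blocks tile the volume. The output
volume is partitioned into N disjoint blocks (N a perfect cube dividing
each axis), one independently trained sub-model per block, with no
information exchange between sub-models.

Targets are min–max normalized to [0, 1] per channel with statistics
from the training split only; inputs are standardized per element with a
single global scale. Training minimizes MSE with Adam (default lr 1e-3,
batch 16 at full scale; the desk-scale pipeline uses lr 2e-3, batch 25);
all shuffling derives from the run seed, and NaN loss aborts with
diagnostics. The networks run on a numpy layer engine written for this
package (strided-window GEMM convolutions; the transposed convolution is
implemented as one GEMM plus kernel-offset scatter-adds and is the exact
adjoint of the strided convolution, verified by adjointness and
finite-difference tests).

## Enhancement network

The preliminary volume (normalized units) is cut into 2-channel XY
slices, edge-padded to a multiple of 16, and mapped by a 2-D U-Net: four
encoder stages of two 3×3 convolutions + ReLU followed by 2×2 max
pooling, a bottleneck, four decoder stages of a 3×3 up-convolution
(stride 2) with skip concatenation and two 3×3 convolutions, and a 1×1
output convolution. Stage widths double from a configurable base (32 at
full scale, 8 in the desk-scale pipeline). Both channels are enhanced
jointly by one network; all z-slices are pooled into one training set.
Training pairs are slices of stage-1 reconstructions of *training*
phantoms — computed at noise levels cycled through
{none, −10, −20, −30, −40} dB so the enhancer learns to denoise as well
as sharpen — against ground-truth slices. Enhancement of a volume
normalizes, predicts slice-wise, crops, restacks, denormalizes and
clamps.

## Evaluation protocol

Model misfit standardizes each channel by the truth channel norm before
concatenation, so permittivity (tens) and conductivity (units)
contribute equally; per-channel misfits are reported alongside. Data
misfit compares re-simulated scattered fields against the *noise-free*
truth fields — it measures reconstruction fidelity, not the noise
realization. The benchmark evaluates held-out phantoms (a normal case,
and an anomaly case with one phantom per menu radius) at
{none, −10, −20, −30, −40} dB for both stages, averaging per
(stage, level), and writes a CSV plus a JSON sidecar with the
configuration hash and seeds. Anomaly localization thresholds the
reconstructed permittivity (default 85, between the densest tissue and
the anomaly menu), takes the largest connected component and reports
centroid error, equivalent-radius error and mean reconstructed
properties inside the true sphere; absence of supra-threshold voxels is
reported as "not detected", not an error.

## Desk-scale study conditions

The default pipeline configuration — the conditions under which the
package's own benchmark and acceptance tests run — uses a 24³ grid
(10 mm voxels), 100 training phantoms (half with anomalies), an 85/15
train/validation split, 6 normal and 3 anomaly test phantoms sharing the
training base anatomy (held out through their strategy draws, matching a
protocol in which a single base head model underlies all cases), N = 8
blocks of 12³, reduced network widths (encoder 16…128, decoder 64/32/16,
reshape 1³; U-Net base 8), 40 reconstruction epochs and 12 enhancement
epochs. These sizes were chosen so the full generate→train→evaluate
cycle runs in about ten minutes on one CPU while the architecture,
strategy menus and protocol structure are preserved exactly. Full-scale
results (an anatomical base model, GPU training, 256³/512³ volumes) are
outside this package's scope.

## What the synthetic study does and does not show

The generator reproduces the *structure* of the strategy (16 nested
deformable tissues, menu-driven scaling and anomalies) but not human
anatomy: real heads are not nested superellipsoids, tissue dispersion is
ignored, and the Born operator understates multiple scattering at brain
contrast. Passing tests therefore demonstrate that the pipeline's
machinery — geometry, solver, aggregation, networks, metrics — is
correct and that the two-stage scheme behaves as designed
(enhancement helps; quality degrades gracefully with noise), not that
the specific misfit percentages transfer to clinical data.

## Known limitations

* Born-mode training data linearize a strongly nonlinear problem; full
  coupled-dipole data generation is available but slow at 24³ and above.
* The coupled-dipole self-term is quasi-static; sub-percent field errors
  at 10 mm cells are expected relative to a mixed-FEM reference.
* The numpy engine is single-threaded GEMM-bound; it is sized for
  desk-scale studies, not for 256³ training.
* Determinism is exact for fixed seeds on one platform; BLAS vendor
  differences can perturb float32 training at the last digit.
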