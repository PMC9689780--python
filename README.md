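# brainwave

Desk-scale 3-D microwave brain imaging with a dual-module deep-learning
inversion. The package contains everything needed to study the approach
end to end on a single CPU: a procedural generator of dielectric brain
phantoms, a volume-integral forward scattering solver with the four-layer
60-transceiver measurement array at 300 MHz, a fully-convolutional 3-D
reconstruction network, a 2-D U-Net image-enhancement stage, and the
relative-L2 misfit evaluation protocol with white-noise robustness sweeps.

## The problem

Microwave tomography of the head is an electromagnetic inverse scattering
problem: 60 point-dipole transceivers arranged in four circular layers
around a 0.24 m cubic domain of interest (DOI) illuminate the head at
300 MHz, and the scattered electric field — 3 × 60 × 59 = 10,620 complex
measurements — must be inverted for the voxelized relative permittivity
εr(r) and conductivity σ(r). Brain tissue is a strong, high-contrast
scatterer (ε̃r = εr + σ/(jωε0) with εr up to ~80 and σ up to ~2.2 S/m), so
classical iterative inversion is slow and fragile. The scheme studied
here replaces it with two learned maps:

1. **Reconstruction.** The 10,620 measurements are aggregated per
   receiver and Cartesian component into M = 180 complex values (a
   2 × M = 360 real input). A fully convolutional encoder–decoder (1-D
   convolutional encoder with strided down-sampling, reshape to a cubic
   feature map, 3-D transposed-convolution decoder, 2-channel head) maps
   this vector to one block of the (εr, σ) volume; N independent
   sub-models tile the volume block-wise.
2. **Enhancement.** The preliminary volume is cut into 2-channel XY
   slices and passed through a 4-stage 2-D U-Net trained to map
   preliminary reconstructions to ground-truth property slices.

Training data come from a procedural strategy that emulates anatomical
variability around a single base head model: random global scaling in
{0.8 … 1.2} applied to both geometry and electrical properties, normal
random deformation of every tissue boundary, and optional insertion of a
spherical anomaly (lesion/bleed stand-in, radius ∈ {4, 7, 10} mm,
εr ∈ {90, 120, 150}, σ ∈ {1.038, 1.384, 1.73} S/m).

Reconstruction quality is reported as the relative-L2 **model misfit**
‖m_R − m_T‖₂/‖m_T‖₂ over all voxels and the **data misfit**
‖d_R − d_T‖₂/‖d_T‖₂ between re-simulated and reference scattered fields,
both in percent.

## Worked example

```python
from brainwave.pipeline import RunConfig, run_pipeline

cfg = RunConfig(out_dir="run", seed=1)   # 24^3 grid, 100 training phantoms
result = run_pipeline(cfg)

fc = result["fcernn"]
print(f"validation model misfit: {fc['val_model_misfit_pct']:.2f}%")
print(f"constant-volume baseline: {fc['baseline_valmean_misfit_pct']:.2f}%")
for row in result["benchmark"]["cases"]["normal"]:
    print(row["stage"], row["noise_level_db"], f"{row['model_misfit_pct']:.2f}%")
```

On the default desk-scale configuration this prints (about ten minutes on
one CPU):

```
validation model misfit: 47.46%
constant-volume baseline: 64.95%
fcernn None 48.37%
fcernn -10.0 50.15%
fcernn -20.0 48.49%
fcernn -30.0 48.38%
fcernn -40.0 48.37%
fcernn+unet None 47.39%
fcernn+unet -10.0 48.47%
fcernn+unet -20.0 47.45%
fcernn+unet -30.0 47.41%
fcernn+unet -40.0 47.40%
```

Reading the numbers: the trained reconstruction network recovers held-out
phantoms substantially better than the best constant-volume predictor
(47% vs. 65%), the U-Net enhancement stage never degrades the
reconstruction at any noise level, and enhanced quality improves
monotonically as the measurement noise drops from −10 dB to −40 dB — the
qualitative behavior expected of the two-stage scheme. The benchmark CSV
(`run/benchmark/benchmark.csv`) additionally reports per-channel misfits
and data misfits, and `run/benchmark/done.json` contains anomaly
localization reports (centroid and radius errors in mm) for the anomaly
test case.

The same pipeline is exposed on the command line:

```bash
brainwave all --config cfg.yaml --out run --seed 1
brainwave generate --n 190 --grid 24 --anomaly on --seed 1 --out data.h5
brainwave stage --run run --stage benchmark
```

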