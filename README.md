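# curvislice

Adaptive curved en face slicing for optical coherence tomography (OCT)
volumes — and for anyone whose target layer refuses to lie flat.

A conventional en face image slices a 3D OCT volume with a horizontal plane,
or projects a statistic (mean, max) along depth. When the structure of
interest is a thin layer draped over a curved or tilted sample — a latent
fingerprint under the glue layer of a translucent tape, the ink band of a
thermal-printed label — flat slicing mixes the target with bright
reflections from other layers and the signal drowns. `curvislice` instead:

1. **finds the morphology automatically** — Otsu's threshold (per B-scan, on
   dB intensities) separates foreground voxels, and a Tikhonov-regularized
   polynomial surface

   `f(x, y) = Σ_{a+b≤k} C_ab x^a y^b`,  fitted by  `min ‖z − Xw‖² + α‖w‖²`
   (defaults k = 3, α = 0.1),

   tracks the sample's curvature through the point cloud;
2. **selects individual boundary layers** with the boundary score
   `γ(Δz) = (1/N) Σ_i 1/(|f(x_i, y_i) − z_i + Δz| + 1)`, whose peaks mark the
   depth offsets where the shifted surface `F_m(Δz) = f(x, y) + Δz` crosses a
   layer; the points nearest a chosen peak are kept (default 30 %) and the
   surface refitted on them alone, rejecting the other layers as outliers;
3. **slices along the curve** at any depth offset Δz, producing en face
   images that isolate a single conformal layer; and
4. **measures thin-layer thickness**: for a periodic print pattern, the 2D
   FFT of each curved slice shows sidebands whose strength traces the
   pattern's depth extent. A double Gaussian fit (with a 1/e² right-side
   clip) gives the layer count `l_z = 2σ` in voxels, converted to physical
   thickness with the tilt-corrected projection

   `r = (Mz/Mx·∂f/∂x, Mz/My·∂f/∂y, 1)ᵀ`,  `L = n · Mz · l_z · (e_z·r̂)`.

A seeded phantom generator (`curvislice.phantom`) produces volumes with
complete ground truth — fingerprint-tape and printed-label scenarios
included — so the entire pipeline is testable without instrument data.

## Worked example

Measure the ink thickness of a synthetic 20 µm printed label, tilted 10°:

```python
from curvislice import PipelineConfig, make_label_phantom, make_phantom, run_auto_thickness

spec = make_label_phantom(thickness_um=20.0, tilt_deg=10.0, seed=1)
volume, truth = make_phantom(spec)

config = PipelineConfig(region_size=128, pool_kernel=8, n_medium=1.0)
report = run_auto_thickness(volume, config)

print(f"candidate slice  dz_m = {report['dz_m']}")
print(f"layer count      l_z  = {report['l_z']:.3f} voxels")
print(f"tilt projection  e_z.r = {report['unit_projection']:.4f}")
print(f"ink thickness    L    = {report['thickness_um']:.2f} um")
print(f"ground truth     T    = {truth.true_thickness_um:.2f} um")
```

prints

```
candidate slice  dz_m = -5
layer count      l_z  = 4.803 voxels
tilt projection  e_z.r = 0.9848
ink thickness    L    = 19.90 um
ground truth     T    = 20.00 um
```

Reading the numbers: the automated scan found the pattern-bearing slice 5
voxels above the fitted paper boundary; the Gaussian fit to the pattern
signal spans 4.80 voxels to its 1/e² point; the 10° tilt shortens the axial
count by the factor 0.9848; and the resulting 19.90 µm agrees with the
phantom's constructed 20 µm band. The full report also carries the γ(Δz)
profile, the P2/P100 ratio curve, both Gaussian fits and a provenance block
with the exact configuration.

The same stages are available as a CLI for shell pipelines:

```bash
curvislice simulate --preset label --seed 1 --output phantom.h5
curvislice thickness --volume phantom.h5 --region 128 --pool 8 \
    --refractive-index 1.0 --output thickness.json
curvislice segment --input phantom.h5 --points points.tsv
curvislice fit --points points.tsv --degree 3 --alpha 0.1 --output surface.json
curvislice slice --volume phantom.h5 --surface surface.json --dz -5 --output enface.png
```

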