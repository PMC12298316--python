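# Methods

`curvislice` implements adaptive curved en face slicing for volumetric OCT
data: it finds a sample's curved structural morphology automatically, slices
the volume along that morphology at arbitrary depth offsets, and measures the
thickness of thin patterned layers from the spatial-frequency signature of
the slices. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic phantoms do and do not demonstrate.

## Processing model

**Reconstruction.** A spectral-domain acquisition records, per lateral
position, an interference spectrum riding on the source spectrum. The source
is estimated per B-scan plane as the per-frequency median over the plane's
A-lines — the median is robust to the structured interference terms that vary
from A-line to A-line — subtracted, tapered with an `nf`-point Hann window to
limit spectral leakage, and discrete-Fourier transformed. Real-valued input
makes the transform conjugate-symmetric, so only the magnitudes of bins
`0 … nf/2 − 1` are kept: 2048 spectral samples become 1024 depth voxels. No
wavenumber resampling or dispersion compensation is modelled; the transform
axis is treated as uniformly sampled. Repeat scans are averaged voxel-wise in
the linear magnitude domain, suppressing uncorrelated noise by √n.

**Foreground.** Otsu's threshold is computed per B-scan on log-compressed
(dB) intensities with a 256-bin histogram. The between-class variance
`w0·w1·(μ0 − μ1)²` is scanned over every histogram cut; ties break toward the
lower cut, and voxels strictly above the threshold are foreground. dB
compression is the default because OCT magnitude histograms are heavy-tailed
and raw-magnitude Otsu collapses onto the speckle tail; a raw mode and a
single global threshold are provided. A constant slice yields an
all-background mask with a warning rather than an error.

**Surface fit.** The morphology is a bivariate polynomial
`f(x, y) = Σ_{a+b≤k} C_ab x^a y^b` (default `k = 3`), fitted to the
foreground voxel coordinates by Tikhonov-regularized least squares,
`min ‖z − Xw‖² + α‖w‖²` with `α = 0.1` and the intercept left out of the
penalty so constant surfaces are recovered exactly. Lateral coordinates are
affinely mapped to `[−1, 1]` before the monomial expansion: raw voxel indices
up to ~10³ raised to the cube make the normal equations ill-conditioned and
change what a fixed `α` means. The transform is stored on the surface, so
evaluation and analytic gradients are always in raw voxel coordinates; a
`normalize=False` mode keeps literal coordinates. The solver is a direct
normal-equations solve — deterministic, no iterations, no random state. A
rank-deficient unregularized fit raises with guidance to set `α > 0`.

**Layer selection.** The fitted surface extends to the family
`F_m(Δz) = f(x, y) + Δz`. The boundary score
`γ(Δz) = (1/N) Σ 1/(|f(x_i, y_i) − z_i + Δz| + 1)` lies in (0, 1] and peaks
whenever the shifted surface crosses a layer of foreground points; the
magnitude of a peak approximates that layer's share of the foreground. Peaks
are local maxima with prominence ≥ 10 % of the profile's range on a
configurable grid (default integer steps over ±nz/8); ties among equal peaks
resolve toward smaller |Δz|. Optional parabolic refinement interpolates a
peak position to sub-grid precision from its three surrounding samples
(off by default; an integer grid quantizes a layer that sits at a half-voxel
offset). Selecting a layer keeps the `⌈keep_fraction·N⌉` points closest to
the shifted surface (default 0.3) and refits with the same degree, penalty
and normalization — the outlier cut is what removes the other layers' voxels
and makes the refit track a single boundary.

**Curved slicing.** An en face image samples the volume at `f(x, y) + Δz`
for every lateral position, with linear interpolation along depth by default
(sub-voxel offsets are meaningful); nearest-neighbour mode reproduces flat
slicing bit-exactly for constant surfaces. Depths outside the volume are
masked and filled with zero, never clamped — clamping would fabricate edge
data. Flat baselines (horizontal slice, mean/max projection over a band) are
provided for comparison. Contrast stretching exists only for display copies.

**Pattern analysis and thickness.** A periodic print pattern confined to a
thin band appears as a pair of symmetric sidebands in the 2D FFT of the
central square region of a slice. The automated workflow:

1. For each Δz in a scan range (default −20 … 19): slice, FFT the central
   region (default 256², Hann-tapered), max-pool the magnitude spectrum
   (default 8×8 cells), and compute the P2/P100 intensity ratio — P1 is DC,
   P2 the strongest sideband candidate, P100 a noise-floor representative.
2. The candidate slice Δz_m maximizes that ratio (ties toward smaller |Δz|).
   Its 23 largest pooled cells become *dominant* locations, the rest
   *recessive*.
3. Per Δz, the pattern signal is (max pooled intensity within one cell of a
   dominant location) − (max near recessive locations). The DC neighbourhood
   is excluded from both searches, and dominant neighbourhoods are excluded
   from the noise search, so bright low-frequency structure can neither pose
   as signal nor inflate the floor.
4. A Gaussian `A·exp(−(Δz−μ)²/2σ²)` is fitted to the signal (initialized
   from the max, argmax and second moment), samples beyond `μ + 2σ` are
   clipped — deep slices carry multiple-scattering tails — and the fit is
   repeated. The layer count is read at the 1/e² amplitude point:
   `l_z = 2σ` (peak-to-cutoff half-width; a `width_mode="full"` switch gives
   4σ).
5. The physical thickness follows from the local tilt. With voxel pitches
   `Mx, My, Mz` (defaults 4.8828, 19.5312, 4.2068 µm/voxel) the
   gradient-plane vector is `r = (Mz/Mx·∂f/∂x, Mz/My·∂f/∂y, 1)ᵀ` at the
   analyzed region's centre, and `L = n·Mz·l_z·(e_z·r̂)` with `e_z·r̂ = 1/|r|`.
   The refractive index defaults to 1.557 (plain paper) and is always a
   configuration value.

Two numerical details matter here. The FFT region is Hann-windowed by
default: without it, edge discontinuities and broad reflectivity structure
leak energy along the spectral axes and a bright boundary slice can out-rank
the true pattern slice. And the pooling grid is circularly aligned so the DC
bin sits at the centre of its cell; otherwise the taper mainlobe straddles a
cell boundary and DC leakage becomes a permanent spurious "P2".

## Synthetic phantoms

The `phantom` module generates volumes with complete ground truth (height
maps, boundary voxel masks, the pattern image, band thickness), emitted by
the generator itself so tests never re-derive truth. Bands are deposited
with partial-voxel overlap weights, making sub-voxel geometry meaningful.
All randomness flows through one seeded generator; a spec is bit-reproducible
and serializes to JSON.

Noise model: additive gamma-distributed background speckle with shape `m`
(mean `background`; `m = 1` is fully developed exponential-magnitude speckle,
larger `m` emulates the contrast reduction of an m-scan average), optional
multiplicative gamma speckle on the deposited structure (contrast `1/√m`),
and a small magnitude readout term that keeps the volume strictly positive —
real detector magnitudes never hit exact zero, and an exact-zero voxel would
put a −240 dB spike in the log histogram. The defaults model averaged
acquisitions (shape 4–8) rather than single-look speckle: per-slice Otsu on
a log histogram needs the foreground mode to win against splitting an
~11 dB-wide single-look background mode, which with a foreground occupancy of
a few percent it does not reliably do. That is a genuine limitation of
single-look data, not of the implementation, and the reconstruction module's
multi-scan averaging is the standard remedy.

Three presets define the scenarios used throughout the tests:

* **two-layer** (128×64×128): two parallel gently curved bright bands 11
  voxels apart — layer detection, peak spacing and outlier-rejected refits.
* **tape** (160×160×128): a rough bright diffusive top boundary (smooth
  random reflectivity field), a low-contrast glue layer 11 voxels deeper
  whose band intensity is modulated by a fingerprint-like ridge pattern, and
  a sparse (5 % coverage) residue layer deeper still. The top layer's
  reflectivity variance is what drowns flat/average projections while the
  curved slice isolates the ridge pattern.
* **label** (160×128×192, instrument voxel pitches): a tilted cubic paper
  boundary (tilt angle and azimuth configurable; the azimuth emulates
  re-orienting the sample) with a periodic ink band centred 6 voxels above
  it. The band's depth profile is Gaussian with `σ_p` = half the nominal
  voxel thickness, i.e. the nominal thickness equals the profile's
  peak-to-1/e² distance — the same convention the measurement reads out. A
  hard-edged (boxcar) profile is also available, but a least-squares Gaussian
  fitted to a boxcar of width W has 2σ ≈ 0.72 W, so the 1/e² convention only
  calibrates when the axial profile is smooth, as finite axial resolution
  and scattering make real profiles. The band's z-extent is
  `thickness_µm / (n·Mz·cosθ)` so its physical thickness measured along the
  surface normal is exact; at zero tilt, 20 µm ↔ 4.754 voxels.

What the phantoms do not emulate: axial point-spread convolution and
roll-off, shadowing, refraction at interfaces, motion, or detector
saturation. Passing tests therefore demonstrate the geometry and signal
chain of the method, not robustness to every physical artifact of an
instrument.

## Problem sizes and defaults

Phantom tests run at roughly 160×128×192 voxels with a 128-pixel FFT region
and 8×8 pooling (≥ 100 pooled cells, so the P100 noise rank exists) — a
desk-scale rendition of the 1024×256×1024, 256-region geometry the defaults
target. The thickness-recovery check spans 5 seeds plus 6 orientations; all
other checks are single-seed with fixed generators.

Key defaults: degree `k = 3`, ridge weight `α = 0.1`, `keep_fraction = 0.3`,
Δz scan ±nz/8 (boundary score) and −20…19 (pattern), pool kernel 8, 23
dominant locations, neighbourhood radius 1 cell, linear interpolation,
half-width (2σ) layer counting, `n = 1.557`, `Mx, My, Mz` as above. Every
default is overridable per call, via `PipelineConfig`, YAML, or CLI flags,
and each run's report embeds the full configuration for reproducibility.

## Known limitations

* One polynomial surface per layer: no splines, periodic bases or learned
  surfaces; surfaces that fold or self-occlude are out of scope.
* Layers are processed one at a time; there is no joint multi-surface
  segmentation.
* The candidate-slice ratio assumes the pattern's sidebands fall outside the
  DC pooling cell; extremely low spatial frequencies (< one pooling cell)
  are indistinguishable from DC structure.
* The 70 %/30 % outlier cut is a user parameter, not inferred per sample;
  the boundary-score peak magnitudes are exposed to guide the choice.
* Multi-scan averaging assumes co-registered volumes; no registration is
  performed.
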