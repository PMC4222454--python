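# Methods

`nanouptake` quantifies the absolute number of fluorescently labeled
nanoparticles per cell, and their subcellular location, from two-channel 3D
confocal stacks: one channel images the plasma membrane stain, the other the
particles. This note documents the model behind each stage, the parameters
that matter, and what the synthetic-data tests do and do not demonstrate.

## Cell reconstruction and the membrane region

The membrane stain images the plasma membrane as a bright closed shell. The
reconstruction is:

1. Gaussian smoothing with `smoothing_sigma_um` (default 0.2 µm), converted
   per axis to voxel units so the smoothing is isotropic in physical space.
2. A global threshold (Otsu on the smoothed stack's full 3D histogram by
   default; a fixed threshold is available for pathological histograms).
3. Per-slice 2D hole filling. The membrane is a shell, so its interior must
   become solid; filling slice-wise rather than in 3D also closes cells that
   the stack crops at its top or bottom plane, which is common in confocal
   acquisitions of adherent cells.
4. 26-connected 3D component labeling; components smaller than
   `min_cell_volume_um3` (default 50 µm³) are discarded as debris and the
   largest survivor is taken as *the* cell. The workflow is intentionally
   single-cell; fields with several cells should be cropped first
   (`--cell-bbox`).

Space is then partitioned by an anisotropy-aware Euclidean distance
transform (`scipy.ndimage.distance_transform_edt` with `sampling` equal to
the voxel sizes): the **membrane region** is every voxel within `w/2` of the
detected boundary on either side, the **intracellular** region is everything
deeper inside, and the **extracellular** region is the remainder. The width
`w` (`shell_width_um`) defaults to 1.4 µm. This region is deliberately much
wider than the actual lipid bilayer: it is an uncertainty buffer between
inside and outside, absorbing segmentation error, the PSF, and genuinely
membrane-bound particles. Placing the region symmetrically about the
detected boundary (w/2 in, w/2 out) is this package's convention; only the
total width is a meaningful physical choice.

The distance-transform construction, rather than iterated voxel morphology,
is what keeps the shell's *physical* thickness equal along z and x/y when
voxels are anisotropic (e.g. 250 nm z spacing vs 110 nm pixels). On
isotropic grids it is exactly equivalent to morphological
dilation/erosion with a Euclidean ball, which the test suite verifies by
brute force on small grids.

## Spot detection and photometry

Particles (and their agglomerates) are diffraction-limited or near-limited
bright spots. Detection:

1. **Background subtraction.** A per-slice 2D median filter (window radius
   `median_radius_um`, default 1.0 µm) estimates the background. Two
   implementation choices matter and are deliberate:
   - The 2D median is computed as two orthogonal 1D median passes
     (separable approximation). For sparse, compact spots on a slowly
     varying background this is equivalent to the full 2D median and about
     5× faster.
   - The estimate is made twice: spots found in the first-pass residual are
     masked (threshold + size filter + dilation over the PSF skirt) and
     replaced by their slice's median before the filter runs again. Without
     this, spot pixels inside the median window shift the window's rank
     statistics and inflate the background by up to one noise σ over the
     entire spot neighbourhood — enough to swallow ~25% of a spot's flux.
   The returned residual is *signed*, not clipped at zero: clipping would
   give the residual noise a strictly positive mean and bias every
   integrated intensity upward by hundreds of noise σ per object.
2. **Thresholding.** Voxels above `median + k · 1.4826 · MAD` of the
   residual (default `k = 5`) are foreground. Median/MAD are robust to the
   spots themselves. On noiseless synthetic stacks (MAD = 0) the threshold
   falls back to 10% of the peak residual, since a blurred spot is positive
   over its whole truncated-PSF support.
3. **Labeling.** 3D connected components, 26-connectivity by default so that
   axially elongated spots stay in one piece; components with fewer than
   `min_voxels` (default 4) voxels are discarded as noise.
4. **Photometry.** Each object's integrated intensity is the sum of residual
   intensities over its detection mask *dilated* by
   `integration_dilation_um` (default 1.0 µm; contested voxels go to the
   nearest object, computed with one distance transform). The dilation
   recovers the PSF tail flux below threshold. This matters for counting:
   the above-threshold core captures a brightness-dependent fraction of a
   spot's flux (as little as ~30% at SNR 10), which would make intensity
   ratios overestimate agglomerate sizes. With the default dilation the
   captured fraction is ≳ 99.5% for all multiplicities of interest.
   Finally, the mean residual over all voxels outside every aperture is
   taken as the residual sky level and subtracted per aperture voxel
   (aperture photometry with a global sky estimate). This removes the
   median-estimator's mean/median skew, which would otherwise integrate to
   a few percent of a spot's flux over a several-thousand-voxel aperture.

Centroids are intensity-weighted over the detection core and reported in µm
with the origin at the center of voxel (0, 0, 0).

## Calibration

The single-particle intensity `I₁` is measured from stacks of particles
spread on a coverslip and imaged with the same setup as the cells (the
package warns when voxel geometries differ). Spot intensities are collected
with the detection pipeline above and fitted with an iteratively trimmed
Gaussian: values outside mean ± 2.5 sd are discarded and the fit repeated to
a fixed point (≤ 10 iterations). The trim removes multi-particle spots,
which sit near integer multiples of `I₁`: with ~10% intensity CV, a doublet
at 2·I₁ lies ≈ 10 sd from the singlet mode, so 2.5 sd separates the modes
cleanly. The fit is the maximum-likelihood mean/sd of the trimmed sample —
bin-free, and equivalent to histogram fitting at large n. `fit_ok` is
false when trimming removes more than half of the spots.

For strongly agglomerating particles the coverslip "single particle" is
really a single agglomerate; the counting unit is then one agglomerate, and
the interpretation is left to the user.

## Counting and classification

Each object's particle count is `round(I / I₁)` (half-up), clamped to ≥ 1:
an object that passed detection represents at least one particle. The rule
assumes dye self-quenching in agglomerates is negligible, so integrated
intensity is additive in the number of particles; the synthetic forward
model reproduces exactly this additivity, which is what makes the rule
exact in tests.

Objects are assigned to the region containing their centroid voxel. Objects
are near-pointlike relative to the 1.4 µm membrane region, and any boundary
ambiguity is absorbed by that region by design. Whether sub-unit objects
(I < 0.5·I₁) should be clamped to one particle or discarded is an open
choice; clamping is this package's documented behavior.

## Synthetic data

The generator emulates the target imaging regime so that every stage is
testable without microscope data:

- **Geometry.** Sphere (analytic oracle), hemisphere-on-coverslip (adherent
  cells are flat), or ellipsoid. `cell_radius_um` is the outer surface; the
  optical membrane band (default 0.4 µm) is drawn on its inner side, so the
  thresholded mask's outer edge coincides with the nominal radius.
- **Optics.** Gaussian PSF, σ = 0.15 µm lateral / 0.45 µm axial — an
  approximation to a 1.4 NA oil objective; no vectorial PSF, no depth
  aberration.
- **Sampling.** Default voxels 0.25 µm in z (typical confocal section
  spacing) and 0.11 µm in x/y (typical 63× EMCCD sampling).
- **Particles.** Each requested particle deposits `k` unit intensities
  (unit default 48090 camera counts, a realistic integrated brightness for
  a dye-loaded ~300 nm particle; CV 10%) at a sub-voxel position via
  trilinear splatting, then the field is PSF-convolved. Expected integrated
  spot intensity is exactly `k·µ` before noise. Positions are sampled
  uniformly within the requested region class, 0.35 µm clear of region
  boundaries (so ground-truth classes survive the ≲ 0.15 µm boundary error
  of the reconstruction) and ≥ 2.5 µm apart (so objects are resolvable and
  their photometry apertures independent).
- **Noise.** Flat background (100 counts), Poisson shot noise at 0.5
  photons per count, Gaussian read noise (30 counts sd). Single-particle
  peak SNR under the defaults is ≈ 25.
- **Calibration fields.** 200 spots on the mid plane of a 30 × 30 µm × 14
  plane stack, ≥ 1.5 µm apart, a configurable fraction doublets at 2µ.

What passing synthetic tests does **not** show: robustness to structured
cytoplasmic autofluorescence, depth-dependent attenuation, photobleaching,
spot motion during acquisition, touching cells, or particle densities high
enough that apertures overlap. Real dense uptake (thousands of particles
per cell) produces merged objects whose counts rely entirely on the
intensity-additivity assumption.

The kinetics-table generator draws per-cell counts from a negative binomial
(cell-to-cell uptake is strongly overdispersed) and exists solely to
exercise the statistics layer at realistic group sizes without imaging.

## Statistics

Per-condition summaries are mean ± SEM over cells (SEM = sample sd with the
n−1 denominator over √n; undefined and reported as missing for n = 1).
Group comparisons use the unpaired two-sample Student's t-test with pooled
variance — Welch's correction is available behind a flag but is not the
default. Significance flags: `*` for 0.01 ≤ p < 0.05, `**` for p < 0.01.
Cells are pooled across independent experiments; experiment-level nesting
(mixed models) is out of scope, as is multiple-testing correction.
Degenerate input (both groups constant and equal) returns p = 1 by
convention. The classical p-value is validated against a permutation test
in the suite.

## Numerical and scale choices

- Intensities stay in native camera units end to end; `I₁` and object
  intensities share units, so counting is invariant to any common gain.
- Analyses are deterministic given inputs and configuration; all generator
  randomness flows through one seeded `numpy` Generator.
- Validation problem sizes: geometry checks use an 8 µm sphere at 0.1 µm
  isotropic voxels; end-to-end recovery uses 20 seeded 6 µm cells at the
  default anisotropic sampling; calibration recovery uses 100 seeded
  200-spot fields; agglomerate counting uses 500 objects with k = 1…10.
  These sizes give sub-percent sampling error on the quantities checked
  while keeping the whole suite fast to run routinely.

## Known limitations

- One cell per analysis; no watershed splitting of touching cells, no
  nucleus or organelle segmentation.
- No sub-diffraction localization or PSF fitting; two particles closer than
  about one PSF width are one object (counted correctly by intensity, but
  reported as a single location).
- Calibration assumes the particle brightness distribution is unimodal
  Gaussian with agglomerates at integer multiples; heavily skewed brightness
  distributions would bias the trimmed fit.
- The counting rule inherits the negligible-self-quenching assumption; for
  dyes that self-quench in dense agglomerates, counts are lower bounds.
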