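# nanouptake

Absolute nanoparticle counting and subcellular localization from two-channel
3D fluorescence microscopy stacks.

## The problem

Quantifying how many nanoparticles a cell has taken up — not a relative
fluorescence signal, but an absolute number, and *where* those particles are
(inside the cell, at its membrane, or outside) — is central to
nanotoxicology and nanomedicine. Confocal microscopy can watch live cells in
3D, but it cannot resolve individual sub-200 nm particles, and particles
agglomerate in biological medium, so a bright spot may be one particle or
twenty.

`nanouptake` implements the intensity-calibrated counting strategy for this
problem. Two confocal z-stacks are acquired per cell: a membrane-stain
channel and a particle channel. The analysis:

1. **Cell reconstruction** — the membrane channel is smoothed, thresholded
   (Otsu), hole-filled and labeled into a solid 3D cell mask. A Euclidean
   distance transform in physical units splits space into three regions:
   *intracellular*, an enlarged *membrane region* of width w (default
   1.4 µm, w/2 on each side of the detected boundary — an uncertainty
   buffer much wider than the actual bilayer), and *extracellular*.
2. **Spot detection** — the particle channel is background-subtracted
   (masked per-slice median filter) and thresholded at
   median + 5·1.4826·MAD; 3D connected components become objects, each with
   an intensity-weighted centroid and an aperture-integrated intensity I.
3. **Calibration** — the single-particle intensity I₁ is measured from
   coverslip stacks of isolated particles: spot intensities are fitted with
   an iteratively trimmed Gaussian (±2.5 sd) that rejects multi-particle
   spots.
4. **Counting and classification** — each object represents
   n = max(1, round(I / I₁)) particles (valid when dye self-quenching in
   agglomerates is negligible) and is assigned to the region containing its
   centroid. Per-cell totals and per-object tables are written as CSV/JSON,
   plus a pseudo-colored RGB overlay (membrane cyan, intracellular red,
   membrane-associated yellow).
5. **Statistics** — per-condition summaries as mean ± SEM over cells and
   unpaired Student's t-tests with `*` (p < 0.05) / `**` (p < 0.01) flags.

A synthetic-data module generates two-channel stacks with exact ground
truth (analytic cell geometry, Gaussian PSF, Poisson + read noise,
anisotropic voxels), so the entire pipeline is testable without microscope
data.

## Worked example

Simulate a calibration field and a cell with known content, then run the
full analysis:

```python
import nanouptake as nu

det = nu.DetectionParams()

# calibration: 200 coverslip spots, 10% brightness CV, 10% doublets
field, _ = nu.generate_calibration_field(n_spots=200, seed=11)
cal = nu.calibrate_single_particle([field], det)
print(f"I1 = {cal.i1_mean:.1f} +/- {cal.i1_sd:.1f} "
      f"({cal.n_spots_used} spots used, {cal.n_spots_rejected} rejected)")

# one cell: 9 intracellular singles + 1 triplet agglomerate,
# 4 membrane-region singles, 5 extracellular singles
specs = ([nu.ParticleSpec("intra")] * 9
         + [nu.ParticleSpec("intra", multiplicity=3)]
         + [nu.ParticleSpec("shell")] * 4
         + [nu.ParticleSpec("outside")] * 5)
membrane, particles, truth = nu.generate_cell_stack(
    nu.ScenarioParams(particles=specs, seed=3))

regions = nu.reconstruct_cell(membrane)
objects = nu.detect_objects(nu.subtract_background(particles, det), det)
result = nu.summarize_cell(objects, regions, cal, grid=particles)
print(result.totals)
```

Output:

```
I1 = 47752.6 +/- 5047.5 (178 spots used, 22 rejected)
{'n_intracellular': 12, 'n_membrane': 4, 'n_extracellular': 5, 'n_total': 21}
```

The fitted I₁ is within 0.7% of the simulated unit brightness (48090 camera
counts); the 20 simulated doublets are among the 22 rejected spots. The
per-region totals match the ground truth exactly — note the triplet
agglomerate is detected as *one* object but counted as *three* particles
from its intensity.

The same workflow is available from the shell:

```sh
nanouptake simulate  --scenario scenario.yaml --out sim/
nanouptake calibrate --stacks cal_stacks/ --out cal.json
nanouptake quantify  --membrane sim/membrane.ome.tif \
                     --particles sim/particles.ome.tif \
                     --calibration cal.json --out results/
nanouptake report    --counts counts.csv --out report/ --compare HUVEC HeLa
```

`quantify` writes `per_object.csv` (one row per object: position in µm,
region, integrated intensity, particle count), `per_object.json` (per-cell
totals + provenance) and `overlay.tif`.

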