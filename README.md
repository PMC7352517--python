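# stromascan

Quantitative tools for studying how stromal collagen architecture shapes
ovarian-cancer cell migration on *image-based* scaffolds — fibrous matrices
fabricated so that their fiber layout reproduces second-harmonic-generation
(SHG) microscopy images of real tissue.

The package covers the full computational chain of such a study:

1. **Blueprints and scan plans** (`stromascan.blueprint`) — discretize a
   grayscale fibrous image into a fabrication blueprint (Hessian-eigenvalue
   tubeness filter, Otsu threshold, small-object removal), map its graded
   intensities linearly onto the per-pixel shutter *open fraction* of a
   modulated raster scan (tiled, e.g. 3×3 repeats of a 200×200 µm pattern
   → 600×600 µm), simulate the fabricated readout (Gaussian PSF blur +
   shot noise), and score blueprint↔fabrication **fidelity** by
   colocalization (mask Dice overlap and intensity Pearson correlation).
2. **Motility analysis** (`stromascan.migration`) — instantaneous speeds,
   step headings, time-and-ensemble-averaged mean squared displacement,
   and a nonlinear least-squares fit of the persistent-random-walk (Fürth)
   model

   MSD(t) = 2 n_d µ [ t − P (1 − e^(−t/P)) ],  n_d = 2,

   for the motility coefficient µ (µm²/min) and persistence time P (min).
3. **Orientation statistics** (`stromascan.orientation`) — structure-tensor
   local orientation fields, axial (180°-periodic) angular distributions,
   an alignment index, Pearson correlation between distributions, the
   two-sample Watson U² test with permutation p-values, and circular mean
   directions.
4. **Morphometry** (`stromascan.morphometry`) — spread area, circularity
   (4πA/p²), cell-vs-fiber alignment angle, difference-of-Gaussians focal-
   adhesion detection, and corrected total cell fluorescence (CTCF).
5. **Synthetic data** (`stromascan.synthetic`) — seeded phantoms for all of
   the above: fiber images for four stromal morphology classes (normal
   mesh-like, benign thick-fibered, high-risk aligned, high-grade aligned
   and crimped), persistent-random-walk trajectories with known (µ, P) and
   optional contact-guidance bias, elliptical cell masks, and punctate
   focal-adhesion images — each with ground truth.
6. **Pipeline** (`stromascan.pipeline`, `stromascan` CLI) — seeded,
   fully reproducible end-to-end runs with ANOVA + pairwise Welch t-tests
   across conditions.

It is aimed at groups building image-based tissue models (multiphoton-excited
fabrication, electrospun or printed fibrous scaffolds) and at anyone needing
a tested persistent-random-walk fitter or axial-statistics toolbox for cell
and fiber orientations.

## Worked example

Generate a high-grade-class phantom, discretize it, simulate fabrication
and score fidelity:

```sh
$ stromascan generate high_grade --seed 7 -o hg.tif
wrote hg.tif (400x400)
$ stromascan discretize hg.tif -o hg_bp.tif
blueprint: 33734 fiber pixels (21.1% of image)
$ stromascan simulate hg_bp.tif --seed 8 -o hg_fab.tif
$ stromascan fidelity hg_bp.tif hg_fab.tif
{
  "spatial_overlap_pct": 97.79711320441683,
  "intensity_corr": 0.9653047367322776,
  "fidelity_pct": 97.1637934388223
}
```

The fabricated readout (0.6 µm FWHM blur, Poisson noise at SNR 20) retains
97.8% spatial overlap with the blueprint mask and an intensity correlation
of 0.965; the combined fidelity score is 97.2%.

Fit the persistent-random-walk model to simulated trajectories (200 cells
sampled every 30 min over 72 h, true µ = 10 µm²/min, P = 30 min):

```python
from stromascan import PRWParams, generate_trajectories
from stromascan.io import save_trajectories
tracks = generate_trajectories(PRWParams(n_cells=200, n_frames=145), seed=1)
save_trajectories(tracks, "tracks.csv")
```

```sh
$ stromascan motility tracks.csv
{
  "mu_um2_per_min": 9.98416219964563,
  "P_min": 33.18615727076207,
  ...
  "converged": true,
  "identifiable_P": true
}
```

The fit recovers µ within 0.2% and P within 11% of the generating values;
`identifiable_P` is false whenever the persistence time runs into its bound
or its standard error exceeds the estimate (purely ballistic or purely
diffusive data).

A full multi-condition run (`stromascan report --seed 3 --out run/`) writes
per-class phantoms, blueprints, scan plans, trajectories, orientation
distributions, a machine-readable `metrics.json` and a plain-text summary.

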