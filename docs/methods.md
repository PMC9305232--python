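# Methods

## Scope and model

`myconet` measures the architecture of 2D filamentous (hyphal) networks in
binary rasters and computes two assay-side quantities used with such
imaging. The observable unit is a square region of interest (ROI);
the canonical geometry is a 5 × 5 mm² field imaged at 640 × 640 px²
(7.8125 µm/px), and all defaults are stated at that scale. Three ROIs
placed along the axis from the partner-compartment barrier towards the
centre of the fungus-only compartment form a *gradient profile*.

### Mass fractal dimension

For grid size *s* (px), the raster is partitioned into an axis-aligned grid
of *s* × *s* boxes and *N(s)* counts boxes containing ≥ 1 foreground pixel.
Under the mass-fractal model *N(s)* ∝ *s*<sup>−D<sub>m</sub></sup>,
D<sub>m</sub> is estimated as minus the slope of an unweighted ordinary
least-squares fit of ln *N(s)* on ln *s* (`scipy.stats.linregress`); the
log-space intercept and r² are reported as fit diagnostics.

Numerical choices:

- **Grid sizes.** Default *s* ∈ {8, 16, 32, 64}: geometric spacing across
  the 8–64 px range appropriate for a 640 px ROI (1/80 to 1/10 of the
  side). Any list can be supplied; analytic work on the Sierpinski carpet
  uses aligned powers of 3.
- **Anchoring.** The grid is anchored at the ROI's top-left corner by
  default (reproducibility first). An optional mode averages *N(s)* over
  the four corner anchorings (phase offsets 0 and extent mod *s* per axis)
  for sparse masks where grid placement matters; on grid-divisible rasters
  all four anchorings coincide.
- **Partial edge boxes** (non-divisor grids only) count as ordinary boxes.
- **Degenerate points.** Grid sizes with *N(s)* = 0 are dropped from the
  fit with a warning; fewer than two usable distinct sizes is an error
  (the dimension is undefined). If *N(s)* is constant, the slope is
  exactly 0 and r² is reported as 1 (the flat line fits perfectly), so an
  isolated point yields D<sub>m</sub> = 0.
- **Plausibility flag.** Estimates outside [−0.1, 2.1] are flagged rather
  than clipped; fit noise can push slightly past the geometric [0, 2]
  range.

Box counting is performed by two nested `numpy.add.reduceat` reductions;
its correctness oracle in the tests is an independent per-box double-loop
scan.

### Which raster is counted

The preprocessing chain is binarize → close → remove small clusters →
skeletonize. Box counting runs on the 1-px skeleton by default — it
measures the space-filling of the network's centreline, independent of
strand thickness — with `source="clean_mask"` available to count the full
network surface instead. Surface density is always measured on the cleaned
mask (it is a surface measure by definition) as the exact foreground pixel
fraction.

### Preprocessing defaults

- **Binarization**: Otsu's threshold, assuming bright hyphae on a dark
  background (`invert` for the opposite polarity); fixed-threshold
  override. Foreground is strictly above the threshold. Already-binary
  inputs pass through unchanged, making the step idempotent.
- **Closing**: disk radius 1 px by default, bridging 1-px pinholes in
  strands; radius 0 skips it. With radius 0 the chain is monotone
  (skeleton ⊆ clean ⊆ binarized), which the tests exercise.
- **Cluster removal**: components < 20 px (8-connectivity) are deleted.
  20 px at 7.8125 µm/px is a tunable chosen to sit well above
  single-pixel speckle and well below any real hyphal fragment; it is not
  a measured constant.
- **Connectivity**: 8 by default — diagonal neighbours are common in 1-px
  skeletons of curvilinear strands.
- **Skeletonization**: topology-preserving thinning
  (`skimage.morphology.skeletonize`); re-thinning is a no-op and the
  skeleton is a subset of its source mask.
- Coordinates are 0-based (row, col) with top-left origin; ROIs are
  half-open squares and must lie fully inside the image.

### Calibration and transfer efficiency

Dry fungal biomass (mg) is regressed on qPCR total copy number per strain
(statsmodels OLS), from reference subsamples spanning roughly 0.5–5 mg.
The intercept is free by default; a through-origin option exists because
the physically motivated line passes through zero but a free intercept
absorbs assay background. Predictions below 0 mg are clamped to zero with
a warning. Groups that cannot be fitted (fewer than two samples,
zero-variance copy numbers) are reported as failures without aborting the
remaining strains.

Transfer efficiency per replicate is

  efficiency = QD signal in whole focal root /
               (fungal biomass in focal compartment +
                focal-strain biomass in central compartment)

in relative fluorescence units per mg; no absolute phosphorus conversion
is attempted. Replicates with a zero denominator are excluded and
reported. When qPCR cannot distinguish the focal strain from a genetically
near-identical partner, the pipeline attributes all central-compartment
copies to the focal strain and logs that choice prominently; callers with
a better attribution rule can supply pre-split biomass columns.

## Synthetic data generator

Real micrograph collections are large and archived externally, so the test
bed is generative. Hyphal tips perform a correlated random walk: each live
tip advances `step_len_px` (default 4 px) per round, its heading perturbed
by N(0, `angle_jitter_rad`²) (default 0.25 rad); with probability
`branch_prob` (0.04/round) it bifurcates at 0.4–1.2 rad, and when its new
segment touches an existing strand it terminates with probability
`fusion_prob` (0.10), an anastomosis analogue. Segments are Bresenham
lines stamped to `strand_width_px` (2 px), keeping the raster strictly
binary. Growth halts when coverage reaches `target_coverage_frac` or all
tips have died (boundary exits kill tips); the overshoot is at most one
growth round, so realized coverage tracks the target tightly (the tests
require the 20-seed mean within ±20% relative, and observe ≲ 2%).
Salt (speckle) noise flips a chosen fraction of pixels to foreground after
growth, exercising the cleaning stage. Defaults — 640 px images, 12 seed
tips, 4–8% coverage targets for gradient series — reflect sparse
extraradical networks at the canonical scale.

Ground truth attached to every image: realized coverage, 1-px centreline
length, branch count, a target-reached flag, and the noise-free mask.
Output is a pure function of the parameter set including its seed
(bit-identical across runs).

What the generator does **not** emulate: uneven illumination and focus
gradients, strand-width variation and overlapping crossings thicker than
the stamp, spores and mycelial aggregates, true anastomosis topology
(fusion here just terminates a tip), 3D growth and time-lapse dynamics.
Passing tests therefore demonstrate the correctness and robustness of the
measurement chain on controlled filamentous structure, not segmentation
performance on real plates — binarization of difficult micrographs still
needs case-by-case threshold choices.

Analytic fixtures provide exact oracles: filled square (D = 2), single
1-px row (D = 1), single pixel (D = 0), and the depth-*k* Sierpinski
carpet (3<sup>k</sup> px side, D = log 8 / log 3 ≈ 1.8928, coverage
(8/9)<sup>k</sup>), for which aligned power-of-3 grids give
*N(3<sup>j</sup>)* = 8<sup>k−j</sup> exactly.

## Pipelines and provenance

The architecture pipeline emits one tidy row per image/ROI: label,
D<sub>m</sub>, r², coverage percent, raw *N(s)* counts, config hash (first
12 hex digits of the SHA-256 of the canonical config JSON) and package
version. Analytic-fixture presets are measured as-is (no cleaning or
thinning — the fixtures *are* the object of measurement, and e.g. thinning
a filled square would measure its skeleton instead). Given a config and
seed, output tables are byte-identical across runs. Configurations
round-trip losslessly through YAML.

Estimator classes follow the scikit-learn protocol (`fit`,
`get_params`/`set_params`, trailing-underscore fitted attributes) so they
compose with sklearn pipelines and model selection; the module-level
functions are thin one-shot wrappers over them.

## Problem sizes in the test suite

The default suite and the acceptance script run at the sizes the
properties are stated for: 640 px networks; 100 networks for the inclusion
chain; 50 noisy seeds for cleaning recovery; 20 seeds × 2 directions × 3
ROIs for gradient shape; 1000 random 64 × 64 masks against the naive
box-count oracle; 100 simulated calibration sets of n = 20. The full
suite completes in about a minute on one CPU.

## Known limitations

- D<sub>m</sub> from four grid sizes has non-trivial estimator variance on
  sparse masks; the averaged-anchoring mode reduces but does not remove
  grid-placement sensitivity. Estimates are comparable within a fixed grid
  set and anchoring, not across them.
- Box counting of a 2-px-wide strand at s = 8 is already thickness-aware;
  the skeleton default avoids this but discards width information
  entirely.
- The efficiency metric inherits whatever attribution rule assigns
  central-compartment biomass when strains are qPCR-indistinguishable.
- The generator's coverage control assumes tips survive long enough to
  reach the target; at high fusion probabilities or very high targets the
  target-reached flag must be checked.
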