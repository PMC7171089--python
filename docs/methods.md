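# Methods

`devbrainmap` implements the quantitative pipeline used to map labelled
cells across postnatally developing mouse brains imaged by serial
two-photon tomography (STPT): age-specific average templates, cross-age
anatomical label propagation, per-region count/density quantification,
layer-specific cortical flatmaps, and negative-binomial group statistics.
This note records the models, conventions, parameter choices, and the
limits of what the phantom-based tests demonstrate.

## Coordinate and counting conventions

Volumes are rank-3 arrays in `(x, y, z)` order with `z` the 50 μm
sectioning axis; the working voxel is 20 × 20 × 50 μm (the 20×
in-plane downsampling of 1 μm STPT data). Physical coordinates are
micrometres with the origin at the corner of voxel `(0, 0, 0)`; a point
maps to voxel `floor(coord / spacing)` with half-open intervals, so a
coordinate exactly on a boundary plane belongs to the higher-index voxel.
Mirroring is always about the mid-`x` plane. NIfTI files carry spacing in
header zooms with micron units (millimetre zooms are converted); TIFF
stacks require a JSON sidecar — a file without spacing metadata is an
error, never a silent default.

Cells are detected on 2D sections, so regional counts start as `n2d`.
The 3D estimate is `n3d = 1.4 × n2d`, the cytoplasmic-signal conversion
factor established for this imaging protocol, applied to per-region sums
(equivalent to per-cell application by linearity). Regional volume is
`voxel_count × 20 000 μm³`, density is `n3d / volume_mm3`. Parent regions
in the ontology aggregate *summed* counts and volumes of their
descendants — never averaged child densities — so `density × volume = n3d`
holds at every node. Cells landing in background or outside the grid are
flagged and excluded from regional counts but kept in a conservation
report; the tables always include zero-count regions because the group
statistics need them.

## Registration

Two stages in physical space, in the classic whole-brain-mapping
configuration: a 3D affine over a 4-level image pyramid, then a free-form
cubic B-spline over a 6-level schedule. The similarity metric defaults to
Mattes mutual information (robust across ages and channels); mean squares
is available for same-modality work and is what the phantom studies use.
The affine stage is optimised by gradient descent with line search and
physical-shift parameter scaling; the B-spline stage by LBFGSB with the
control-point mesh held fixed across pyramid levels (the pyramid supplies
the coarse-to-fine schedule; default mesh 6³ control-point cells).
Metric sampling is either exhaustive or a seeded regular subsample
(default 25 %), so registration is deterministic for fixed inputs,
config, and seed. The optimiser trace per level is attached to the
returned transform; a finest-level divergence raises instead of returning
silently.

A `Transform` maps fixed-space points to moving-space points (the
resampling convention). Label images are always resampled
nearest-neighbour, so propagation can never invent a region id. Point
sets move the other way (moving → fixed) through a numerically inverted
map: fixed-point iteration `x ← x − (T(x) − p)` to 0.1 voxel tolerance,
which converges for non-folding deformations. Composition is associative
and is how the sequential cross-age route is built.

Defaults were chosen so a desk-scale volume (~64³ voxels) registers in
tens of seconds on one CPU; production-scale parameter sets can be loaded
through `RegistrationConfig`.

## Templates and label propagation

A template is built by registering every cohort member to a chosen
reference — by default the subject with the best left-right symmetry
score, the Pearson correlation between a volume and its mid-`x` mirror —
rescaling each registered subject to its 1st–99th percentile range (the
acquisition-gain-robust normalisation; the choice is ours, as no standard
exists for these data), and taking the voxelwise mean. One-pass
averaging only; iterative template refinement is a possible extension,
deliberately not done here. Labels travel from the adult-like reference
to each age directly, or through an intermediate age with composed
transforms when the morphological gap is too large for one hop — the
situation that motivates the sequential adult → P14 → P7 route.

## The phantom

The generator produces what the pipeline consumes, with known ground
truth, and nothing more — no PSF or noise modelling. The base brain is an
ellipsoid whose outer shells form a 6-layer "cortex" (one concentric
shell per layer, ~2.5 voxels thick, comparable to real laminar thickness
at the working resolution) around an interior with mirror-symmetric
left/right nucleus pairs and a midline nucleus. With asymmetry 0 the
intensity volume equals its mirror exactly; the asymmetry knob adds a
right-hemisphere bump. Subjects are generated by a random smooth
B-spline warp (3³ control mesh, default 40 μm displacement scale)
composed with a per-age global scale; the exact warp is returned, so
registration accuracy can be scored against truth.

Cell counts per region are negative binomial with mean
`density × volume` and size parameter θ (default 20, i.e. ~22 %
between-subject CV — mid-range for inter-animal variability of regional
cell counts; the real dispersions are unknown, so this is a free,
documented choice). Cells are placed uniformly inside their region and
carry their z-plane as `section_index`. 2D detection is emulated by
binomial thinning with probability 1/1.4, which makes the ×1.4 correction
exactly unbiased — the conversion factor and its emulation are an inverse
pair by construction. All randomness derives from one seed through
`numpy.random.SeedSequence` spawning.

What phantom success does *not* show: robustness to real microscopy
artefacts (stitching seams, bleaching, vascular shadows), to detector
false positives, or to genuinely different age-dependent tissue contrast;
the phantom's intensity pattern is the same at every age, which makes
direct registration easier than in real data.

## Group statistics

Counts per region are compared between groups with NB2 regression
(`Var = μ + αμ²`, log link, group indicator, log-volume offset).
Two inference routes:

* **Single-region test** (`nb_group_test`): dispersion by per-region
  maximum likelihood, likelihood-ratio test with a Bartlett-type scaling
  `LR / (1 + 3/N)` before the χ²(1) reference. The asymptotic reference
  is anti-conservative at N = 5 + 5 (empirical level ≈ 0.09); the scaling
  constant was calibrated once by null simulation across a grid of
  means and dispersions, giving empirical level 0.046–0.058 and
  near-nominal tails. A Wald option with a t(N−3) reference exists but
  is less well calibrated at this scale.
* **Many-region screen** (`compare_regions`, default): one *common*
  dispersion estimated by pooled within-group moments across all regions
  and held fixed in every region's LR test (scaling `1 + 1/N`). Sharing
  dispersion is the standard stabilisation for count screens with few
  subjects; it also avoids the power loss of re-estimating dispersion
  under each region's null. Regions with all-zero counts in both groups
  are flagged degenerate, given p = 1, and excluded from the FDR family
  so untestable hypotheses do not dilute the correction.

P-values are adjusted by Benjamini–Hochberg step-up (via statsmodels;
tested exhaustively against the textbook definition). Power is Monte
Carlo under the same NB model at significance 0.05 and assumed effect
size 0.85, N = 5 per group. Two effect conventions are exposed because
the standardized one (0.85 count SDs) yields the *same* power in every
region — per-region power statements are only meaningful when the effect
scales with the mean, so a fold-type alternative (`mean × 1.85`) is
available; the default follows the standardized reading.

The puncta positivity rule for single-molecule in situ counting is a
configurable comparator (`>= 4` by default, `> 4` available) because both
phrasings circulate. Spine densities are `10 × spines / length_μm` per
dendritic segment, compared by the two-tailed pooled-variance Student
t-test.

## Flatmaps

The flatmap bin volume (one positive bin id per cortical voxel on the
reference grid, plus a bin → 2D grid table) is an input artifact; this
package does not re-derive the cortical flattening. The phantom supplies
a toy bin map by laying a regular grid over the shell's angular
parameterisation, so all layers of one radial column share a bin. Layer
restriction intersects the bin volume with the superficial (layers 1–3)
or deep (layers 5–6) mask, resolving layer identity from acronym
suffixes (`2/3`, `6a`, `6b` count as their leading layer); layer 4 (and
any unmatched lamina) appears only in the full-cortex map. Bins emptied
by restriction are kept and reported as *missing*, not zero.

Per-bin density divides `1.4 × n2d` by the bin's **volume in mm³** (bins
are voxel sets, so "area" is interpreted as voxel measure), with
age-specific volumes obtained by warping the bin volume through the
reverse (reference → age) registration; there is deliberately no silent
fallback to reference-space volumes — the reference age passes an
identity transform explicitly. Rendering is deterministic; the TSV is
the source of truth and empty bins get a distinct missing colour.

## Problem sizes and numerical choices

The shipped studies run at desk scale, chosen as the package's own
test-design point: phantom grids of 40–64 voxels per axis, cohorts of
2–8 subjects, 100-replicate screens, 2000-replicate null calibrations.
Degenerate inputs are errors, not warnings: grids under 8 voxels per
axis, constant-intensity volumes for symmetry scoring, densities for
region ids absent from a label volume, cells assigned to regions with
zero voxels. Ties at voxel boundaries follow the half-open rule; the
B-spline inverse tolerance is 0.1 voxel; NB dispersion estimates are
floored at 1e-8 (the Poisson limit).

## Known limitations

* The registration defaults trade accuracy for desk-scale speed; at
  production scale the pyramid depths, mesh, and iteration counts should
  be raised (the config carries them all).
* The blob detector is deliberately minimal plumbing — thresholded
  connected components with area bounds — and is not a substitute for a
  trained cell classifier; it exists so the pipeline runs end to end
  from images.
* Sequential-vs-direct label propagation is demonstrated in the regime
  where cumulative deformation exceeds a single registration's model
  capacity; with gentler morphing a direct hop can match or beat the
  two-step route because each registration contributes its own error.
* Small phantom nuclei have single-digit expected counts, so
  power-fraction summaries over phantom regions mix well-powered large
  regions with intrinsically underpowered tiny ones.
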