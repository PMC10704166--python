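# Methods

## The forward model

The package solves the quasi-static volume-conduction equation
∇·(σ∇φ) = 0 on a labelled voxel grid.  Tissue is assumed linear, isotropic
and purely resistive (no capacitive or frequency-dependent effects — a
standard assumption for direct-current stimulation).  Current enters the
model as a pure Neumann condition: the total current *I* is distributed
uniformly over the outer-face voxels of the anode pad, −*I* over the
cathode's, and every other boundary face carries zero flux, so no current
leaks through the head surface by construction.

**Discretization.**  A finite-volume 7-point stencil on the voxel grid.
The conductance of the face between neighbouring voxels *i*, *j* is
H(σᵢ, σⱼ)·A/d with H the harmonic mean, A the face area and d the
center-to-center spacing.  The harmonic mean is exact for layered media
(series resistors), which is the dominant geometry in a head — skin, skull
and CSF form nearly concentric layers.  Voxels with σ = 0 (air) are excluded
from the unknowns rather than given a tiny conductivity; this keeps the
operator well conditioned and makes the zero-flux boundary exact.  The
operator is symmetric with zero row sums, i.e. it conserves current
discretely.

**Solve.**  The pure-Neumann operator is singular (constants in the null
space).  With a compatible source (components summing to zero) conjugate
gradients stays in the range space, so the singular system is solved
directly with Jacobi preconditioning to a relative residual of 1e-10
(default; configurable, capped at 1e-4).  The free constant is fixed by the
mean-zero gauge over the conductive domain.  The solve is deterministic, and
negating the source negates the iterates exactly, which is why
anode/cathode reciprocity holds bit-for-bit in the tests.  A relative
residual of 1e-10 is far below the discretization error at 1–2 mm voxels;
the choice buys exact-looking invariants (linearity, reciprocity,
plane-flux conservation) at negligible cost (~500 CG iterations, about a
second per head at 96³).

**Fields.**  E = −∇φ by central differences inside the conductive domain and
one-sided differences at its boundary; J = σE per voxel.  Outside the
conductive domain fields are NaN — "no tissue" is deliberately distinct
from "zero field" in all outputs.

**Verification.**  The solver is checked against independent oracles rather
than against itself: series-resistor chains and layered slabs (closed
forms), a dense pseudoinverse solve on small grids, plane-flux conservation
(flux through any interior cross-section equals *I*), and the uniform-slab
dose identity |J| = I/A — with I = 2 mA through a 35 cm² cross-section,
0.571 A/m² ≡ 0.057 mA/cm².

## Head phantoms and atrophy

Real segmented MRI heads are replaced by multi-shell ellipsoids: a WM core,
a 4 mm GM shell, CSF, skull and scalp, with default outer radii 58 / 64 /
70 / 77 mm — an adult-sized head.  A voxel belongs to the innermost shell
containing its center, which makes rasterization orientation-free and
deterministic; identical spec + seed reproduces a volume bit-for-bit.

Atrophy is a single scale factor in (0, 1] on the brain's outer radius: the
skull and scalp stay fixed and CSF fills the vacated space, thickening the
CSF layer around the brain.  An interior CSF ellipsoid ("ventricle analog",
default 12 mm) grows as 1/atrophy to mimic ventricular enlargement.  The
brain volume ratio (GM+WM)/(GM+WM+CSF) is then strictly decreasing in
atrophy, and — because CSF is ~6× more conductive than gray matter — the
median brain current density decreases with it.  This CSF-shunting
mechanism is the phantom-level analog of the empirical finding that more
atrophied brains receive less current at a fixed dose.

A cohort spreads atrophy scales evenly (plus seeded jitter) across a range,
default [0.86, 1.0] over 16 subjects.  No published quantitative atrophy
range exists for the comparison this emulates, so the default was chosen
once to produce volume-ratio spreads wide enough to resolve the regression
at 2 mm resolution, and is documented here rather than tuned.  Head size
and per-axis ellipticity receive small multiplicative jitter (SD 2% and 1%)
to emulate inter-individual anatomy.

**ROI analogs.**  FreeSurfer parcellation is meaningless on an ellipsoid, so
regions of interest are angular sectors of the brain measured from the
inter-electrode midline direction: the superior-frontal analog is the cap
within 25°, the middle-frontal band 25–45° (anterior half), the
inferior-frontal band 45–65° (anterior, below 27° elevation), and the
temporal analog the lateral sector beyond 75° that is posterior-inferior to
the electrodes.  The bands are disjoint by construction and configurable.

## Electrodes

Both electrode models drape a 70 × 50 mm pad with a conductive-gel layer
onto the scalp.  Within an oriented rectangular footprint (long axis along
the azimuthal direction toward the opposite electrode), gel occupies the
first 3 mm of space above the head surface (by Euclidean distance to the
head) and the pad the next 3 mm.  Draping reproduces the intended 35 cm²
pad–scalp interface exactly on a flat surface, conforms to curved scalps
with no gel–skin gap, and is clamped to at least one voxel layer on coarse
grids.  Electrode voxels not face-connected to the head are discarded
(staircase islands would be floating conductors).

* **Artificial mode** places the pad at the planned anchor exactly — the
  idealized-pipeline behaviour.
* **Real mode** emulates as-placed electrodes: the anchor shifts
  tangentially by a systematic 13 mm away from the head midline plus
  isotropic Gaussian scatter (SD 5 mm, truncated at 2 SD), the pad rotates
  about its normal (SD 10°, truncated), and the gel footprint area is
  multiplied by a uniform draw from [0.90, 1.40] — erosion below 1 models
  obstructed contact, dilation above 1 models paste smear.

The generative process behind real-world placement scatter is not
observable; only the resulting distributions are.  The perturbation
defaults were therefore calibrated once so that a 16-subject cohort
reproduces the reported distributions of the study this package emulates —
idealized separation 4.7 ± 1.2 cm versus as-placed 7.2 ± 1.4 cm, and
normalized as-placed contact area 1.12 ± 0.10 — and then frozen.  Per
subject, one seeded anchor jitter (SD 11 mm) is applied identically to both
models before the real-mode perturbation, so the "real" deviation is
relative to that subject's planned montage.  In this additive model the
as-placed variance necessarily exceeds the idealized variance for every
metric; the emulated study's printed separation SDs (1.22 vs 1.06 cm) order
the other way, which a shared-jitter-plus-independent-noise model cannot
reproduce and which we treat as cohort idiosyncrasy.

**Metrics.**  Contact area counts gel–skin face pairs at 6-connectivity
times the face area.  On a flat interface this equals the geometric area;
on an obliquely oriented scalp patch the staircase measure converges under
grid refinement to ∫(|n_x|+|n_y|+|n_z|)dA rather than to the geometric
area, so absolute areas on the sphere exceed 35 cm² by an
orientation-dependent factor (~1.6 for the default montage).  The analysis
only ever uses *normalized* areas (each area divided by the idealized-model
mean), which cancel the factor.  Separation distance is the Euclidean
distance between the two pads' facing short-edge midpoints, measured on the
scalp-facing pad face; ties between equidistant midpoints break toward the
anterior one.

## The paired comparison study

Each subject's tissue volume is solved twice — once per electrode model —
and the tissue labels are verified to be bit-identical across the two
solves, so every difference in the fields is attributable to the electrode
geometry alone.  Region summaries use medians of |J| (robust to the skewed
voxel distributions); paired differences are expressed as
PD = 100·|artificial − real|/real.  If a pad placement fails (colliding
footprints in the jitter tails) the subject's seeded jitter is redrawn, up
to five times — the synthetic analog of re-sticking a misplaced pad — and
the whole study is a deterministic function of one master seed.

Statistics are intentionally plain: paired t-tests (two-sided, t-CDF via
the regularized incomplete beta function, cross-checked against scipy) and
ordinary least squares with R² and the slope's t-based p-value.  No
multiple-testing correction is applied anywhere, matching the uncorrected
reporting convention of the emulated analysis; voxelwise paired t-maps use
α = 0.001 uncorrected on the shared phantom grid (phantoms are
co-registered by construction, so no template registration exists).
The Dice operand for volume similarity is not standardized for continuous
current-density volumes; this package binarizes each volume at its own
99th percentile (configurable) before computing overlap.

## Problem sizes and defaults

| parameter | default | note |
|---|---|---|
| grid / voxel | 96³ at 2 mm | whole pipeline ~2.5 s per subject model |
| cohort size | 16 | two solves per subject |
| input current | 2 mA | fixed-dose convention |
| solver tolerance | 1e-10 relative | ≪ discretization error |
| atrophy range | [0.86, 1.0] | documented choice, see above |
| ROI sector bounds | 25/45/65/75° | configurable |

The 2 mm default (rather than the 1 mm typical of MRI-based pipelines) was
chosen as the package's standard problem size; 1 mm grids are supported
through the same configuration surface and are used in the refinement
tests.

## What the synthetic cohort does and does not show

The phantoms reproduce the *mechanisms* — CSF shunting of injected current,
dose sensitivity to electrode separation, frontal-target versus
temporal-control dose ordering — and the tests assert directions,
significance and self-contained arithmetic, not the emulated study's
participant-specific magnitudes, which depend on private MRI anatomy.
Smooth ellipsoids lack gyral folding, skull inhomogeneity, anisotropic
white matter and realistic scalp topology; absolute ROI medians and R²
magnitudes on phantoms should therefore not be read as predictions for real
heads.  Within those limits the pipeline reproduces the published
self-contained numbers it can reach: the 0.057 mA/cm² slab dose arithmetic,
every printed percent-difference pair in the bundled reference table, the
normalization identity (idealized mean ≡ 1), and electrode-property
distributions matching the reported means.

## Known limitations

* Rigid draping without mechanical pad bending; extreme curvature with
  large pads will under-cover.
* Face-count contact areas are orientation-dependent (see above); only
  normalized areas are comparable across montages.
* Isotropic conductivities; no anisotropic WM tensor support.
* The real-mode perturbation model is a stand-in for unobserved physical
  placement errors (hair, head-coil pressure); its functional form is a
  design choice, its moments are calibrated.
* The rubber pad conductivity (0.59 S/m) is a typical conductive-rubber
  value, not a measured one; it is configurable, and the solution is
  insensitive to it because the gel layer dominates the interface.
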