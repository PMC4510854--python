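# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `cytoarch3d`. It is the package's own account of its
science; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`, not asserted.

## Coordinate and unit conventions

Voxel arrays are indexed `(z, y, x)` with `z` the sectioning axis; voxel
sizes are `(x, y, z)` in nm. All public coordinates are 0-based,
voxel-centre, physical nm — voxel indices never cross module boundaries, so
every distance is representation-independent and anisotropy-aware
(Euclidean after scaling indices by the voxel size).

The cell is oriented as in a serial block-face acquisition of the organ of
Corti: the apico-basal long axis lies **in-plane along y** (basal pole at
low y), the flattened/rounded lateral asymmetry along **x**, and serial
sections advance along **z**, which also carries the anterior/posterior
split. Modiolar/pillar naming of the x-axis split is anatomical context
that cannot be derived from a single-cell volume; the caller supplies it
(`flat_faces`).

## Cell frame

* **Dynamic centre line** — per-section area centroid of the cell mask,
  smoothed with a 5-section moving average. The centroid is the simplest
  asymmetry-aware choice: the rounded side's bulge shifts the dividing
  line appropriately. Translation-equivariant; an empty section inside the
  cell's z-range is an error naming the section.
* **Hemispheres** — flattened/rounded (and modiolar/pillar) split the cell
  through the centre line along the y–z plane; anterior/posterior split at
  the cell's mid-section along z, anterior being the end where the cell
  first appears. All partitions are exact (disjoint, exhaustive).
* **Flatness** — measured on the central section: per side, a line
  parallel to the long axis is placed tangent to the maximal lateral
  extent over the requested depth bands (default 1–4, 5–7 and 7–11 µm
  below the neck); the per-band mean boundary-to-line distance is the
  deviation. The neck is the minimal cross-section above the nucleus
  (override available). The flatter side has the lower mean deviation
  across bands; ties are flagged and broken toward a configurable side.
  How the tangent lines are anchored is a documented assumption (tangent
  at maximal extent); an analytic hemicylinder reproduces the closed-form
  mean sagitta R(1 − π/4) under it.
* **Infranuclear region** — cell voxels strictly basal to the nucleus'
  basal-most extent; the peri-nuclear window (1.5 µm either side of the
  nucleus z-midline, 60 sections at 50 nm) is emitted for partial-volume
  stereology.

## Stereology

Systematic point grids with a seeded uniform-random origin offset within
one spacing cell (removing raster-alignment bias; fixed offsets available).
Whole-cell mode: 200 nm spacing in all three axes (the in-plane spacing is
not independently fixed by the acquisition convention and is exposed as
config). Partial mode: every 50 nm section inside the peri-nuclear window.
A point takes the semantic class of its containing voxel; nucleus and
ribbon voxels count as cytoplasm, terminals lie outside the cell. The
volume fraction of membranes+mitochondria in a region is the hit fraction
among in-cell points with binomial SE; on analytic solids the estimator is
unbiased (sphere-in-cube recovery within 2 SE at 100 nm spacing), and
estimates are invariant to label renumbering.

## Sheet assembly and classification

Strands are per-section 8-connected membrane components; lengths are the
8-neighbour edge sums of their 2D skeletons. Two strands in adjacent
sections belong to one sheet when their in-plane pixel sets overlap by at
least `overlap_min` (default 1) pixels; a centroid-distance alternative
(≤100 nm) is provided for sensitivity analysis. Gaps in z never join
sheets (strict adjacent-section rule). Sheet linkage is exactly the
transitive closure of the pairwise overlap relation (verified against a
brute-force oracle on random instances).

Areas follow the representative-tube model (50 nm radius = half the
section spacing). The default `sheet_face` convention, Σ length × Δz,
approximates the face area of the implied sheet; `tube_surface`
(Σ 2πr·length) is always emitted alongside because reference per-sheet
area conventions are not generally recoverable — reference mean areas for
the *smallest* class can exceed what a face-area reading of a single cell
would allow, so both conventions are reported and the discrepancy is
documented rather than resolved.

Classification into Type 1 (few very large sheets), Type 2 (intermediate
plateau) and Type 3 (numerous small sheets): the Type 1 boundary is the
widest gap among the top 25 log₁₀-area order statistics (requiring ≥0.25;
otherwise no Type 1 and, if the whole census spans <0.05 in log-area, a
flagged degenerate single class); the Type 2/3 boundary is the breakpoint
of a two-segment least-squares fit to the top 50 sorted log-areas versus
rank — the "flat plateau then steep fall" elbow. Classification is
monotone in area and conserves total area. On well log-separated 3/8/2000
censuses the split is recovered exactly in ≥95% of seeds; on censuses with
the reference dispersion (sd reconstructed as s.e.m.·√n) the Type 2/3
boundary is intrinsically ambiguous and recovered mean areas for Type 2
run a few percent low.

## Spatial statistics

* **Association** — the surface gap between two voxelized objects is the
  minimal voxel-centre distance minus one in-plane voxel pitch (floored at
  0), so in-plane face contact reads as zero gap; "close association"
  means gap ≤ one in-plane voxel (19 nm) — the operational form of "no
  visible gap in section images". The threshold is config and echoed in
  outputs; association is monotone in it. Distances use voxel positions
  on both sides except ribbon centres (the ribbon is reduced to its
  approximate centre), and all nearest-distance operations equal
  brute-force search (checked on random ≤64³ volumes).
* **Densities** — mitochondria touching exactly one membrane type, divided
  by that type's total area; densities recompose to the single-type count.
* **Terminals** — located by voxel centroid; the longitudinal position is
  the straight-axis distance from the basal pole (a curved-axis convention
  would differ but is not used; documented choice).
* **Group tests** — Welch/paired t, one-way ANOVA with Games–Howell post
  hoc (implemented from the Welch statistic and the studentized-range
  distribution, cross-checked against an independent reference
  implementation), and Kruskal–Wallis. No additional multiplicity layer is
  stacked on Games–Howell.

## Tomogram morphometry

Tether length is surface-to-surface: the tether is skeletonized in a local
crop, its path traced, and the arc length plus a 1.5-voxel end correction
reported. The correction compensates the stand-off between terminal
skeleton voxels and the adjacent structure surfaces; it was calibrated on
rasterized known-gap phantoms (axis-aligned and oblique), after which
per-context biases are ≲1 nm at 2 nm voxels. The straight chord between
attachment points is emitted alongside (filament-path vs chord conventions
differ between studies). Endpoints resolve to the structures the tether
touches; a vesicle–vesicle link within 100 nm of the ribbon surface is
"@ribbon" (operational cutoff, config). Vesicle diameters are
equivalent-sphere diameters from voxel volume, 2(3V/4π)^{1/3}; objects
under two voxels across are flagged unreliable; location classes use the
centroid-minus-radius surface distance (exact for spheres up to
discretization).

## Synthetic phantoms

The generators define the study conditions; all geometry is laid out in nm
and rasterized second, so distance truths are exact.

**Cell phantom.** Flask profile along y (basal cap, body, neck
constriction at 0.86 of the cell length, cuticular head); cross-sections
perpendicular to the long axis are two half-superellipses (exponent 6 on
the flattened side, 4 on the rounded — boxier sections keep the
organelle-bearing band wide); each side carries a mid-cell Gaussian bulge
whose rounded:flattened amplitude ratio is `flatness_contrast` (default
3). The cell axis drifts sinusoidally in x along z so the centre line is
genuinely dynamic. Defaults mirror the imaged biology: 19×19×50 nm
voxels, ~30×15 µm cells with ~11 µm infranuclear cytoplasm, 16 terminals
with flattened-side probability 0.63 (≈10.1 of 16.1), 16 ribbons,
flattened/rounded membrane+mitochondria volume fractions 0.23/0.16
(anterior/posterior 0.21/0.19 available as an alternative plant axis —
both axes at once are generally inconsistent and are refused).

Membrane sheets are boundary-following curtains on four concentric shells,
3 voxels thick, one strand per section; each section also carries the next
section's trace (as a real surface cut by finite sections would), which
guarantees the pixel overlap the linkage rule needs, so the planted census
is recovered exactly. Ribbons sit near the basolateral membrane; each is
placed a gamma-distributed stand-off (mean 515 nm, sd 370 nm = s.e.m.·√n
of the reference summary) below the basal tip of a dedicated Type 3
partner sheet, with membrane-free corridors enforced so the planted
nearest-Type-3 distance survives; the recorded truth is the exact post-hoc
nearest distance. Mitochondria are rounded blobs grown from seeds adjacent
to a sheet with probability `p_mito_association` (0.96, the midpoint of
the observed 95–98%) or seeded in the membrane-free sectioning fringe
otherwise; growth claims free cytoplasm until the per-hemisphere fraction
target is met exactly, to the voxel. (An earlier analytic-ellipsoid packing
could not robustly reach 23% — that target sits at the packing limit of
the membrane-adjacent band — hence growth; blob shapes are mito-like and
association/distance truths remain exact.) Per-blob touched-type truth is
measured post hoc with the same gap convention the analysis uses.

**Tomogram phantom.** 2 nm isotropic voxels; a stack of three RER
cisternae decorated with small mitochondria and vesicles, and a ribbon
surrounded by radial vesicle chains, in a ~0.7×1.75×0.76 µm field. Planted
per-context tether lengths are gamma with the reference means
(30.9 / 52.9 / 45.4 / 22.3 / 26.8 nm) and sd = s.e.m.·√n at the reference
n (44 / 63 / 61 / 78 / 36); vesicle diameters are normal with mean 37.3 nm
(sd 5) away from the ribbon and 36.3 nm (sd 4.7) at it. Tethers are
rasterized straight segments between surfaces (curvature out of scope —
only lengths are measured).

**Sheet-area mixtures.** Two numeric censuses: `reference_scale()` (3/8/2073
sheets, mean areas 38 000/2383/85 µm², sd = s.e.m.·√n — the reference
dispersion) and `separated()` (3/8/2000, tighter sds), the latter being
the "well log-area-separated" planted-partition condition under which
exact class recovery is a meaningful requirement.

**What the phantoms do not emulate:** EM texture, noise, the point-spread
function, segmentation errors, membrane curvature in-plane beyond the
boundary-following shape, organelle shape diversity, or supranuclear
content. Passing recovery tests therefore demonstrates correctness of the
measurement chain on clean segmentations, not robustness to segmentation
quality.

## Problem sizes

Tests and the acceptance script run on scaled-down cells (~4×8×4 µm at the
native 19×19×50 nm voxel size, with proportionally fewer sheets, ribbons
and terminals) and on full-condition tomograms; this is the package's own
choice of desk-scale replicate size. The acceptance script pools
replicates — 4 fully-featured cells, 24 lighter ribbon-bearing cells, 56
terminal-bearing cells, 3 tomograms, 50 numeric censuses — so that each
reported mean carries a sampling error well inside the dispersion of the
quantities it recovers. Full-scale (~30×15 µm) cells generate with the
same code but need several hundred million voxels.

## Known limitations

* The flatness tangent anchoring and the in-plane-biased gap convention
  are documented operational choices, not uniquely determined by the
  imaging convention they formalize.
* Terminal hemisphere counts follow a Bernoulli placement law; patterns
  that a single observed cohort shows (e.g. a flat-side majority in 7 of 8
  cells) replicate across seeds only at the rate the binomial law allows.
* Sheet areas from skeleton lengths carry a few percent of rasterization
  bias for the smallest profiles.
* The Type 2/3 boundary is only exactly recoverable when the planted
  populations are log-separated; at the reference dispersion it is
  intrinsically fuzzy.
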