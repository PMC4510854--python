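# cytoarch3d

Quantitative 3D cytoarchitecture analysis for segmented volume-EM data,
built around the workflow used to dissect the infranuclear organisation of
cochlear inner hair cells (IHCs): flask-shaped sensory cells whose
intracellular membranes, mitochondria and afferent synapses segregate
toward one ("flattened") side of the cell.

Given integer label volumes (multi-page TIFF + JSON sidecar, or MRC) on
anisotropic voxels — e.g. 19×19×50 nm serial block-face SEM stacks, or
2 nm isotropic electron tomograms — the package provides:

* **Cell frame** (`cell_geometry`) — dynamic centre line (per-section area
  centroid), flattened/rounded, modiolar/pillar and anterior/posterior
  hemisphere partitions, a boundary-flatness metric per depth band below
  the neck, and the infranuclear region.
* **Point-counting stereology** (`stereology`) — systematic point grids
  (200 nm whole-cell mode; every-section partial mode around the nucleus),
  point classification (`not_in_cell` / `cytoplasm` / `membrane` /
  `mitochondrion`) and per-region volume fractions
  V̂_V = hits / points, with binomial SE √(p(1−p)/n).
* **Membrane-sheet assembly** (`sheet_assembly`) — per-section strands
  (8-connected membrane profiles, skeleton lengths), linkage of strands in
  adjacent sections that lie directly above each other into putative
  sheets, tube-model areas (Σ length × Δz face convention, 50 nm tube
  radius; tube-surface convention also emitted), and Type 1/2/3 size
  classification (few very large sheets / intermediate plateau / numerous
  small sheets) by a largest-gap + two-segment-elbow rule on log-areas.
* **Spatial statistics** (`spatial_stats`) — mitochondrion–membrane
  association (surface gap ≤ one in-plane voxel), per-type mitochondrial
  densities, ribbon-centre-to-nearest-sheet distances per type, terminal
  hemisphere distributions, region volume/area shares, and group tests
  (Welch/paired t, one-way ANOVA with Games–Howell post hoc,
  Kruskal–Wallis).
* **Tomogram morphometry** (`tomo_links`) — tether (linkage) lengths by
  structural context (mito–RER, vesicle–RER, vesicle–vesicle at RER or at
  the ribbon, vesicle–ribbon), skeleton-arc surface-to-surface convention,
  and equivalent-sphere vesicle diameters.
* **Synthetic phantoms** (`synthetic_data`) — cell-scale and
  tomogram-scale label volumes with complete planted ground truth
  (hemisphere volume fractions, sheet census and areas, association
  probability, ribbon distances, tether lengths, vesicle diameters), so
  every stage is validated by parameter recovery.
* **Pipeline + CLI** (`pipeline`, `cytoarch3d …`) — config-driven,
  seeded, byte-reproducible runs.

## Worked example

```python
from cytoarch3d.synthetic_data import CellGenParams, generate_cell_volume
from cytoarch3d.cell_geometry import build_cell_frame
from cytoarch3d.stereology import make_point_grid, classify_points, volume_fraction

vol, truth = generate_cell_volume(CellGenParams.small(seed=1))
frame = build_cell_frame(vol, flat_faces=truth.summary["flat_faces"])
grid = classify_points(make_point_grid(frame.infranuclear, vol.voxel_size, rng=1),
                       vol, frame)
idx = vol.nm_to_index(grid.points_nm)
inside = frame.infranuclear[idx[:, 0], idx[:, 1], idx[:, 2]]
for hemi in ("flat", "round"):
    sel = inside & (grid.hemisphere_tags["flat_round"] == hemi)
    est = volume_fraction(grid, region=sel, region_name=hemi)
    print(f"{hemi:5s} membrane+mito fraction {est.fraction:.3f} ± {est.se:.3f} "
          f"(n={est.n_points})")
```

prints (cell planted with 0.23/0.16 flattened/rounded fractions):

```
flat  membrane+mito fraction 0.228 ± 0.008 (n=2910)
round membrane+mito fraction 0.161 ± 0.007 (n=2841)
```

i.e. the point-counting estimate recovers the planted hemisphere volume
fractions within one standard error, and the flattened-side enrichment of
the membrane–mitochondria network is directly visible.

The same pipeline runs from the shell:

```sh
cytoarch3d run --seed 4 --out runs/demo
cytoarch3d report runs/demo
```

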