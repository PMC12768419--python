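# Output files and column dictionaries

`corneasim run` (and `corneasim.cli.run_scenario`) writes one set of files
per replicate into the output directory.

## `metrics_rep<k>.csv`

One row per sampling interval (default every 40 MCS = 4 h).

| column | meaning |
|---|---|
| `mcs` | Monte Carlo step of the sample |
| `day` | simulated day (`mcs / 240`) |
| `thickness_com_um` | central-region thickness, superficial-minus-basal center of mass, μm (NaN while a layer is missing) |
| `wound_open_fraction` | fraction of surface columns whose top epithelial voxel is not superficial |
| `stratified` | all four epithelial types present in depth order |
| `mean_egf_basal` | mean EGF concentration over basal-cell voxels, arb. units |
| `n_stem`, `n_basal`, `n_wing`, `n_super` | live cell counts per type |
| `bin_top_0..9` | per-segment apical height (topmost epithelial voxel), μm |
| `bin_thick_0..9` | `bin_top` minus the membrane height, μm |
| `bin_super_y_0..9` | per-segment mean superficial-cell height, μm (the uniformity statistic) |

Segments split the x-axis into 10 equal bins; bin 0 is the limbal end.

## `events_rep<k>.csv`

One row per cell event.

| column | meaning |
|---|---|
| `mcs` | step of the event |
| `cell` | cell id (ids are never reused) |
| `event` | `divide`, `differentiate`, `slough`, `culled`, `crushed`, `dying`, `chem_death`, `injury` |
| `old_type`, `new_type` | type codes before/after (−1 when not applicable) |
| `lifetime_mcs` | birth-to-removal lifetime (removal events only) |
| `layers` | anatomical layers traversed, vertical climb / 5 voxels (removal events only) |

## `summary_rep<k>.json`

Provenance (config digest, seed, package version), final counts,
stratification and stability days, final thickness.

## `cells_rep<k>.csv`

Live-cell registry at the end of the run: id, type, volume (voxels),
centroid x/y (voxels).

## Snapshots

`final_rep<k>.png` renders the type map with the standard palette (stroma
lilac, limbal membrane pink, central membrane magenta, stem rose, basal
peach, wing blue, superficial cyan, tear green, medium black).  Field
heatmaps and legacy-VTK structured-points dumps are available through
`corneasim.io.snapshot` with kinds `field:<name>` and `vtk`.
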