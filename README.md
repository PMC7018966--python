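# scartools

Quantitative analysis of cardiac scar tissue, in two pipelines:

- **`scartools.spread`** — passive-spread electrophysiology from optical-mapping
  data: voltage movie → maximal-amplitude map → region masking → equal-width
  (isopotential) amplitude bins → edge-referenced radial distances →
  single-exponential fit of the tissue **decay constant** (the distance at
  which amplitude falls to 1/e ≈ 37% of the edge amplitude) → per-group
  summaries normalized to a control group.
- **`scartools.morpho`** — morphometrics of labeled 3D voxel volumes
  (e.g. segmented serial block-face SEM stacks): per-cell volumes and
  voxel-face surface areas, intercellular contact interfaces (6-connected
  shared faces, anisotropic face weighting), the cell-contact network, and
  per-cell-type summaries.
- **`scartools.synth`** — synthetic voltage maps/movies (pure exponential
  decay or a finite-difference cable-equation steady state) and packed
  multi-cell label volumes, each emitted together with its exact ground
  truth, so every downstream stage has a recovery test.

All array inputs/outputs travel as multi-page TIFF with a JSON sidecar
(`<file>.tif.json`) carrying the physical metadata (pixel pitch in mm,
frame rate, voxel pitch in nm, label→type tables, RLE-encoded masks,
ground truth). Results are CSV/JSON.

## CLI

```sh
scartools simulate-map     --config map.yaml  --out out/sim     # map or movie + ground truth
scartools simulate-volume  --config vol.yaml  --out out/vol     # label volume + ground truth
scartools amplitude-map    --movie out/sim/movie.tif --pulse-window 10 30 --out out/amp
scartools decay-constant   --map out/sim/map.tif --annotation out/sim/annotation.json \
                           --region scar --n-bins 5 --out out/fit
scartools morphometrics    --labels out/vol/labels.tif --out out/morpho
scartools group-summary    --config groups.yaml --out out/groups
```

Every output directory contains `run_config.json` with the exact config,
its hash, the seed, and the package version. `--seed` overrides the config
seed for the simulators. Example map config:

```yaml
grid_shape: [220, 220]
pixel_pitch: 0.0928          # mm / pixel
electrode_center: [109.5, 109.5]
scar_mask:
  sector: {r_inner_px: 21.6, r_outer_px: 37.1, angle_start_deg: 30, angle_end_deg: 70}
lambda_scar: 0.48            # mm
lambda_uninjured: 0.57       # mm
v_edge: 10.0                 # a.u.
noise_sd: 0.0
mode: pure_exponential       # or cable_steady_state
seed: 1
# movie: {frames: 40, pulse_window: [10, 30], frame_rate: 1000}
```

## Conventions

- Volumes are indexed `(z, y, x)`, 0-based; label 0 is extracellular
  matrix/background; voxel pitch is stated in nm, derived quantities in
  μm³/μm². Surface and contact areas are voxel-face sums (reproducible and
  oracle-checkable); a marching-cubes mesh area is available as a clearly
  labeled secondary estimate (`morpho.mesh_surface_area`).
- Maps are indexed `(row, col)` with pixel pitch in mm; distances are
  continuous Euclidean distances from the electrode center, referenced to
  the analyzed region's closest edge (minimum distance = 0).
- Binning uses equal-width amplitude intervals between the in-mask min and
  max (bin 1 = highest amplitude); bins with fewer than 5 pixels merge into
  their lower-amplitude neighbor and are flagged.
- All generators are deterministic for a fixed spec + seed.
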