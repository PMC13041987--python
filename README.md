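# epimend

Headless curation toolkit for segmented-and-tracked 2D time-lapse movies of
confluent epithelia.

Automatic segmentation and tracking of epithelial movies is never perfect:
cells get falsely split or merged, drop out for a frame, or swap track
identities, and those errors cascade into wrong track durations, wrong
division/extrusion counts and biased feature measurements.  `epimend`
implements the computational core of an assisted-curation workflow as a
library and CLI, with no GUI dependency:

- **core** – label-movie data model (T×Y×X integer movies, 0 = background),
  validity checks (one 4-connected region per label, confluence), junction
  skeletons and cell adjacency graphs.  Both "dense" movies (cells share
  edges) and "junction-gap" movies (1-px background skeleton) are supported.
- **io** – multi-page TIFF label/intensity/probability movies, CSV track and
  event tables (with column aliases for third-party trackers), JSON/CSV edit
  scripts, YAML config.
- **tracking** – frame-to-frame linear assignment (squared centroid distance
  × relative-area penalty, hard similar-area and pixel-overlap gates, no-link
  alternative priced at `max_link_distance²`), gap closing, post-hoc division
  hypotheses, and local track relinking after every edit.
- **inspection** – suspicious-track flags: unexplained appearance /
  disappearance, area jumps, position jumps, very short tracks; registered
  division/extrusion events and border cells are exempt.
- **corrections** – scripted edit operators with automatic relinking:
  `merge`, `split_seeded` (marker watershed), `draw_junction`,
  `remove_cell`, `swap_tracks`, `set_track`, `fill_hole`, plus batch replay
  of JSON edit scripts.
- **events** – rule-based division detection (one track ends, two start
  nearby), extrusion detection (early interior end with a small apical
  area), cross-filtering against an external event-probability movie, fate
  groups ("Dividing"/"Extruding") and relative-area-to-event time series.
- **measures** – per-cell features (`area`, `perimeter`, `shape_index`,
  `NbNeighbor`, `orientation`, junctional/cytoplasmic intensity) and
  per-track features (duration, average speed, straightness), intensity
  threshold group classification, per-frame mean ± 95% CI temporal tables.
- **evaluation** – before/after curation metrics: pooled skeleton IoU,
  cell-count error, track-duration error, track-area error.
- **synthetic** – a weighted-Voronoi epithelium simulator with exact
  ground-truth tracks and lineage, scheduled divisions (programmed
  pre-division growth) and extrusions, a junction-bright intensity render,
  event-probability movies, and an error injector whose corruptions come
  with an exact inverse edit script: replaying it restores the ground truth
  bit-for-bit.

## CLI

Everything is reachable through one entry point:

```sh
# synthetic dataset: ground truth + corrupted copy + inverse edit script
epimend simulate --seed 1 -o data/

# build tracks, flag suspicious ones
epimend track data/corrupted_labels.tif -o data/tracks.csv
epimend inspect data/corrupted_labels.tif data/tracks.csv -o data/flags.csv

# replay corrections, detect + filter events, measure, evaluate
epimend correct data/corrupted_labels.tif data/fixed.tif \
    --script data/inverse_edits.json --tracks data/corrupted_tracks.csv \
    --out-tracks data/fixed_tracks.csv
epimend events data/corrupted_tracks.csv \
    --probability data/event_probability.tif -o data/events.csv
epimend measure cells data/fixed.tif --features area,NbNeighbor -o cells.csv
epimend evaluate data/corrupted_labels.tif data/truth_labels.tif \
    --tracks-before data/corrupted_tracks.csv \
    --tracks-after data/truth_tracks.csv
```

Exit codes: 0 success, 1 usage error, 2 data/integrity error.  A YAML config
(`--config run.yaml`) provides defaults per section (`tracking`,
`inspection`, `events`, `simulation`, `corruption`); explicit flags win.

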