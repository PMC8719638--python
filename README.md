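# polarpunc

Quantitative image analysis for front-polarized, substrate-fixed protein
puncta in migrating amoeboid cells.

Fast-moving immune-like cells (e.g. HL-60 neutrophils under agarose) form
diffraction-limited puncta of actin nucleation-promoting factors on their
ventral surface. These puncta are striking in three ways: they stay fixed
to the substrate while the cell slides over them, they nucleate close to
the leading edge, and they are extinguished before the cell's midline — a
front-restricted "permissive zone". `polarpunc` implements the measurement
chain needed to establish and quantify that behaviour:

* **synthetic scenes** (`polarpunc.synthetic_scene`) — calibrated,
  ground-truthed time-lapse stacks: a polarized elliptical cell
  translocating over substrate-fixed puncta, rear-biased second marker,
  substrate beads with size- or position-dependent marker signal, EDTA mode
  (retrograde punctum flow) and nanoridge mode (heading-biased migration);
* **detection** (`polarpunc.puncta_detection`) — difference-of-Gaussians
  band-pass, weighted Otsu threshold, 2-D Gaussian fits; a punctum's
  background-independent signal is the volume under its fitted Gaussian,
  `2π·A·σx·σy`;
* **tracking** (`polarpunc.puncta_tracking`) — optimal-assignment linking
  with gap closing, track filtering, substrate-fixed vs flowing
  classification, kymographs;
* **cell-frame statistics** (`polarpunc.cell_frame`) — segmentation,
  automatic front/rear anchors, relative positions `p` (rear = 0,
  front = 1) and `q = 1 − p` (distance from front), spatial histograms,
  appearance/extinction positions and their empirical CDFs;
* **bead enrichment** (`polarpunc.bead_enrichment`) — marker signal at
  substrate-attached beads normalized per sphere surface area `π·d²`
  (curvature comparison), position-resolved bead profiles, gain/loss maps;
* **colocalization** (`polarpunc.colocalization`) — Pearson r over square
  ROIs with a 90°-rotation negative control;
* **migration** (`polarpunc.migration_stats`) — total/axis-decomposed
  distance, contact-guidance alignment ratio, ensemble MSD
  `⟨|x(t) − x(0)|²⟩`, persistence ratio (net displacement / path length),
  bootstrap confidence bands;
* **stats & I/O** (`polarpunc.stats_io`) — replicate-aware aggregation,
  paired/unpaired t-tests, TIFF/CSV/YAML I/O and an end-to-end pipeline
  runner.

The headline population statistics the event model is calibrated to: puncta
appear at 19.8% and are extinguished by 37.4% of the cell length from the
front, with 84% gone by mid-cell.

## Worked example

Simulate one calibrated cell, detect and track its puncta, and map the
track endpoints into the cell frame:

```python
from polarpunc import DetectionConfig, LinkConfig, detect_stack, \
    filter_tracks, link
from polarpunc.cell_frame import CellOutlineSeries, event_positions, \
    fraction_by
from polarpunc.synthetic_scene import puncta_recovery_config, simulate_scene

cfg = puncta_recovery_config(n_frames=300, snr=8.0)
stack, truth = simulate_scene(cfg, seed=1)

masks = [s.mask for s in truth.cell_states]
detections = detect_stack(stack, channel=0, config=DetectionConfig(),
                          masks=masks)
link_cfg = LinkConfig(max_gap=2)
tracks = filter_tracks(link(detections, link_cfg), link_cfg, stack.n_frames)

outline = CellOutlineSeries.from_cell_states(truth.cell_states)
events = event_positions(tracks, outline, cfg.frame_interval_s,
                         subframe_disappearance=True)
print(f"{len(detections)} detections -> {len(tracks)} interior tracks")
print(f"mean appearance   : {100 * events['appear_q'].mean():.1f}%"
      " of cell length from the front")
print(f"mean disappearance: {100 * events['disappear_q'].mean():.1f}%")
print(f"gone by mid-cell  : {100 * fraction_by(events['disappear_q'], 0.5):.0f}%")
```

Output:

```
2407 detections -> 147 interior tracks
mean appearance   : 20.2% of cell length from the front
mean disappearance: 37.6%
gone by mid-cell  : 82%
```

One cell's 147 puncta scatter around the population values; pooling cells
(below) converges on them. The same stages are available from the shell:

```bash
polarpunc simulate --seed 3 --out scene/
polarpunc detect   --in scene/scene.tif --channel 0 --out det.csv
polarpunc track    --detections det.csv --out tracks.csv
polarpunc cellframe --stack scene/scene.tif --tracks tracks.csv --out events.csv
polarpunc report   --config run.yaml --out report/
```

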