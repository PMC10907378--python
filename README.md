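# trasein

Tracking and spike estimation of individual neurons in two-channel
fluorescence movies of deforming animals.

The package implements an end-to-end pipeline for movies acquired with two
simultaneous channels: a calcium-insensitive nuclear **anchor** channel used
for detection and tracking, and a cytoplasmic calcium-indicator **activity**
channel from which per-neuron signals and spike times are extracted.

Pipeline stages:

1. **Detection** (`trasein.detection`) — nucleus segmentation per frame via
   an undecimated a-trous B3-spline wavelet transform with statistical
   thresholding, plus distance-gated precision/recall/f1 evaluation and a
   grid-search calibration of the two hyperparameters (scale, threshold).
   Any callable `frame -> FrameDetections` can be plugged in instead (e.g. a
   deep-learning detector).
2. **Tracklet linking** (`trasein.linking`) — conservative frame-to-frame
   linking with a constant-velocity Kalman filter and gated Jonker-Volgenant
   assignment, behind a pluggable tracker contract.
3. **Stitching** (`trasein.stitching`) — tracklets of the same neuron merged
   by propagating undetected positions forward/backward with smoothed
   thin-plate splines fitted on neighboring tracklets, and solving a global
   linear assignment with a non-linking cost.
4. **Calcium linking** (`trasein.calcium`) — sub-ROI association of each
   tracked nucleus with its (misaligned) cell body in the activity channel:
   prior-weighted local maxima, nearest-candidate selection, exponential
   moving average, disc-mean signal extraction.
5. **Signal processing** (`trasein.signals`) — normality-test filtering of
   plateau (nematocyte-like) cells, two-signal ICA motion-artifact removal,
   zero-phase high-pass detrending, rolling-average smoothing.
6. **Spike inference** (`trasein.spikes`) — constrained AR(2) deconvolution
   (sparsity-penalized nonnegative least squares solved with accelerated
   projected gradient), followed by temporal blurring, merging, and adaptive
   thresholding into a discrete spike raster.

A first-class synthetic generator (`trasein.simulate`) produces two-channel
movies of a deforming pseudo-animal with full ground truth (per-frame
positions in both channels, spike times, cell classes, deformation fields),
so every stage is testable without real data.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked example on
reference confusion counts, plus property-based criteria on synthetic data);
the rest are per-module unit and property tests.

## CLI

```bash
# generate a synthetic movie + ground truth
trasein simulate --config sim.yaml --out-dir data/

# run the full pipeline (detect -> link -> stitch -> calcium -> signals -> spikes)
trasein run --config pipeline.yaml

# score tracks against synthetic ground truth
trasein evaluate --tracks run/tracks.csv --truth data/ --d-track 3
```

`pipeline.yaml` mirrors `trasein.pipeline.PipelineConfig`; every parameter
defaults to the reference protocol values (distance threshold d=1 px, TPS
smoothness alpha=10, non-linking cost eta=5 px, 25x25 ROI, 5 maxima,
smoothing sigma 1 px, prior sigma 5 px, extraction radius 5 px, Butterworth
order 5 with a 100-frame critical period, rolling average 5, blur sigma 5
frames, merge window 5 frames, threshold k=2, minimum area 5 px). A run
directory receives the resolved config, per-stage CSV artifacts, a review
report for flagged non-neuronal cells, the spike raster (CSV + PNG), and a
log.

## Data formats

Movies are grayscale multi-page TIFF stacks (one file per channel).
Detections, tracks, traces, and rasters are plain CSV; configuration is
YAML. Coordinates are 0-based `(row, col)` pixels with the origin at the
top-left and pixel centers at integer coordinates.
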