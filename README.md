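# vesselperm

Quantification pipeline for rapid wound-induced vascular responses in
calibrated time-lapse fluorescence microscopy, paired with a seeded
synthetic-movie generator so that every stage is testable without any
microscope data.

The package covers four read-out families:

- **Leakage and dilation** (`vesselperm.leakage`): ROI mean-intensity traces,
  per-timepoint background subtraction, normalization to the mean of the
  pre-shift baseline window (first 10 frames, t = 0–270 s), trapezoidal
  time-integrated leakage over the 0–3600 s window (a constant trace yields
  exactly the 3600 a.u.·s no-leakage baseline), apparent leakage rates,
  percent-blockade effect sizes against the theoretical baseline,
  line-scan kymographs, Otsu-binarized per-frame vessel diameters, maximal
  normalized dilation, and kymograph area/onset metrics for high-molecular-
  weight tracer.
- **Nuclear-envelope reporter translocation** (`vesselperm.binding`): nucleus
  segmentation (Gaussian → rolling-ball → Otsu → marker-based watershed),
  rim:nucleoplasm intensity ratios, nearest-centroid nucleus tracking with
  discontinuity flagging, first-timepoint-normalized binding curves with peak
  statistics, 2-D line profiles, and wavefront speed estimation by regressing
  per-nucleus half-rise onset times on distance from the wound origin.
- **Leukocyte motion** (`vesselperm.tracking`): per-frame detection,
  mutual-nearest-neighbor linking, centroid-extrapolation "ghost" identity
  repair across short detection gaps, a hybrid polygon-overlap/centroid mode
  for amoeboid cells, net-displacement and angular rose statistics, and
  still-image spot counting (blur–subtract–median–prominence maxima).
- **I/O, registration, reporting** (`vesselperm.io`, `.registration`,
  `.report`): OME-TIFF read/write with calibration metadata (or sidecar
  files), maximum-intensity projection, translation-only drift registration
  by phase cross-correlation, the 300 px XY / 50 px Z drift exclusion rule,
  run manifests, group summaries and blockade tables, and the
  endothelium/tailfin area-ratio metric.

The generator (`vesselperm.synth`) renders two-channel movies (tracer +
reporter) from a declarative `SceneSpec` — vessel band with optional
dilation, perivascular/wound regions with saturating-exponential leak
kinetics, pulsing nuclei whose onsets propagate from the wound origin at a
configurable front speed, moving cell blobs, Poisson–Gaussian noise and
rigid drift — and returns the matching analytic `GroundTruth` for
parameter-recovery tests.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact analytic
values, end-to-end blockade recovery, wave-speed Monte Carlo, property
suites); the rest are per-module unit and property tests.

## CLI

A `vesselperm` command group (subcommands also installed standalone):

```bash
vesselperm quantify-leakage --stack movie.ome.tif --rois rois.json --out out/ \
    [--no-background-correction] [--window 0 3600]
vesselperm quantify-binding --stack wave.ome.tif --wound-origin 120,40 --out out/
vesselperm track-cells --stack cells.ome.tif --mode neutrophil|macrophage --out out/
vesselperm count-spots --image still.tif
vesselperm report --runs metrics.csv --control-group control --out summary.csv
```

ROI files are JSON lists of `{kind, coordinates, role, line_width}` with
rectangles as `(top, left, height, width)` and lines as `(y0, x0, y1, x1)`,
all in 0-based pixel coordinates. Plain TIFFs lacking calibration metadata
take a `<stack>.calib.json` sidecar or explicit `--pixel-size` /
`--frame-interval` options.
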