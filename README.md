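# sidegait

Markerless extraction and tracking of six body joints (head, shoulder,
elbow, hip, knee, ankle) from **side-view depth-frame sequences**
(320 × 240, per-pixel depth in mm, 0 = no reading), aimed at instrumenting
the Get Up and Go Test (GUGT) without wearable markers or machine-learned
skeletons.

The pipeline has three stages:

1. **Background construction** — the empty scene (wall at ~3.3 m, floor,
   armless chair) is averaged over ~100 frames into a reference background
   frame; a pixel is foreground when its depth differs from the background
   by at least 150 mm, and the subject is the largest 8-connected
   foreground component.
2. **Front-plane calibration** — from a single frame of the subject facing
   the sensor with arms held out, anthropometric rules (head/stature
   ratio, a piecewise hip coefficient, ankle–knee = 0.2 × body height)
   locate seven joints and store the five inter-joint pixel distances in a
   per-subject `BodyModel`.
3. **Side-view tracking** — each GUGT frame is processed independently:
   the body side nearest the sensor is isolated with an 80-mm depth-gap
   rule, head/ankle come from calibrated row shifts, shoulder/knee are
   re-projected to their calibrated distances, and elbow/hip are fitted
   with fixed-length rotating vectors (2° steps) maximizing raster overlap
   with the near-side region.

Estimated trajectories are compared against reference tracks (synthetic
ground truth or marker detections) with per-joint Euclidean difference
series, optional least-squares constant-offset compensation, and
occlusion-aware mean/sd summaries.

A fully synthetic depth-scene generator (`sidegait.synthdepth`) replaces
the depth sensor: a 2.5-D capsule figure with survey-table body
proportions is rendered through the pinhole camera model over the scene,
with exact projected joint ground truth, optional Gaussian depth noise and
dropout.

## CLI

```bash
# render a synthetic GUGT (depth stacks + ground-truth CSV)
sidegait simulate --out run/sim --preset gugt --frames 120 --noise-sigma 10 --seed 1
sidegait simulate --out run/front --preset front-pose --seed 1

# calibrate from the front-plane pose
sidegait calibrate --background run/front/background \
    --front-pose run/front/front_pose --out run/calibration.yaml

# track the six joints over the sequence
sidegait track --background run/sim/background --calibration run/calibration.yaml \
    --frames run/sim/sequence --out run/trajectory.csv

# compare against the reference track
sidegait validate --estimated run/trajectory.csv \
    --reference run/sim/ground_truth.csv --compensate

# or everything at once
sidegait demo --out run/demo --frames 120 --seed 1
```

Trajectory CSVs use the dialect `frame,joint,row,col,missing` (missing
frames are written as `0,0` with `missing=1`). Depth sequences are stored
as 16-bit PNG or PGM stacks (one file per frame, zero-padded numeric
suffixes) or as a single headered little-endian raw file.

## Coordinate and angle conventions

* 0-based `(row, col)` with row 0 at the top; depths in mm; 0 = invalid.
* Default intrinsics: focal 285.6 px, center (159.5, 119.75) — canonical
  Kinect-v1 values halved to 320 × 240; overridable via `--config`.
* Elbow sweep: θ from the horizontal image axis, 2°–178° in 2° steps,
  through straight-down at θ = 90°; ties go to the smaller θ.
* Hip sweep: γ from the upward vertical at the knee, opening toward the
  body rear (configurable `rear_sign`), 4° → 90° then wrapping through
  vertical to the forward side; ties go to the earliest angle swept.
* Segment rasterization: one-pixel steps along the major axis with the
  minor coordinate rounded half-up (8-connected, endpoint-inclusive).
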