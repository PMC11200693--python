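# skewgait

Quantify walking skew from markerless 2D pose keypoints. Given per-frame
BODY_25 keypoint sequences of a person walking a known straight path toward
or away from a static camera, `skewgait`:

1. samples frames on a fixed time grid (default every 0.3 s),
2. merges per-frame joint-node heatmaps into a single dynamic joint-nodes
   plot (DJNP) for visual inspection,
3. traces the four corners of the per-frame keypoint bounding box
   ("iso-block") across sampled frames and fits each corner trajectory with
   an ordinary least-squares line `y = α + βx`,
4. turns the sign-adjusted arctangents of the top and bottom corner slopes
   into two angle-ratio features — TAR (top-angle ratio) and BAR
   (bottom-angle ratio) — plus walking velocity,
5. classifies straight / skew-left / skew-right walking with an RBF-kernel
   SVM under stratified 10-fold cross-validation, and runs Kruskal–Wallis
   group tests and pairwise ROC analyses with Youden-J cutting points.

Straight walking gives TAR ≈ BAR ≈ 1; veering to the walker's left pushes
both ratios above 1, veering right pushes them below 1.

Since real gait videos are not bundled, the package ships a synthetic gait
generator (`skewgait.synthetic_gait`): an articulated 25-joint stick body
walking a 5 m path with controllable heading skew, pinhole-projected with
perspective scaling, Gaussian keypoint jitter, and confidence-0 dropout. All
tests and the acceptance report run against this generator.

## CLI

```bash
# simulate a labeled cohort (one pose CSV per walk + manifest.json)
skewgait simulate --subjects 35 --walks 6 --seed 7 --out walks/

# convert OpenPose BODY_25 JSON frames to the pose CSV dialect
skewgait convert --in frames_dir/ --fps 30 --out walk.csv

# render a walk's merged joint-node plot
skewgait djnp --in walks/S000_w0.csv --interval 0.3 --sigma 3 --out plot.png

# per-walk features (TAR, BAR, velocity)
skewgait features --in walks/ --interval 0.3 --out features.csv

# 10-fold RBF-SVM classification report
skewgait classify --features features.csv --folds 10 --seed 7 --report report.json

# ROC cutting point for one feature and group pair
skewgait roc --features features.csv --positive skew_left --feature tar --out roc.json

# everything end to end (simulate -> features -> classify -> ROC -> DJNP)
skewgait run --seed 7 --out rundir/
```

Exit codes: 0 success, 2 validation error, 1 stage failure. `skewgait run`
accepts a YAML config (`--config`) mirroring `skewgait.pipeline.PipelineConfig`;
explicit CLI flags override it.

## Library

```python
from skewgait import (
    CohortSpec, generate_cohort, sample_frames, extract_features,
    train_svm_cv, roc_analysis,
)

cohort = generate_cohort(CohortSpec(seed=7))          # 210 labeled walks
feats = [extract_features(seq, interval_s=0.3) for seq in cohort]
```

## Tests and acceptance report

```bash
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script regenerates its inputs from the synthetic module and
reports the frame-sampling count for a 3 s / 30 fps walk on the 0.3 s grid
(t1) and the default cohort size (t2).

## Conventions worth knowing

- Pose I/O stores pixels in image convention (y down); feature extraction
  flips to Cartesian y-up before regression. TAR/BAR are invariant to the
  flip, so the assumed image height is not critical.
- A keypoint with confidence 0 is missing; its coordinates are meaningless.
- DJNP kernels are unit-mass Gaussians, so grid mass equals the number of
  merged keypoints (edge-clipped kernels lose mass by design).
- `skew_deg` in the generator is a heading offset in the walker's body frame
  (positive = veers to their own left), which keeps the TAR/BAR direction
  consistent across both walking directions.
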