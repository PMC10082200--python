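# orgloc

Organ localization and contour extraction in abdominal CT volumes by
**orthogonal-projection slice classification**: three small CNNs classify
sagittal (X), coronal (Y) and axial (Z) projections of candidate points;
the agreement of the three per-axis decisions defines a 3D region-of-interest
cube around the organ (kidney or spleen), and intensity K-means clustering
inside the ROI recovers the organ contour.  A synthetic phantom generator
provides labeled CT-like volumes, so the whole pipeline — training, ROI
search, clustering and evaluation — runs end-to-end without clinical data.

## How it works

1. **Sampling** (`orgloc.sampling`): organ-class (OC) points on a 50 px grid
   inside the expert mask; background-class (BC) points on a 50 px grid
   outside a 60 px disk-dilation of the mask and outside 20 px-padded
   strips through its bounding box, so no BC point's row/column ray crosses
   the organ.  Each point yields three projection images
   (43x512 sagittal, 43x256 coronal cropped to the organ's image half,
   512x512 axial).
2. **Models** (`orgloc.models`): per axis, one CNN with the layer census
   input / 2x conv(32 filters, 3x3) / 3x batch-norm / 3x ReLU /
   2x max-pool(2x2) / fully-connected(2) / softmax, trained with SGD with
   momentum (lr 0.01, minibatch 64, shuffle each epoch; 40 epochs default,
   4-epoch fast preset).  Implemented in pure numpy (`orgloc._nn`) — no
   GPU or DL framework needed.
3. **ROI search** (`orgloc.roi_search`): scan each axis at a 10 px step;
   a negative decision excludes the whole line of points (the exclusion
   scan is an exact refactoring of per-point classification — tested
   against brute force).  Positive in-plane points are merged into
   segments, the largest connected component is kept, dilated by a 30x30
   square, and its bounding box plus the contiguous run of positive axial
   slices (padded by 1) defines the ROI cube.
4. **Clustering** (`orgloc.clustering`): per axial ROI slice, 7-cluster
   K-means on intensity (Lloyd iteration; deterministic
   DP-optimal-histogram initialization), selection of the cluster whose
   center matches the ROI's central intensity, clipping to the ROI, hole
   filling and largest-component extraction.
5. **Metrics** (`orgloc.metrics`): TP/FP/FN/TN, F1 (= Dice), TPR, PPV,
   VOE, RVD, and symmetric surface distances ASSD / MSSD (Hausdorff),
   with per-case and cohort-mean reporting.

## CLI

```bash
orgloc phantom  --n 10 --seed 7 --out phantoms/          # NIfTI volumes + masks
orgloc dataset  --organ kidney_right --n 4 --out data/   # PNG projections + manifest
orgloc train    --axis X --data data/ --epochs 4 --seed 7 --out models/roinet_x
orgloc locate   --organ kidney_right --models models/ --in vol.nii.gz --out roi.json
orgloc segment  --roi roi.json --in vol.nii.gz --out mask.nii.gz
orgloc evaluate --pred mask.nii.gz --ref expert.nii.gz
orgloc run      --demo --seed 7 --out run/               # full pipeline + report.csv
```

`orgloc run` executes phantom generation, dataset construction, training,
localization, segmentation and evaluation; every artifact embeds the
config hash and re-running with the same seed reproduces all outputs
byte-for-byte.  `--ablation` additionally clusters the whole image half
without the ROI step, quantifying how much the ROI contributes.

## Acceptance

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

There are no numeric acceptance targets: the source study's headline
numbers were measured on a restricted clinical dataset, so the script
writes an empty report.  The quantitative validation is
`tests/test_acceptance.py`, seven property-based criteria on seeded
phantoms: ROI containment of the organ, exclusion-scan exactness,
clustering and sampling oracle equivalence, metric identities, the
ROI-ablation direction (mean F1 with ROI > without, and >= 85%), and
bit-level determinism of the demo pipeline.

## Conventions

- Grids are indexed `(z, y, x)`, 0-based, with half-open ranges everywhere.
- Axial = fixed z, coronal = fixed y, sagittal = fixed x.
- `kidney_right` denotes the anatomical right kidney, which appears in the
  *left* image half (radiological convention); the organ tag determines
  which half the coronal crop and the in-plane scan use.
- Masks are stored as NIfTI uint8 {0, 1}; intensities normalized to [0, 1]
  (window configurable, default soft tissue -135..215 HU).
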