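# mcipredict

Prediction of MCI-to-AD conversion from structural brain MRI, built around
hippocampus-constrained 2.5D patches and deep/structural feature fusion.

The pipeline:

1. **IO** — NIfTI volumes and a binary hippocampus mask on a common template
   grid; subject and feature tables as CSV (`mcipredict.io`).
2. **Preprocessing** — histogram matching to a template and linear age
   correction: a per-voxel (or per-feature) OLS model `y = w*age + b` fitted on
   healthy (NC) subjects, every subject shifted to reference age C=75 via
   `y' = w*(C - age) + y` (`mcipredict.preprocess`).
3. **Patch sampling** — 151 random in-mask locations, pairwise Euclidean
   distance > 2 voxels, fixed across all subjects; 32×32×3 tri-planar patches
   (transverse/coronal/sagittal channels) centered at each location
   (`mcipredict.patches`).
4. **CNN features** — a small convnet (three 5×5 conv stages, 32/32/64 maps,
   3×3 stride-2 ceil-mode pooling, LRN; spatial trace 32→16→8→4) trained with
   momentum SGD (m=0.9, η=0.001, λ=0.0001, 30 epochs, batch 151) on AD vs NC
   patches only, implemented from scratch on numpy. The flattened 1024-d
   output of the last pooling layer is the per-patch deep feature vector;
   151 patches give 154 624 features per image (`mcipredict.cnn`).
5. **Feature selection** — standardization, PCA (29 dims per patch for CNN
   features, 150 for the 325-column structural table) and LARS-LASSO selection
   stopping after exactly L variables enter (35 CNN + 40 structural = 75 fused
   features) (`mcipredict.selection`).
6. **Classifier** — kernel extreme learning machine with RBF kernel, solved in
   closed form as `beta = (Omega + I/C)^-1 y` with C=1; SVM and random-forest
   baselines behind the same interface (`mcipredict.elm`).
7. **Evaluation** — accuracy/sensitivity/specificity/AUC, leave-one-out and
   stratified 10-fold CV with per-fold refits of every trainable selection
   stage, the end-to-end experiment driver with feature ablations, and a
   patch-vote protocol comparing AD/NC-trained vs MCI-trained CNNs
   (`mcipredict.evaluate`).

Real cohort data are access-controlled, so `mcipredict.synthetic` generates
phantom cohorts — smooth background plus two ellipsoidal "hippocampi" with
group-dependent intensity loss and shrinkage, a linear age trend, optional
per-subject severity jitter, and a matching 325-column structural feature
table — giving every stage a testable substrate.

## CLI

```bash
mcipredict synth --seed 1 --out data/                 # phantom cohort
mcipredict patches --mask data/mask.nii.gz --out locs.csv
mcipredict agecorrect --subjects data/subjects.csv --volumes data/volumes --out corrected/
mcipredict train-cnn --subjects data/subjects.csv --volumes corrected/ \
    --locations locs.csv --out cnn.npz
mcipredict extract-features --model cnn.npz --subjects data/subjects.csv \
    --volumes corrected/ --locations locs.csv --out deep.csv
mcipredict select --features deep.csv --subjects data/subjects.csv \
    --kept-dim 29 --n-select 35 --out selected.csv
mcipredict classify --features selected.csv --subjects data/subjects.csv --out scores.csv
mcipredict run --config experiment.yaml --out results/   # end-to-end driver
```

`run` takes a single YAML file with `synthetic`, `cnn` and `fusion` sections
plus top-level keys (`n_patches`, `cv`, `k`, `ablations`, `age_correction`,
`seed`); it writes `metrics.json`, per-subject and ROC CSVs, and the sampled
patch locations.

## Conventions

* Volumes are indexed 0-based with axis order (x, y, z); transverse = fixed z,
  coronal = fixed y, sagittal = fixed x. The center of a 32-long window sits
  at index 16 (window spans [c−16, c+15]).
* The positive class is the MCI converter throughout; patch-vote and ELM ties
  resolve to the positive class.
* The CNN and the age-correction model never see MCI labels; they are fit once
  per experiment outside the CV loop, while standardization, PCA (by default),
  LASSO and the classifier are refit inside every fold.
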