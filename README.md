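# emseg

Iterative multi-modal MR image processing: smooth bias-field (inhomogeneity)
correction, atlas-prior-driven EM tissue classification with region-specific
intensity-context constraints, and registration refinement — bundled with a
synthetic phantom generator and an evaluation harness so every stage is
testable without external data.

## What it does

Given a scan session (any combination of modalities, any number of repeats
per modality) and a prior atlas (one probability volume per tissue class plus
a tissue table), the pipeline:

1. rigidly aligns all intra-session scans to the first scan and averages
   repeats per modality;
2. registers the atlas to the subject (affine, or an external deformable
   plug-in with affine fallback) and resamples the priors;
3. iterates: recompute per-tissue quantile intensity bounds → constrain the
   spatial priors with the multi-modal intensity indicators → run
   full-covariance Gaussian-mixture EM → fit and remove a low-order
   polynomial bias field per modality (in log-intensity space) → update the
   atlas registration — until the log-likelihood stabilizes;
4. writes posteriors, hard segmentations (full class set and a collapsed
   CSF/GM/WM view), corrected images, bias fields, transforms, and a
   manifest.

The shipped default tissue table (`src/emseg/data/tissue_config_17.yaml`)
defines 17 classes — 12 biological plus 5 background "Not-tissue" nuisance
classes — each with a prior weight, a bias-correction eligibility flag, and
conservative per-modality quantile bounds.

The `phantom` module generates deterministic synthetic sessions (nested
ellipsoids rendered as piecewise-constant intensities, multiplicative smooth
bias of exact peak amplitude `rf`%, additive Gaussian noise of `pn`% of the
WM mean) together with ground-truth labels, true bias fields, and
deliberately degraded prior atlases (blur + translation offset), which drive
all tests and experiments.

Evaluation metrics: Dice index and the average (modified) Hausdorff boundary
distance in mm, plus a factor-grid runner (`metrics_eval.run_grid`) scoring
the pipeline over noise × bias × context × prior-alignment cells.

## CLI

```sh
# generate a synthetic session with ground truth + prior atlas
emseg phantom --spec spec.yaml --seed 4 --out phantom/

# run the full pipeline
emseg run --atlas phantom/ \
    --tissue-config src/emseg/data/phantom_tissue_config.yaml \
    --scan T1=phantom/scan_T1_0.nii --scan T2=phantom/scan_T2_0.nii \
    --seed 1 --out result/

# score a segmentation against ground truth
emseg evaluate --segmentation result/labels_three_tissue.nii \
    --truth phantom/truth_labels.nii

# run the noise x bias factor-grid experiment
emseg grid --shape 32 --seeds 3 --out grid.csv --plot grid.png
```

`emseg run --config run.yaml` accepts any `RunConfig` field (iteration
limits, tolerances, bias polynomial order, context priors on/off,
registration mode `none|affine|deformable`, …). Every run writes a
`manifest.json` (seed, config digest, versions) and per-iteration
log-likelihood and quantile-bound tables.

## Notes and conventions

- Volumes are NIfTI (float32 on disk, float64 in memory); grids are indexed
  (x, y, z) in native axis order; spacing/origin pass through untouched.
- The bias field is additive in log-intensity space (multiplicative in
  linear space), one independent field per modality, polynomial basis of
  order 4 by default, zero-mean over the fit mask.
- Quantile bounds are computed against the full-image histogram by default
  (`quantile_scope: image`) — the shipped tables are expressed on that
  scale — with an atlas-head-mask option.
- Intensity-context indicators use open intervals and a conjunction across
  modalities; voxels losing all prior support fall back to the unconstrained
  prior (counted and logged).
- The three-tissue view maps deep gray (Thalamus/Globus) to GM and excludes
  venous blood and background classes from evaluation.
- Deformable registration is a plug-in contract only (callable or command
  template producing a displacement-field NIfTI); without a plug-in the
  pipeline falls back to affine with a warning.
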