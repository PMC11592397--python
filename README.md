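# petrad

A robust PET radiomics survival-analysis pipeline, built as a tested, reusable
Python package. It covers the full workflow:

1. **Synthetic data** (`petrad.synthetic`) — spherical-lesion PET phantoms with
   controllable texture (Gaussian-random-field heterogeneity) and a survival
   cohort generator with planted Cox log-hazard coefficients, right censoring
   and a consistent 1-year endpoint, so every downstream stage is testable
   without any external data.
2. **Segmentation** (`petrad.segmentation`) — five contour variants per lesion:
   fixed-threshold contours at 35/40/45% of the lesion SUVmax (largest
   26-connected component through the seed region), a CT-perception surrogate
   (ground-truth support) and a PET-perception surrogate (seeded stochastic
   boundary perturbation of the 40% contour).
3. **Features** (`petrad.features`) — IBSI-style radiomics: 18 first-order, 14
   shape (marching-cubes mesh), 24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM and 14
   GLDM features, over the original image, Laplacian-of-Gaussian filtered
   images and the 8 subbands of a one-level 3D Haar DWT; fixed-bin-width
   discretization; optional trilinear resampling. The six-parameter-set grid
   (bin widths 5/25/75 × with/without resampling) is provided as
   `default_parameter_grid()`.
4. **Robustness** (`petrad.robustness`) — ICC(2,1) (two-way random effects,
   absolute agreement, single measurement) screening per perturbation family
   at a strict `ICC > 0.75` cut, plus intersection of the robust sets.
5. **Survival** (`petrad.survival`) — stratified 80/20 split, min–max +
   one-hot preprocessing, nested cross-validated elastic-net Cox feature
   selection (frequency-based top-7 across inner repetitions; winner outer
   fold carried to the held-out test set), risk scores, mean-split risk
   groups, Kaplan–Meier, logrank and Harrell's concordance.
6. **Classifier** (`petrad.classifier`) — balanced random forest (per-tree
   balanced bootstraps) with 5-fold grid search, AUC/accuracy/sensitivity/
   specificity reporting, and a utility that reconstructs integer confusion
   matrices from printed sensitivity/specificity pairs.
7. **Orchestration** (`petrad.pipeline`, `petrad.cli`) — a fully seeded
   end-to-end run producing byte-identical reports under identical seeds.

Volumes are read and written as NRRD (raw/gzip/ascii encodings, attached or
detached headers) via a small self-contained reader in `petrad.io`.

## CLI

```sh
petrad simulate --config cohort.yaml --out DIR --seed 1
petrad segment  --volume v.nrrd --seed-mask m.nrrd --out DIR [--fractions 0.35 0.40 0.45]
petrad extract  --volume v.nrrd --masks DIR --config extraction.yaml --out features.csv
petrad screen   --features long.csv --threshold 0.75 --out icc.csv
petrad survive  --features table.csv --out DIR --seed 1
petrad classify --features table.csv --selected selection.json --out DIR --seed 1
petrad run      --config pipeline.yaml --out DIR --seed 1   # end to end
```

`petrad run` without `--config` uses a small toy configuration. All
subcommands are pure functions of (inputs, config, seed).

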