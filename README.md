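# qusrim

Quantitative-ultrasound (QUS) characterization of breast-like lesions from
the statistics of radiofrequency (RF) echo signals, comparing features
computed **inside** a lesion contour with features from the **peritumoral
rim** of surrounding tissue.

The pipeline:

1. **synth** — synthetic RF scenes with controlled ground truth: speckle
   envelopes drawn from a Nakagami law per region (background, elliptical
   lesion interior, rim band), reference phantoms with a depth-dependent
   gain, and reproducible two-class lesion cohorts with two scan planes per
   lesion.
2. **preprocess** — analytic-signal envelope detection, resampling to an
   isotropic pixel grid, log compression to a 20–100 dB B-mode window, and
   reference-phantom depth-correction curves for parametric maps.
3. **roi** — rasterization of a contour polygon into an internal mask, a
   5 mm external rim via the Euclidean distance transform, and sliding
   windows (1 mm × 1 mm, 92 % overlap by default) assigned to ROIs by their
   centre pixel.
4. **features** — 12 per-window parameters: Nakagami shape (method of
   moments), amplitude-weighted entropy, and contrast / correlation /
   energy / homogeneity / variance of 20×20 gray-level co-occurrence
   matrices for vertical and horizontal displacements (0.3 mm). Window
   values are averaged per lesion, ROI, and parameter over both scan
   planes, giving a 24-column feature table.
5. **classify** — k-NN (k=4, standardized Euclidean distance, leave-one-out
   cross-validation) scores, ROC/AUC, Youden operating points, two-sided
   Wilcoxon rank-sum significance, exhaustive search over all non-empty
   feature subsets of a group (4095 classifiers for 12 features), and
   paired internal-vs-external AUC comparison.
6. **pipeline / cli** — a validated configuration object and a `qusrim`
   command orchestrating everything with fixed seeds and cached stages.

## Test

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks structural
counts (4095 subsets, 20×20 GLCM, 12 features per ROI), hand-computed
estimator oracles, Monte-Carlo parameter recovery, AUC pair-counting
equivalence, permuted-label null calibration, and direction-of-effect
recovery on seeded 59/57 synthetic cohorts (a class effect confined to the
rim must make the external classifiers win, and vice versa). The full run
takes on the order of 10 minutes, dominated by the cohort simulations.

## CLI

```sh
qusrim synth --seed 1 --out cohort/                  # write a synthetic cohort
qusrim extract --cohort cohort/ --out features.csv   # per-lesion feature table
qusrim classify --features features.csv --out reports/ --max-subset-size 2
qusrim run --config config.yaml --out run/           # end to end
qusrim report --summary run/summary.json             # best-classifier table
```

A config YAML holds the flat pipeline settings (rim width, window size,
overlap, dB range, gray levels, displacement, entropy bins, k, correction
mode, seed) plus an optional nested synthetic cohort spec; see
`qusrim.pipeline.PipelineConfig`. Note that an unrestricted exhaustive
search over the combined 24-feature group enumerates 2^24 − 1 subsets;
use `max_subset_size` to bound it.

## Data formats

RF frames are HDF5 (`rf`, `fs_hz`, `line_pitch_mm`, `sound_speed_mps`);
contours are JSON vertex lists in mm; labels and feature tables are CSV;
classifier reports are CSV plus a JSON summary.
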