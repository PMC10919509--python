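# nodulecad

A computer-aided detection/diagnosis pipeline for nodule-like blobs in 2D
grayscale slices, exercised end to end on synthetic phantoms — no external
image data required.

The pipeline mirrors a classic CAD architecture:

1. **fixtures** — phantom generator: bright compact "nodules" (smooth or
   spiculated margins), elongated vessel-like distractors, additive noise;
   plus Gaussian-mixture feature tables for classifier-only experiments.
2. **preprocessing** — denoising (joint spatial/range mean-shift filtering,
   Gaussian / Perona–Malik / Catte explicit diffusion), image-quality
   metrics (PSNR, Pratt figure of merit, SSIM), and adaptive Otsu
   segmentation with cavity filling and rolling-ball closing.
3. **candidate_detection** — 8-connected components with a descriptor block
   (mean/variance, circularity, flatness, elongation, rectangularity) and a
   rule cropper that drops candidates violating configurable bounds.
4. **features** — the hybrid 17-feature vector per candidate: gray
   statistics (mean, variance, histogram energy/entropy, calcification),
   GLCM texture (contrast, homogeneity at distances 1 and 2, four angles
   averaged), 2D shape, and gradient statistics; optional voxel-based 3D
   shape block (volume, surface, sphericity, compactness).
5. **lda** — Fisher discriminant reduction (generalized eigenproblem with
   diagonal shrinkage) applied before the SVM.
6. **classifiers** — RBF-SVM, the rule+SVM hybrid (rules decide first,
   survivors go to the SVM, every decision carries a rationale),
   PSO-optimized logistic regression (log-likelihood fitness, linearly
   decaying inertia weight), random forest with OOB error, and
   NB/KNN/decision-tree baselines behind one predict/scores contract.
7. **evaluation** — confusion metrics, ROC/AUC by threshold sweep,
   train/test split ladders, k-fold cross-validation, and a paired
   with/without-LDA ablation.
8. **pipeline / cli** — YAML-configured orchestration with per-stage seeds,
   stable artifact names, sha256 manifests, and byte-identical reruns.

## CLI

```bash
nodulecad phantom --n-nodules 3 --seed 7 --out ph/
nodulecad denoise --method catte --in ph/slice0.png --out den.png \
    --report metrics.json --reference ph/slice0.png
nodulecad detect --in den.png --out cands/
nodulecad featurize --in den.png --candidates cands/ --out feats.csv
nodulecad train --model svm --features train.csv --out model.json
nodulecad predict --model model.json --features test.csv --out preds.csv
nodulecad eval --preds preds.csv --truth-col label --out report.json
nodulecad run --config pipeline.yaml --out runs/exp1/
nodulecad benchmark --seeds 20 --out bench.json
```

A pipeline config lists one block per stage (all blocks are validated
before any compute):

```yaml
seed: 3
phantom: {n_slices: 6, n_nodules: 3, n_vessels: 5, noise_sigma: 0.05}
denoise: {method: catte, iterations: 8}
segment: {closing_radius: 2}
rules: {}
features: {}
lda: {enabled: true}
model: {kind: hybrid}
eval: {test_fraction: 0.4}
```

## Acceptance

The acceptance contract is property-based; each criterion is one test in
`tests/test_acceptance.py` (exact formula oracles, PSO/LDA/AUC oracle
agreement, the qualitative classifier-bank and denoiser orderings on the
standard phantom benchmarks, and end-to-end determinism). The report
script runs a self-check and emits the (empty) target report:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Notes

- Images are normalized to [0, 1]; masks are boolean arrays on the image
  grid, coordinates are 0-based (row, col).
- DICOM input/output needs the optional `pydicom` dependency
  (`pip install nodulecad[dicom]`); PNG/TIFF work out of the box.
- All randomness flows through seeded `numpy.random.Generator` instances;
  pipeline stages derive their seeds from the global seed.
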