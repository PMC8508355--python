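# ki67topo

Quantitative description of the spatial organisation of Ki-67-positive
(immunostained) cells on whole-slide histology exports, and prognosis
classification built on those descriptors.

The pipeline:

1. **slide ingestion** (`ki67topo.slide_io`) — outline-annotated RGB bitmap
   exports (green contours delimit analysable tissue, red contours mark
   exclusions) are turned into an inclusion mask; the frame is rotated so the
   tissue's major axis lies horizontal and cropped to content, making the
   downstream pipeline independent of the export framing.
2. **nucleus detection** (`ki67topo.nuclei`) — median + Gaussian smoothing,
   RGB thresholding of DAB-brown pixels (the blue-channel upper bound is the
   single per-image parameter, selected automatically by Otsu when not given),
   cleanup, hole filling, watershed splitting and size filtering; centroids
   are emitted in µm.
3. **feature extraction** (`ki67topo.features`) — 490 named descriptors per
   pattern, in fixed order:
   - 441 graph features: proximity graphs at 25/50/75 µm, 9 per-node metrics
     × 16 summary statistics + 3 whole-graph metrics per threshold
     (`ki67topo.graphfeat`);
   - 39 stochastic-geometry features: process intensity plus Ripley K and L
     at radii 5–50 µm step 2.5, translation edge correction
     (`ki67topo.pointprocess`);
   - 6 windowed Shannon-entropy features (sides 20–640 µm,
     `ki67topo.entropy`);
   - 4 fractality features: box-counting dimension (10–1100 µm dyadic box
     ladder) and Higuchi dimensions of the row/column count projections
     (`ki67topo.fractal`).
4. **feature selection** (`ki67topo.selection`) — constant filter, perfect-
   correlation filter, then neighbourhood-component feature weighting with
   cross-validated regularisation and a 0.01 weight cut-off.
5. **classification** (`ki67topo.models`) — k-NN (k = 3, inverse-square
   distance votes) and a cubic-polynomial-kernel SVM under repeated
   stratified 5-fold cross-validation, plus single-metric threshold
   baselines (labelling index, cell density).
6. **feature statistics** (`ki67topo.statstests`) — Pearson correlation with
   the labelling index and cell density, Mann–Whitney histology-independence
   tests, Benjamini–Hochberg FDR per batch, and the resulting set report.

`ki67topo.synth` generates everything needed to exercise the stack without
data: seeded point patterns with known spatial statistics (CSR, Thomas
clusters, hard-core, grids, lines, Sierpinski vertices), rendered
pseudo-IHC slides with ground truth, and labelled two-class cohorts.

## CLI

```sh
ki67topo simulate --kind csr --n 300 --seed 1 --render --out-dir work/sim
ki67topo detect --image work/sim/slide.png --out-csv work/cells.csv --report work/report.json
ki67topo features --centroids work/cells.csv --window 1000 1000 --out work/features.csv
ki67topo select --features cohort_features.csv --metadata cohort_metadata.csv --seed 1 --out-dir work/sel
ki67topo classify --features cohort_features.csv --metadata cohort_metadata.csv \
    --ranking work/sel/selection.json --model knn --out-dir work/cv
ki67topo analyze --features cohort_features.csv --metadata cohort_metadata.csv --out-dir work/stats
ki67topo run --config config.yaml --out-dir work/run   # staged pipeline + manifest
```

`run` consumes a YAML config (seed, cohort size, CV repetitions, models)
and writes staged CSV/JSON artefacts plus a `manifest.json` with the seed,
a config hash and artefact checksums; reruns with the same seed are
bit-identical.

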