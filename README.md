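# nucleoqh

Nuclear quantitative histomorphometry (QH) for H&E biopsy regions:
a pipeline that segments nuclei in stained tissue images, extracts 216
morphometric features describing nuclear position, shape, orientation and
clustering, identifies a small discriminative feature set by a repeated
half-split protocol, and builds a classifier for binary patient outcomes
such as progression under active surveillance of low-risk prostate cancer.

It is aimed at computational-pathology researchers who want a transparent,
fully reproducible alternative to black-box models: every feature has a
name, units and a geometric definition, and every stage can be exercised
on synthetic nucleus fields with known ground truth.

## The method

For a pathologist-annotated tumor region at known resolution
(microns per pixel):

1. **Stain normalization** — per-image stain vectors are estimated in
   optical density by SVD plane projection and mapped onto a reference
   hematoxylin/eosin basis, scaling each stain's 99th-percentile
   concentration to the template.
2. **Segmentation** — a bank of directional Gaussian second-derivative
   filters (3 scales × 6 orientations) over the hematoxylin channel yields
   nucleus seeds; marker-controlled watershed on the hematoxylin gradient
   produces one boundary polygon and centroid per nucleus.
3. **Feature extraction** (216 features, fixed manifest):
   - *graph* (51): Voronoi cell areas/perimeters/chords, Delaunay triangle
     sides/areas, MST edge lengths, k-NN distances and neighbor-count
     densities — each summarized by mean, SD, min/max ratio and the
     disorder statistic 1 − 1/(1 + SD/mean);
   - *shape* (100): 25 per-nucleus measures (area, perimeter, radial
     statistics, smoothness, fractal dimension, Hu moments 1–7, Fourier
     descriptors 1–10) × {mean, median, SD, min/max ratio} over nuclei;
   - *nuclear disorder* (39): orientation co-occurrence matrices over
     distance-decay local subgraphs, 13 second-order statistics
     (entropy, energy, contrast, … ) × {mean, SD, range};
   - *cluster graph* (26): nuclei merged into clusters by single linkage,
     cluster centroids as graph nodes with distance-decay edges; degree,
     edge-length, path, clustering-coefficient, component and spectral
     measures.
4. **Feature identification** — 30 stratified half-splits of the training
   cohort; per split, 6 features by Wilcoxon rank-sum and 6 by Welch
   t-test each train an LDA and a QDA (4 models/split, 120 records);
   records with validation AUC ≥ 0.65 are retained and the six most
   recurrent features win.
5. **Modeling** — LDA vs QDA vs random forest by 100 × stratified 3-fold
   cross-validation (best mean AUC); operating point by Youden's J;
   held-out evaluation with AUC, confusion matrix, sensitivity,
   specificity, PPV and NPV.

A synthetic-data module generates H&E-like fields of non-overlapping
elliptical nuclei with controllable packing regularity, shape
heterogeneity and orientation alignment, plus labeled two-class cohorts —
see `docs/methods.md` for the model and its calibration.

## Worked example

Simulated study: a 60-patient training cohort (30 progressor-like /
30 non-progressor-like synthetic patients) and a 130-patient held-out
cohort, run through selection → random forest → evaluation:

```python
import nucleoqh as nq

train = nq.extract_cohort(nq.generate_cohort(30, seed=11))
test = nq.extract_cohort(nq.generate_cohort(65, seed=1011))

result = nq.identify_features(train, seed=11)
print("records:", len(result.records), "retained:", len(result.retained))
print("selected:", *result.selected, sep="\n   ")

clf = nq.ProgressionClassifier("RF", features=tuple(result.selected), random_state=11)
clf.fit(train, train["label"])
threshold = nq.choose_operating_point(
    clf.decision_scores(train), train["label"] == "progressor"
)
report = nq.evaluate(clf, test, threshold)
print(f"held-out AUC = {report.auc:.2f} at operating point {threshold:.2f}")
print("percent:", report.percentages)
```

Output:

```
records: 120 retained: 120
selected:
   graph:nn_count_r30:mean
   graph:voronoi_perimeter:mean
   graph:voronoi_chord:mean
   graph:nn_count_r10:mean
   graph:delaunay_area:sd
   graph:nn_count_r40:mean
held-out AUC = 0.90 at operating point 0.53
percent: {'sensitivity': 86, 'specificity': 82, 'ppv': 82, 'npv': 85, 'accuracy': 84}
```

All 120 selector × classifier records clear the AUC ≥ 0.65 retention bar
because the planted class differences (packing variance, orientation
disorder, shape heterogeneity at standardized shift ≈ 1) are real signal;
the six winning features are spatial-arrangement measures that respond to
the planted packing effect, and the random forest separates the held-out
cohort with AUC 0.90 — 86% of progressors are called at the Youden
operating point while 82% of non-progressors are spared.

The same pipeline runs from the shell:

```bash
nucleoqh simulate --out sim/ --n-per-class 30 --seed 11
nucleoqh extract  --cohort-dir sim/ --out cohort.csv
nucleoqh select   --cohort cohort.csv --iters 30 --auc-min 0.65 --seed 11 --out selection.json
nucleoqh train    --cohort cohort.csv --selection selection.json --seed 11 --out model.json
nucleoqh evaluate --train-cohort cohort.csv --test-cohort test.csv --model model.json --out eval.json
```

## Layout

- `src/nucleoqh/synthetic.py` — synthetic fields and cohorts
- `src/nucleoqh/stain.py`, `segmentation.py` — normalization, detection, watershed
- `src/nucleoqh/shape.py`, `spatial.py`, `disorder.py` — feature families
- `src/nucleoqh/manifest.py`, `extract.py` — canonical manifest, full-vector extraction
- `src/nucleoqh/selection.py`, `discriminant.py`, `models.py` — identification and modeling
- `src/nucleoqh/io.py`, `cli.py` — file formats, configuration, CLI
- `docs/methods.md` — models, parameters, calibration and limitations
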