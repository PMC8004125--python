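# usfusion

Multimodal ultrasound fusion classification of hepatocellular carcinoma
(HCC) against the cirrhotic parenchyma (PAR) it grows on.

HCC is often nearly indistinguishable from the surrounding cirrhotic
tissue in conventional B-mode ultrasound, while contrast-enhanced
ultrasound (CEUS) highlights its arterial-phase hyper-enhancement.  This
package implements a complete two-modality classification pipeline over
co-registered B-mode/CEUS image pairs:

* **patch preparation** — lesions delineated as polygons (VIA-3 style
  JSON) are turned into labelled 51×51 patch pairs by a sliding-window
  rule: a 250×250 search region is centred on the polygon centroid and a
  non-overlapping candidate tile is kept as HCC only when its
  intersection with the polygon is exactly 51² = 2601 pixels, as PAR
  only when it is 0 (partial overlaps are discarded);
* **three fusion levels** around pluggable CNN branches —
  *feature level*: pixelwise fusion of the two images
  (arithmetic mean, multiplication, or the CEUS-weighted mean
  `w(i,j) = (2·ceus(i,j) + bmode(i,j)) / 3`) before one classifier;
  *classifier level*: fusion of the per-modality branch feature vectors
  (concatenation, elementwise means/multiplication with PCA dimension
  matching, or concatenation + kernel PCA) before a shared head;
  *decision level*: arithmetic or weighted averaging of the class
  probabilities of two independent classifiers;
* **a 41-feature texture baseline** — Haralick statistics of
  second- and third-order generalized co-occurrence matrices, edge
  features, Laws texture energies, Hurst index, wavelet entropies and
  the autocorrelation index — with correlation-based feature selection
  (best-first search) and gain-ratio ranking (0.15 cutoff), feeding
  conventional classifiers (polynomial SVM, MLP, AdaBoost, random
  forest);
* **evaluation** — stratified 60/15/25 (CNN) and 75/25 (baseline)
  splits, confusion-matrix metrics with HCC as the positive class, and
  ROC/AUC by threshold sweep.

Because clinical data of this kind are not freely available, the package
ships a seeded synthetic generator that emulates the statistical
structure the pipeline assumes (heterogeneous, hyper-enhanced HCC
texture vs homogeneous parenchyma), so every stage is testable end to
end.

## Worked example

```python
from usfusion import SyntheticParams, generate_paired_patches, run_experiment_grid
from usfusion.backbones import scratch_train_config

patches = generate_paired_patches(SyntheticParams(seed=0, n_per_class=60))
table = run_experiment_grid(
    patches,
    [{"level": "single",   "method": "bmode"},
     {"level": "single",   "method": "ceus"},
     {"level": "feature",  "method": "weighted_mean"},
     {"level": "decision", "method": "arithmetic_mean"}],
    seed=0, train_config=scratch_train_config(seed=0))
print(table[["level", "method", "accuracy", "sensitivity", "specificity", "auc"]]
      .round(3).to_string(index=False))
```

prints

```
   level          method  accuracy  sensitivity  specificity   auc
  single           bmode     0.867        0.933        0.800 0.969
  single            ceus     0.833        0.800        0.867 0.893
 feature   weighted_mean     0.767        0.733        0.800 0.893
decision arithmetic_mean     0.967        1.000        0.933 0.991
```

Each row is one experiment on the same 60/15/25 split of 120 synthetic
patch pairs: accuracy/sensitivity/specificity at the 0.5 threshold and
the ROC AUC on the held-out test set.  The single-modality tiny-CNN
branches land in the 0.8–0.9 range by construction of the generator
defaults; decision-level fusion of the two branches recovers the
complementary information (brightness enhancement in CEUS, texture in
B-mode) and outperforms either branch alone.

## Command line

The same stages are scriptable:

```sh
usfusion simulate --out study/ --seed 3            # frames + VIA polygons
usfusion extract-patches --frames study/frames \
    --annotations study/annotations.json --out patches/
usfusion features --in patches/ --channels both --out features.csv
usfusion select --features features.csv --out selection.json
usfusion evaluate --in patches/ --out results/ --epochs 10
```

Every stage writes a `manifest.json` with its configuration and sha256
digests of inputs/outputs, so a run can be verified to reproduce
bit-identically on the same platform.

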