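# mbfusion

Multi-block data fusion for discriminating the geographical origin of a
botanical material from four analytical platforms measured on the same
samples: an LC-MS feature table, a GC-MS feature table, a ¹H NMR
spectrum and a mid-infrared (MIR) spectrum per sample. The package
implements the complete workflow — per-platform spectral preprocessing,
three levels of data fusion, a seven-classifier comparison,
random-forest Gini screening of characteristic variables, and
unsupervised validation on an external sample set — together with a
synthetic multi-block study generator with planted ground truth, so
every stage is testable without proprietary instrument data.

It is written for chemometricians and metabolomics researchers who want
a reproducible, scriptable version of this kind of origin-discrimination
study: samples from two origins build the models, samples from further
origins never seen in training probe whether the screened variables
generalize.

## The method

Each platform yields a block **X**ᵏ (samples × features). Blocks are
made commensurable by per-feature Z-scoring, x → (x − μ)/σ, with μ, σ
estimated on the 70 model samples only (population denominator) and the
fitted transform re-applied to the 14 external samples. The model set
is split 70 : 30 (49 train / 21 test, stratified).

Three fusion levels are compared, each trained with PCA, PLS-DA,
RBF-kernel SVM, 3-NN, a (500, 200, 10) feed-forward network, a
Gini decision tree and a 100-tree random forest:

- **LLDF** (low): the standardized blocks are concatenated unchanged,
  X = [X¹ | X² | X³ | X⁴].
- **MLDF** (mid): each block is first reduced — PCA or PLS-DA scores
  keeping the fewest components with cumulative explained variance
  ≥ 95%, or the top-40 variables by decision-tree / random-forest Gini
  importance — and the per-block features are merged before the
  second-stage classifier (models named SELECTOR–CLASSIFIER, e.g.
  RF–RF).
- **HLDF** (high): per block, a random forest over all variables keeps
  the top 120 by Gini importance g⁽ᵏ⁾ⱼ; a forest refit on those 120
  keeps the top 40. Each surviving variable's importance is weighted by
  the block coefficient w = 1/K (0.25 for K = 4 blocks),
  g̃⁽ᵏ⁾ⱼ = w · g⁽ᵏ⁾ⱼ, the 4 × 40 = 160 variables are merged and sorted
  by g̃, and the overall top 40 train the final forest.

Models are ranked by test-set AUC (then accuracy); the report carries
the full surface — AUC, out-of-bag accuracy (forests), train/test
accuracy, precision, recall, f1. The top k = 38 variables by fused
importance are exported from the best traceable ranking and validated
without labels: the external samples, restricted to those variables,
are projected onto their own first two principal components, and a
separation index (mean between-group / mean within-group pairwise
distance in the 2-D scores) quantifies how well origins separate
relative to a PCA on the full concatenated feature space.

NMR spectra are referenced to the TSP singlet at δ 0.00 ppm and
integrated into 0.002 ppm buckets over 0.4–12.0 ppm with the residual
water window 4.8–5.0 ppm excluded (5700 buckets). MIR spectra are
Savitzky–Golay smoothed, scaled to unit Euclidean norm, and stripped of
the uninformative 4000–3500, 2400–2200 and 500–400 cm⁻¹ windows.

## Worked example

```python
import mbfusion as mb

spec = mb.default_study_spec(seed=1)          # 70 model + 14 external samples
result = mb.full_pipeline(spec, mb.FusionConfig(seed=1), k=38)

print(result.comparison.head(5).to_string())
print(f"best model: {result.best_model}")
print(f"HLDF merged pool: {len(result.hldf.merged)} variables, "
      f"final model on {len(result.hldf.selected)}")
print(result.variable_set.to_frame().head(5).to_string(index=False))
print(f"planted-feature recall in top 38: "
      f"{mb.planted_recall(result.variable_set, result.truth):.3f}")
print(f"external separation index: screened {result.projection.separation_index:.2f} "
      f"vs full baseline {result.baseline_projection.separation_index:.2f}")
```

prints (about 10 s on one CPU):

```
             model  auc  oob  accuracy_train  accuracy_test  precision   f1  recall
1  Single-MIR (RF)  1.0  1.0             1.0            1.0        1.0  1.0     1.0
2       LLDF PLSDA  1.0  NaN             1.0            1.0        1.0  1.0     1.0
3         LLDF SVM  1.0  NaN             1.0            1.0        1.0  1.0     1.0
4         LLDF KNN  1.0  NaN             1.0            1.0        1.0  1.0     1.0
5          LLDF DT  1.0  NaN             1.0            1.0        1.0  1.0     1.0

best model: Single-MIR (RF)
HLDF merged pool: 160 variables, final model on 40
 rank  importance block     feature
    1    0.025980  LCMS  lcms_f0235
    2    0.017624  LCMS  lcms_f0183
    3    0.016377   NMR ppm_11.5570
    4    0.015634  GCMS  gcms_f0072
    5    0.015590  LCMS  lcms_f0168
planted-feature recall in top 38: 0.781
external separation index: screened 6.45 vs full baseline 1.44
```

The default synthetic study carries strong planted signal, so many
model-set strategies tie at AUC 1.0 — the interesting read-out is the
external set: a PCA on all ~6 800 concatenated features barely
separates the four held-out origins (index 1.44), while the same PCA on
the 38 screened variables separates them cleanly (6.45), and 25 of the
32 planted variables sit inside the top 38.

The same workflow is available from the shell:

```bash
mbfusion simulate --out data --seed 1
mbfusion preprocess --in data --out features
mbfusion run --in data --out results --seed 1 --k 38
```

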