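# deeplse

Joint autoencoder–classifier latent-space encoding for antioxidant
protein prediction from sequence-derived CKSAAP features.

## The problem

Antioxidant proteins (AoPs) neutralise free radicals and are of direct
interest for understanding and preventing oxidative-stress diseases.
Identifying them experimentally is slow and costly, so sequence-based
classifiers are used to prioritise candidates.  The benchmark datasets
for this task are heavily imbalanced (roughly one antioxidant per six
non-antioxidants), and the natural sequence descriptor — the
**composition of k-spaced amino acid pairs (CKSAAP)**, which counts every
ordered residue pair `(s[i], s[i+j+1])` at every gap `j = 0..k` — has
`400·(k+1)` dimensions, far more than there are positive examples.

Instead of a separate feature-selection step followed by a classifier,
this package trains a single network in which an autoencoder and a
classifier share a low-dimensional latent space:

```
x ∈ [0,1]^(400·(k+1))  --encoder-->  z ∈ [0,1]^LV  --decoder-->  x̂
                                     z  --classifier-->  softmax(p₀, p₁)
```

with the convex combined loss

```
L = λ·L_decoder + (1−λ)·L_classification,      λ = 0.99 by default,
```

where `L_decoder` is the mean squared reconstruction error and
`L_classification` the 2-class cross-entropy.  Training attention is
dominated by reconstruction, but the small classification term is enough
to pull the two classes into separate regions of the latent space.
`λ = 1` recovers a conventional autoencoder; `λ = 0` a pure classifier.

The package provides the full workflow: FASTA I/O and validation, the
CKSAAP encoder, the jointly trained model (a compact NumPy
neural-network core: dense / batch-norm / dropout layers, RMSprop,
early stopping), the imbalanced-classification metric suite (Sn, Sp,
precision, ACC, MCC, BACC, Youden's index, F1, Cohen's κ, and
reconstruction error in dB), latent-space diagnostics (PCA/t-SNE
embeddings and the generalized contrast-to-noise ratio, GCNR), a
synthetic benchmark generator with planted k-spaced pair enrichment,
and orchestration of repeated trials, (k, LV) ablation grids and
frozen-autoencoder baselines — plus a `deeplse` command-line interface.

## Worked example

Train on a synthetic benchmark shaped like the curated antioxidant
datasets (253 positives / 1552 negatives, split 200/1240 train and
53/312 test, with residue pairs planted in the positive class):

```python
from deeplse import (SyntheticConfig, generate_dataset, make_benchmark_splits,
                     CksaapConfig, encode_dataset, ModelConfig, DeepLSE, pca1d_gcnr)

ds = generate_dataset(SyntheticConfig(n_pos=253, n_neg=1552, seed=0))
train, test = make_benchmark_splits(ds, 200, 1240, seed=0)
cc = CksaapConfig(k=2)
X_tr, y_tr, _ = encode_dataset(train, cc)
X_te, y_te, _ = encode_dataset(test, cc)

model = DeepLSE(X_tr, y_tr, ModelConfig(N=5, k=2, LV=4, seed=0,
                                        max_epochs=150, patience=25))
res = model.fit()
print(res.summary())

report = res.evaluate(X_te, y_te)
print(f"test BACC {report.balanced_accuracy:.3f}  MCC {report.mcc:.3f}  "
      f"YI {report.youdens_index:.3f}")

Z = res.encode_latent(X_te)
print(f"latent 1D-PCA-GCNR {pca1d_gcnr(Z, y_te).gcnr:.3f}  "
      f"feature 1D-PCA-GCNR {pca1d_gcnr(X_te, y_te).gcnr:.3f}")
```

Output:

```
Joint latent-space encoding model
================================================
input dim        1200  (CKSAAP k=2)
encoder widths   1200 -> 50 -> 25 -> 10 -> 4
decoder widths   4 -> 10 -> 25 -> 50 -> 1200
classifier       4 -> 10 -> 10 -> 2
parameters       125016
lambda           0.99
epochs run       40 (best epoch 14)
best val loss    0.001062
test BACC 0.956  MCC 0.866  YI 0.911
latent 1D-PCA-GCNR 0.984  feature 1D-PCA-GCNR 0.939
```

The held-out balanced accuracy of 0.956 shows the planted pair
enrichment is recovered despite the 1:6 class imbalance, and the latent
space is more linearly separable (GCNR 0.984 along its first principal
component) than the 1200-dimensional raw feature space (0.939) — the
classification term has reorganised the bottleneck by class.

The same workflow is available from the shell:

```sh
deeplse simulate --n-pos 253 --n-neg 1552 --seed 0 --outdir data/
deeplse encode --positive data/positive.fasta --negative data/negative.fasta -k 2 --out data/features.csv
deeplse ablate --positive data/positive.fasta --negative data/negative.fasta \
    --k-values 1,2,3 --lv-values 2,4,6 --n-trials 5 --outdir runs/ablation/
deeplse baselines --positive data/positive.fasta --negative data/negative.fasta \
    -k 2 --lv 4 --out runs/baselines.json
```

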