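# lmlssrc

Large Margin and Local Structure preserving Sparse Representation
Classification (LMLS-SRC): discriminative dictionary learning for labelled
numeric feature tables, with the clinical motivation of classifying
volumetric / area / thickness features extracted from brain MRI (e.g. for
staging Alzheimer's disease), but applicable to any samples-by-features
table with class labels.

## The model

Given training features `X ∈ R^{d×N}` (one sample per column) with labels
in `K` classes (one-hot matrix `Y ∈ {0,1}^{K×N}`), the method jointly
learns a dictionary `D ∈ R^{d×m}`, representation codes `A ∈ R^{m×N}` and
a linear classifier `W ∈ R^{K×m}` by minimising

```
F(D, A, W) = ‖X − DA‖²_F            reconstruction
           + λ₁‖A‖₂,₁               row sparsity (atoms used by no sample die)
           + λ₂ tr(A S Aᵀ)          class margin on codes
           + λ₃ tr(A L Aᵀ)          locality preservation on codes
           + λ₄‖WA − Y‖²_F + λ₅‖W‖²_F      joint linear classifier
      s.t. ‖dᵢ‖² ≤ 1 for every atom dᵢ
```

where `S` combines the intra-class (`q_ij = 1/N_k`) and inter-class
(`q_ij = 1/(N−N_k)`) similarity graphs so that `tr(A S Aᵀ)` is the average
within-class minus between-class squared code distance, and `L` is the
positive-semidefinite graph Laplacian of a k-nearest-neighbour heat-kernel
affinity on the raw features, so that `tr(A L Aᵀ)` ties the codes of
feature-space neighbours together.

Training alternates exact block updates (dictionary → codes → classifier):
the `ℓ2,1` term is handled by iteratively reweighted least squares, the
code update solves a Sylvester system coupling the samples through `S` and
`L`, the dictionary update is block-coordinate descent with projection
onto the unit ball, and the classifier update is ridge regression.  Every
step is an exact minimiser of its subproblem, so the objective decreases
monotonically; the loop stops when the relative objective change falls
below `δ` (default `1e-4`).

New samples are ridge-coded against the learned dictionary,
`a = (DᵀD + γI)⁻¹Dᵀx`, and labelled by `argmax W a`.

## Worked example

```python
import numpy as np
import lmlssrc as lm

# 4 classes x 100 samples of 32-dim features generated from a ground-truth
# dictionary with class-block sparse codes plus Gaussian noise (sd 0.05)
ds = lm.generate(lm.SyntheticSpec(seed=7))
train, test = lm.split_train_test(ds, 0.25, seed=7)

model = lm.LargeMarginLocalSRC(train.X.T, train.labels)
res = model.fit()
print(res.summary())

pred = res.predict(test.X.T)
print(lm.evaluate_predictions(test.labels, pred.labels))
```

prints

```
Large Margin / Local Structure SRC results
==============================================
feature dim          32
dictionary atoms     300
classes              4
lambda1..5           1, 0.1, 0.1, 1, 0.1
encode gamma         1
locality sigma       1.09918
iterations           24
converged            True
final objective      200.876
max ||d_i||^2        1.00000000
accuracy=100.00  sensitivity=100.00  specificity=100.00  precision=100.00  f1=100.00  g_mean=100.00
```

The model converged in 24 alternating iterations, every dictionary atom
respects the unit-ball constraint, and all 100 held-out samples are
classified correctly (the six reported metrics are percentages; for
multiclass problems sensitivity/specificity/precision/F1 are one-vs-rest,
macro-averaged, and the G-mean is `sqrt(sens × spec)`).

A command-line interface covers the same pipeline end to end:

```sh
lmlssrc generate --seed 7 --out-prefix data
lmlssrc train    --features data_features.csv --labels data_labels.csv --out-model model.npz
lmlssrc predict  --model model.npz --features data_features.csv --out pred.csv
lmlssrc evaluate --predictions pred.csv --labels data_labels.csv --out-json report.json
lmlssrc cv       --features data_features.csv --labels data_labels.csv --out-json cv.json
lmlssrc gridsearch --features data_features.csv --labels data_labels.csv \
                   --axes '{"lambda2": [0.001, 0.1, 10]}' --out-json grid.json
```

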