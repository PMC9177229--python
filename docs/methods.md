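# Methods

## Model

LMLS-SRC represents each labelled sample `x_i ∈ R^d` over a learned
dictionary `D` of `m` atoms, `x_i ≈ D a_i`, and classifies through a
linear readout `W a_i`.  The training objective couples five ideas:

1. **Reconstruction** `‖X − DA‖²_F` with the unit-ball constraint
   `‖d_i‖² ≤ 1` (the usual scale fix: without it the codes could shrink to
   evade the sparsity penalty while atoms grow without bound).
2. **Row sparsity** `λ₁‖A‖₂,₁` (sum of row norms of the code matrix):
   atoms that no sample needs have their whole coefficient row driven to
   zero, pruning the dictionary.  The penalty is the plain (un-squared)
   `ℓ2,1` norm.  It is handled by iteratively reweighted least squares
   with `Ω = diag(1 / (2‖A_i‖₂))`: with `Ω` frozen, `tr(AᵀΩA)` is a
   quadratic majoriser of `‖A‖₂,₁` up to a constant, so the exact solve of
   the surrogate cannot increase the true objective.
3. **Class margin** `λ₂ tr(A S_sym Aᵀ)`, where `S` is assembled from the
   intra-class graph (`1/N_k` between same-class pairs) and the
   inter-class graph (`1/(N−N_k)` across classes):
   `S = (I − 2Q^w − diag(colsum Q^b) + 2Q^b)/N`.  The trace equals the
   mean within-class minus between-class squared code distance, pulling
   same-class codes together and pushing different-class codes apart.
4. **Locality preservation** `λ₃ tr(A L Aᵀ)` with `L = diag(P·1) − P` the
   graph Laplacian of a k-nearest-neighbour heat-kernel affinity
   `p_ij = exp(−‖x_i − x_j‖²/(2σ²))` on the raw features: samples close in
   feature space must have close codes, independent of labels.
5. **Joint classifier** `λ₄‖WA − Y‖²_F + λ₅‖W‖²_F`: the linear readout is
   learned together with the codes, so the codes are shaped to be linearly
   separable, not only reconstructive.

### Conventions that the assembled matrices must satisfy

Several sign/orientation choices in this construction are easy to get
wrong, so they are pinned down by brute-force oracle tests:

- **Laplacian sign.** `L = diag(P·1) − P` (degree minus affinity) is the
  positive-semidefinite form for which `Σ_ij p_ij‖a_i−a_j‖² = 2·tr(A L Aᵀ)`
  holds with nonnegative value; the factor of two is absorbed into `λ₃`.
- **Quadratic-form orientation.** Samples index the *columns* of `A`, so
  the `N×N` graph matrices act from the right inside `tr(A · Aᵀ)`.
- **Symmetrisation.** `Q^b` (hence `S`) is asymmetric for unbalanced
  classes.  All quadratic forms and gradients use `S_sym = (S + Sᵀ)/2`,
  which leaves the scalar penalty unchanged but makes the gradient exact.
  The diagonal correction uses column sums of `Q^b`; with symmetrisation
  the penalty is identical under the row-sum variant.
- **Self-loops** are excluded from `P` (they contribute nothing to the
  distance sum); kNN ties break by ascending sample index; the kNN
  relation is OR-symmetrised.

## Optimisation

Alternating minimisation, in the order dictionary → codes → classifier,
each an exact minimiser of its subproblem:

- **Codes.**  Setting the gradient of the `Ω`-frozen objective to zero
  gives the Sylvester equation `M A + A G = R` with
  `M = DᵀD + λ₁Ω + λ₄WᵀW` (m×m), `G = λ₂S_sym + λ₃L` (N×N),
  `R = DᵀX + λ₄WᵀY`.  It is solved through symmetric eigendecompositions
  of `M` and `G`; `G` is fixed across the fit and decomposed once.  When
  `λ₂ = λ₃ = 0` this collapses to the familiar regularised normal
  equations.  If some `μ_i(M) + g_j(G) ≤ 0` the subproblem is unbounded
  below (the margin's between-class repulsion overwhelming the
  regularisation); the solver raises a `NumericalError` advising a larger
  `λ₁`, and the grid search records such corners as missing rather than
  failing.
- **Dictionary.**  `min ‖X − DA‖²_F  s.t. ‖d_i‖² ≤ 1` by block-coordinate
  descent over atoms with Euclidean projection onto the unit ball.  Each
  atom step is the exact constrained minimiser given the others, so the
  sweep is monotone; the fixed point satisfies the Lagrange-dual (KKT)
  form `D = XAᵀ(AAᵀ + Θ)⁻¹` with nonnegative multipliers on active atoms
  (verified in tests).  Inside the outer loop 3 sweeps are used — exact
  subproblem convergence is unnecessary for monotone descent of the outer
  objective; a tolerance-controlled variant (`tol`) runs the sweeps to a
  fixed point when the subproblem optimum itself is wanted.  Atoms with an
  all-zero coefficient row are left unchanged.
- **Classifier.**  Ridge regression,
  `W = λ₄YAᵀ(λ₄AAᵀ + λ₅I)⁻¹`.

`Ω` is refreshed from the current `A` immediately before each code
update.  Because every step minimises (a majoriser of) the objective, the
`F` sequence is non-increasing; the loop stops when
`|F(t) − F(t−1)|/F(t−1) < δ`.

**Initialisation.**  Atoms are class-stratified samples of training
columns scaled to the unit sphere; the selection is keyed to a
lexicographic sort of the columns within each class, so permuting the
training samples does not change the fitted model (a property test
asserts this).  `A` starts as the ridge code of `X` on `D`, `W` as an
identity padded/truncated to `K×m`.  LC-KSVD-style initialisation (often
used for models of this family) is deliberately not reproduced; the
stratified-sampling initialiser is reproducible, order-independent and
parameter-free, and an `init=(D0, A0, W0)` hook accepts any alternative.

**Prediction.**  New samples are ridge-coded,
`a = (DᵀD + γI)⁻¹Dᵀx` with `γ = encode_gamma` (default `λ₁`), and
labelled by `argmax W a` (ties to the lowest class index).  The argmax
rule is chosen because `W` is part of the model; the classical class-wise
reconstruction-error rule lives on in the plain-SRC baseline
(`src_baseline_fit_predict`), which codes over the raw training columns
and scores `‖x − D_k a_k‖₂` per class block.

## Defaults and their rationale

| parameter | default | meaning |
|---|---|---|
| λ₁ | 1.0 | `ℓ2,1` weight; also conditions the code solve |
| λ₂, λ₃ | 0.1 | margin / locality weights |
| λ₄ | 1.0 | classifier coupling |
| λ₅ | 0.1 | classifier ridge |
| δ | 1e-4 | relative-objective stopping rule |
| maxiter | 50 | outer iterations |
| eps_row | 1e-8 | IRLS floor for zero rows |
| m | N | dictionary size (one atom per training sample) |
| k_neighbors | 5 | locality graph (clamped to N−1) |
| σ | median | heat-kernel bandwidth: median distance over graph edges |
| encode_gamma | λ₁ | test-time coding ridge |

The λ defaults were fixed once by a coarse grid search (decade steps
within the conventional 1e-3…1e3 search range) on the default synthetic
generator specification, selecting for reliable convergence within the
iteration budget and held-out accuracy; users are expected to re-tune per
dataset via `grid_search`, which is the model family's standard practice.
The median-heuristic `σ` makes the affinity scale-free; `k = 5` is the
common small-neighbourhood default.  `encode_gamma = λ₁` keeps train- and
test-time coding penalties on one scale.

Practical coupling worth knowing: small `λ₁` together with large `λ₂`
can make the code subproblem indefinite (see above), and very large `λ₁`
(≈100 at the default data scale) row-kills the entire dictionary — both
regimes are reported, not silently clipped.

## Synthetic data

Two generators stand in for real feature tables (the motivating
application extracts volumetric/area/thickness features from brain MRI;
no such images ship with the package):

- **dictionary mode** (default: K=4 classes × 100 samples, d=32, 5 atoms
  per class, 3-sparse codes, noise sd 0.05): each class owns a block of
  unit-norm Gaussian atoms; a sample's code activates the
  `code_sparsity` largest entries of a latent AR(1) chain
  (`manifold_corr = 0.6` between consecutive same-class samples), with
  positive activations `|N(0,1)| + 0.5`.  Positive activations keep each
  class in a one-sided cone — matching the "shared latent factors"
  structure of real morphometric features, which are nonnegative and
  far from the origin — and make the class structure visible to a linear
  readout; the AR(1) chain supplies the smooth within-class manifold that
  the locality term assumes.  The defaults are solvable but not trivial:
  nearest-mean classification is clearly beaten by subspace-aware methods.
- **blob mode**: isotropic Gaussian classes with pairwise mean distance
  `class_sep·√2` along random orthogonal directions — a linearly separable
  sanity-check regime with no subspace structure.

What passing on these generators does **not** show: robustness to heavy
class imbalance, feature-scale heterogeneity, non-Gaussian noise, or the
covariate structure of real MRI-derived features.  The generators are
exactly class-balanced and homoscedastic by construction.

## Evaluation machinery

Six indicators, reported as percentages: accuracy, sensitivity,
specificity, precision, F1, G-mean.  Multiclass sensitivity etc. are
one-vs-rest per class and macro-averaged (the only convention under which
"specificity" stays meaningful for K > 2); G-mean is
`sqrt(macro_sens × macro_spec)`, reducing to the standard binary G-mean.
0/0 conventions: a class absent from both truth and predictions is
excluded from the macro averages; an undefined precision counts as 0 with
a warning.  Cross-validation is stratified and seeded
(`StratifiedKFold(shuffle=True)`), reporting per-fold train and test
metrics with mean and sample standard deviation.  The grid search is
exhaustive over the requested λ axes with all other parameters fixed,
selecting maximal mean CV test accuracy (earlier points win ties).

## Problem sizes in the shipped checks

The test suite and the acceptance script run entirely on generated data:
graph oracles at N ≤ 20, block-update oracles on 6×8×10 instances
(20 seeds), convergence sweeps on 20 datasets of 160 samples,
classification checks on the default 400-sample specification, and a
learning curve over 50–400 samples per class with 5-fold CV.  These sizes
were chosen so the complete battery runs in a few minutes on a single
core while exercising every code path at non-toy scale; the solver itself
is dense-matrix bound at `O(m³ + m²N)` per iteration and is routinely
usable to a few thousand samples.

## Known limitations

- Dense `N×N` graph matrices and an `m×m` eigendecomposition per
  iteration bound practical problem sizes to a few thousand samples.
- The margin term makes the code subproblem indefinite when `λ₂` is large
  relative to `λ₁` (by design it is a difference of distances); the solver
  detects and reports this rather than regularising silently.
- Test-time coding is a ridge problem, not the full training coding (which
  would need labels); with extreme `ℓ2,1` weights the train/test coding
  mismatch grows, which is one reason very large `λ₁` degrades accuracy.
- `fit()` requires at least two classes; the margin construction is
  degenerate for one class.
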