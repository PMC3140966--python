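# Methods

## Model and inference

The data matrix `X` (N images × P grid features, each row mean-centered)
is modeled as `X = Λ F + E` with standard-normal entries in the factor
matrix `F`, a Student-t sparseness prior on each loading
(`λ_nk | α_nk ~ N(0, 1/α_nk)`, `α_nk ~ Gamma(a, rate b)`), and
independent Gaussian noise with per-feature precisions
`ψ_p ~ Gamma(c, rate d)` (a scalar-ψ option pools the residual). All
Gamma distributions are parameterized by shape and **rate**
(scale = 1/rate), which makes the conjugate updates additive.

Gibbs sampling cycles through the four exact conditionals in the fixed
order F, Λ, α, ψ:

* factor columns: `f_p ~ N(μ_p, Σ_p)`, `Σ_p = (I_K + ψ_p ΛᵀΛ)⁻¹`,
  `μ_p = ψ_p Σ_p Λᵀ x_p`. Only the scalar `ψ_p` varies with p, so one
  symmetric eigendecomposition of `ΛᵀΛ` diagonalizes every `Σ_p` and all
  P columns are drawn in a single vectorized pass.
* loading rows: `λ_n ~ N(μ_n, Σ_n)`,
  `Σ_n = (diag(α_n) + F Ψ Fᵀ)⁻¹`, `μ_n = Σ_n F Ψ x_n`; the shared K×K
  term is formed once and the N rows are drawn by batched Cholesky
  factorizations of the precision matrices (jitter 1e-10 is added only
  on factorization failure, and logged).
* `α_nk ~ Gamma(a + 1/2, rate b + λ_nk²/2)` entrywise.
* `ψ_p ~ Gamma(c + N/2, rate d + RSS_p/2)` with `RSS_p` the residual sum
  of squares of feature p.

The posterior summary is the plain arithmetic mean of Λ and F over the
retained (post-burn-in) sweeps — no thinning; the per-sweep
reconstruction MSE trace is exposed for convergence inspection. The run
is bit-reproducible from its seed.

### Data scaling and hyperparameter defaults

The Gamma hyperparameters fix an *absolute* scale: the marginal
Student-t prior on a loading behaves like 1/|λ| only for
|λ| ≫ √(2b), so loadings below that floor are invisible to the spike at
zero. Because the N(0,1) prior on F pins the factor scale, the working
loading scale is set by the data scale, and a mismatch silently removes
the sparsity pressure that identifies the factor rotation — the chain
then settles in a rotated mode with visibly mixed templates. Two
defaults address this jointly:

* `run_gibbs` standardizes X to unit global variance before sampling
  and maps the loadings back afterwards (factors are unaffected), so
  loadings work at O(1) scale regardless of the input units;
* `b = 1e-6` places the spike floor (√(2b) ≈ 1.4e-3) two to three orders
  of magnitude below that scale, while `a = 1e-3` keeps the marginal
  heavy-tailed. Noise precisions use broad `c = d = 1e-3`.

With a flat choice a = b = c = d = 1e-3 on unstandardized
data the sampler reaches the same reconstruction error but leaves the
factors rotated (mean |correlation| with the generating templates
0.6–0.8 instead of >0.97); the two changes above are what make recovery
reliable. All four values and the standardize switch are configurable.

### Initialization

The sparse-factor posterior is multimodal: rotations of the factor
basis are separated by low-density barriers, and a randomly initialized
chain sticks in a rotated mode on a noticeable fraction of seeds (the
joint log-posterior of such modes is not reliably lower, so chain
selection does not help). `run_gibbs` therefore starts, by default, from
the varimax-rotated truncated SVD of the standardized data: varimax
rotates the leading-K loadings toward maximal sparsity, which is exactly
the basin the Student-t prior favors, and the sampler refines loadings,
factors and precisions jointly from there. `init="random"` restores the
random start (F ~ N(0,1), Λ ~ N(0, 0.01), precisions at prior means),
which is retained for mixing diagnostics such as the independent-restart
stationarity check in the test suite.

### Factor alignment

Factor models are identified only up to permutation and sign.
`align_factors` greedily matches estimated to reference rows by maximal
|Pearson correlation| and chooses signs to make matched correlations
positive; the greedy matching agrees with exhaustive search on the test
problems. Zero-variance rows match with correlation 0 and are logged.

## Feature extraction

Registered single-embryo grayscale images are linearly mapped to [0, 1]
(loaders invert dark-on-light staining on request so that stronger
staining is always the larger value), bilinearly resampled with clamped
edges, and reduced to grid-patch means stacked row-major (top-left patch
first), so every feature vector folds back into an image. Grid
dimensions must divide the image dimensions — non-divisible inputs are
rejected rather than silently padded, keeping extraction exactly linear
and intensity-conserving. Default resolutions follow a three-level
scheme (80×40, 40×20 and 16×8 patches over a 320×160 rescale), all
configurable; multi-resolution loading matrices can be concatenated
(with provenance columns) for classification.

## Synthetic corpus

The generator reproduces the generative structure the model assumes,
which is what makes every downstream stage testable without external
data:

* **Templates**: unit-norm patterns inside an elliptical embryo mask —
  anterior/posterior caps (the leading 35% of the long axis), dorsal and
  ventral bands, pair-rule-like stripes, and the mask itself as a
  non-expression "shape" factor. Caps rather than half-masks keep the
  template matrix full-rank (left half + right half would equal the mask
  exactly, making one factor unrecoverable in principle).
* **Loadings**: spike-and-slab, zero with probability `sparsity` (default
  0.8), otherwise half-normal. Non-negative weights reflect additive,
  non-negative staining; they also make labels planted by a loading
  threshold linearly separable, which a signed (two-sided) positive
  class would not be. A signed option exists. Images of the same gene
  share one true loading row (replicate assays of one probe); genes
  whose row comes out all-zero get one entry redrawn so "signal" genes
  are guaranteed a pattern. The stored sparsity is the realized zero
  fraction.
* **Noise**: `psi` is set from the target signal-to-noise ratio via
  `var(ΛF)·ψ = SNR` (default SNR 10, giving reconstruction R² ≈
  SNR/(SNR+1)).
* **Planted structure**: a gene carries an annotation term iff its
  |loading| on the term's factor exceeds a threshold (default factor 0,
  threshold 0); every image inherits its gene's terms. One gene set per
  factor contains a fraction (default 0.8) of the factor's top-loading
  genes plus random background genes. An optional fraction of genes
  (default 0 — 0.2 in the filtering analyses) is made non-informative:
  all-zero loading rows, i.e. pure-noise images mimicking ubiquitous or
  maternal staining.

Default scale: 100 genes × 2 images (N = 200), K = 6, 40×20 grid
(P = 800) — desk-scale so a full Gibbs fit takes seconds while leaving
recovery nontrivial. What the generator does **not** emulate:
registration errors, focal blur, view-angle outliers, staining
chemistry, or correlated (non-Gaussian) noise. Passing tests therefore
demonstrate correctness of the method under its own assumptions, not
performance on real corpora.

## Loading-matrix analyses

A gene's loading row is the element-wise mean over its images' rows (a
max-|·| reducer and arbitrary callables are pluggable). Clustering
assigns `argmax_k |λ_gk|` with ties to the lowest index (logged);
all-zero rows stay unassigned. Informative entries are
`{k : |λ_k| ≥ (1−τ)·max_j |λ_j|}` (default τ = 0.1, scale-invariant);
the cluster link graph counts genes informative for both endpoints of an
edge. Non-informative image filtering drops rows whose Euclidean norm is
below a threshold (boundary kept); `suggest_filter_threshold` locates
the histogram valley by Otsu's criterion on **log** norms — noise norms
cluster tightly near zero while signal norms spread over decades, so the
bimodality lives on the log scale. The automatic threshold presumes such
bimodality; on corpora without a non-informative population it should be
inspected (the CLI accepts an explicit `--filter-threshold`).

## Enrichment

Hypergeometric enrichment is the exact upper-tail sum
P(X ≥ x) for the observed overlap; the χ² test is Pearson's statistic on
the 2×2 in/out-of-cluster × target/non-target table without continuity
correction, skipped (flagged NaN) when an expected cell is zero. The
universe is the set of genes present in the loading matrix — enrichment
is relative to the analyzed corpus, not to the GMT. P-values over the
whole set × cluster matrix are corrected jointly; Benjamini–Hochberg is
the default (standard practice for enrichment matrices) with Bonferroni
available, and the choice is recorded in the report metadata.

## Annotation and evaluation

SMLR is the binary case of sparse multinomial logistic regression: with
two classes and a shared-zero reference class the softmax reduces to a
logistic model, and the Laplacian MAP criterion becomes
`max_w l(w) − reg_lambda·Σ|w_i|` with the intercept unpenalized
(penalizing it would couple sparsity to class balance). The optimizer is
FISTA proximal gradient with soft-thresholding on the exact objective,
restart on momentum overshoot, and convergence when the objective change
drops below 1e-8; solutions match a dense objective-grid search on toy
problems. Default `reg_lambda = 0.1`. Note that on correlated designs
the number of selected features is not strictly monotone along the
penalty path (genuine L1 re-entry); nesting holds on orthogonal designs
and is tested there. The SVM adapter delegates to a polynomial-kernel
SVC with cost 1 (degree 2 by default, enough for two-sided regions like
XOR); its contract is only the decision-value interface.

Cross-validation is at gene level: each fold holds out *all* images of
one gene and scores them with a model trained on the remaining genes'
images, so no image ever informs its own prediction; folds iterate over
genes in sorted order and the protocol is deterministic. Because the
loading matrix inherits the arbitrary intensity scale of the images,
`gene_loocv` divides the feature matrix by its global standard deviation
before CV — a label-free re-parameterization that gives `reg_lambda` a
data-independent meaning.

Per-gene aggregation: majority voting assigns the predominant predicted
label (exact ties to the negative class, conservative and logged);
minority voting counts a gene correct if any image is predicted
correctly, so minority accuracy dominates majority accuracy by
construction. The gene score used for ROC analysis is the fraction of
positively classified images — thresholding it at 1/2 reproduces
majority voting and at 0 minority voting, making both voting rules
thresholdings of one score. AUC is the rank-based Mann–Whitney statistic
(ties counted half); ARR is the fraction correct, reported at both image
and gene level and never left implicit, with the usual caveat that a
trivial larger-class predictor attains ARR equal to the majority-class
share while its AUC stays at 0.5. Terms with too few annotated genes
(default: ≤ 10) are filtered before evaluation; balanced gene-level
train/test splits with repeats are available for fixed-size designs.
The evaluation report is the per-term metric table plus its arithmetic
mean, serialized with the full scheme metadata (classifier, CV, voting,
seeds).

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` run the pipeline at the
default corpus scale (N = 200, P = 800, K = 6) with 3000–4000 Gibbs
sweeps and 1000–1500 burn-in; at this scale a fit takes well under a
minute and the headline results are stable across seeds (factor
recovery |r| ≥ 0.97, recovered sparsity within 0.05 of planted,
planted-term LOO-CV AUC ≈ 0.95, 100% noise-image removal at ≤ 10%
signal loss). Monte-Carlo checks of the conditional samplers use 1e5
draws and 3σ bands; scalar conditionals are verified against trapezoidal
quadrature of the unnormalized posterior to three decimals.

## Known limitations

* K is fixed by the user; there is no automatic factor-number selection,
  and no rotation-identified (orthogonalized) output beyond the
  alignment utility.
* Inference is MCMC only (no variational or EM path); runtime grows
  linearly in N, P and sweeps.
* The synthetic corpus omits the messy parts of real imaging data
  (registration error, focus, views); real-data performance claims are
  outside what the tests establish.
* The automatic filter threshold assumes a bimodal norm distribution.
* SMLR is binary; multi-class annotation is handled term-by-term.
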