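# spexfa — sparse Bayesian factor analysis of spatial expression images

`spexfa` decomposes a corpus of registered gene-expression images (for
example *Drosophila* embryo in situ hybridization stains) into a small
set of latent **spatial factors** — image-shaped basis patterns such as
an anterior cap, a dorsal band or pair-rule stripes — together with
**sparse mixing weights** that say how strongly each image uses each
factor. The weights are a compact, interpretable representation of every
expression pattern, and the package builds the downstream analyses on
top of them: gene clustering and spatial co-expression, gene-set
enrichment of the clusters, filtering of non-informative (ubiquitous or
empty) images, and automatic annotation of patterns with anatomical
vocabulary terms. It is aimed at computational biologists working with
high-throughput imaging screens where manual annotation no longer
scales.

## Model

Each image is reduced to a feature vector of grid-patch mean
intensities; the row-wise mean-centered vectors form the data matrix
`X` (N images × P patches), modeled as

```
X = Λ F + E
```

* `F` (K × P): latent factors; each row is a spatial template, each
  entry has a standard-normal prior.
* `Λ` (N × K): factor loadings (mixing weights), with a Student-t
  sparseness prior in Gamma-hierarchy form:
  `λ_nk | α_nk ~ N(0, 1/α_nk)`, `α_nk ~ Gamma(a, rate b)`. Integrating
  out `α_nk` leaves a heavy-tailed marginal that shrinks most loadings
  toward zero — the biological assumption that a pattern uses only a few
  spatial domains.
* `E`: Gaussian noise with per-feature precision
  `ψ_p ~ Gamma(c, rate d)`.

Inference is Gibbs sampling over the four exact conjugate conditionals
(factor columns, loading rows, loading precisions, noise precisions);
posterior means of `Λ` and `F` over the post-burn-in sweeps are the
estimates. Factors are identified only up to permutation and sign, so
comparisons go through `align_factors`.

Downstream, a gene is clustered to `argmax_k |λ_gk|`; entries within a
fraction τ of the row maximum are *informative* and link clusters that
share genes; clusters are tested against gene sets with exact
hypergeometric upper tails or 2×2 Pearson χ², BH-corrected; images whose
loading row has near-zero Euclidean norm are filtered out; and per-term
annotation uses SMLR (L1-penalized logistic regression, a Laplacian MAP
estimate maximizing `l(w) − λ Σ|w_i|`) or a polynomial-kernel SVM under
gene-level leave-one-out cross-validation, scored by rank-based AUC and
absolute recognition rate with majority/minority voting across a gene's
images.

Because public image corpora are not bundled, the package ships a
synthetic-data generator that emulates the assumed generative process —
spatial templates inside an elliptical embryo mask, sparse non-negative
loadings, Gaussian noise at a controlled signal-to-noise ratio, plus
planted annotation terms and enriched gene sets — so the whole pipeline
runs and is testable out of the box.

## Worked example

```python
import numpy as np
import spexfa as sx

# build the demonstration corpus: 100 genes x 2 images on a 40x20 grid
corpus = sx.make_default_corpus(rng_seed=7)
fm = sx.center_gene_patterns(corpus.fm)

# fit K=6 sparse factors by Gibbs sampling
summary = sx.run_gibbs(fm, sx.SBFAHyperParams(K=6), n_iter=3000, burn_in=1000, rng_seed=7)

# compare recovered factors with the generating templates
perm, signs, corrs = sx.align_factors(summary.F_mean, corpus.truth.F_true)
print("factor recovery |r|:", np.round(corrs, 3))

# cluster genes by their strongest loading
Lg, genes = sx.gene_loading_matrix(summary.Lambda_mean, summary.row_meta)
clusters = sx.assign_clusters(Lg, genes)
print("cluster sizes:", [len(clusters.genes_of_factor(k)) for k in range(6)])

# annotate the planted term by gene-level leave-one-out CV
image_ids = [m[0] for m in summary.row_meta]
cv = sx.gene_loocv(summary.Lambda_mean, image_ids, corpus.labels, "term_factor0")
scores, y = [], []
for g in sorted(cv["gene_id"].unique()):
    sub = cv[cv["gene_id"] == g]
    scores.append(sx.gene_score(sub["score"].tolist()))
    y.append(int(sub["y_true"].iloc[0]))
print(f"planted-term AUC: {sx.compute_auc(scores, y):.3f}")
```

Output:

```
factor recovery |r|: [0.996 0.998 0.998 0.999 0.998 0.995]
cluster sizes: [19, 16, 21, 17, 15, 12]
planted-term AUC: 0.941
```

All six generating templates are recovered with |correlation| ≥ 0.995
after sign/permutation alignment, the hundred genes split into six
loading-defined clusters, and the planted anatomical term is predicted
with AUC 0.94 under gene-level leave-one-out cross-validation (no image
of a gene is ever in its own training fold).

The same pipeline is available from the shell:

```
spexfa simulate --out corpus --seed 7
spexfa features --images corpus/images --meta corpus/meta.tsv --grid 40x20 --center --out X.tsv
spexfa fit      --features corpus/X.tsv --k 6 --iters 3000 --burnin 1000 --seed 7 --out model/
spexfa analyze  --model model/ --tau 0.1 --topq 50 --out analysis/
spexfa enrich   --clusters analysis/clusters.tsv --sets corpus/sets.gmt --out enrich.tsv
spexfa classify --model model/ --labels corpus/labels.tsv --term term_factor0 --clf smlr --out report.json
```

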