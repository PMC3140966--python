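"""Shared fixtures: the default synthetic corpus and fitted models.

The heavier Gibbs fits are session-scoped so the parameter-recovery,
annotation and filtering checks share one sampler run each.
"""

import numpy as np
import pytest

import spexfa as sx

CORPUS_SEED = 7
GIBBS_ITERS = 3000
GIBBS_BURNIN = 1000


@pytest.fixture(scope="session")
def default_corpus():
    """Study-conditions corpus: 100 genes x 2 images, K=6 templates on a
    40x20 grid, sparsity 0.8, SNR 10."""
    return sx.make_default_corpus(rng_seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def fitted_default(default_corpus):
    fm = sx.center_gene_patterns(default_corpus.fm)
    hp = sx.SBFAHyperParams(K=6)
    return sx.run_gibbs(fm, hp, n_iter=GIBBS_ITERS, burn_in=GIBBS_BURNIN, rng_seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def noise_corpus():
    """Same corpus with 20% of genes planted as non-informative (all-zero
    loading rows, pure-noise images)."""
    return sx.make_default_corpus(rng_seed=CORPUS_SEED, frac_noninformative=0.2)


@pytest.fixture(scope="session")
def fitted_noise(noise_corpus):
    fm = sx.center_gene_patterns(noise_corpus.fm)
    hp = sx.SBFAHyperParams(K=6)
    return sx.run_gibbs(fm, hp, n_iter=GIBBS_ITERS, burn_in=GIBBS_BURNIN, rng_seed=CORPUS_SEED)


def loocv_gene_metrics(summary, labels, term, classifier="smlr"):
    """Run gene-level LOO-CV for a term and pool image scores per gene."""
    image_ids = [m[0] for m in summary.row_meta]
    cv = sx.gene_loocv(summary.Lambda_mean, image_ids, labels, term, classifier=classifier)
    genes = sorted(cv["gene_id"].unique())
    scores, y_true, majority, minority_ok = [], [], [], []
    for g in genes:
        sub = cv[cv["gene_id"] == g]
        truth = int(sub["y_true"].iloc[0])
        scores.append(sx.gene_score(sub["score"].tolist()))
        y_true.append(truth)
        majority.append(sx.vote_majority(sub["pred"].tolist()))
        minority_ok.append(sx.vote_minority(sub["pred"].tolist(), truth))
    return {
        "auc": sx.compute_auc(scores, y_true),
        "arr_majority": sx.compute_arr(majority, y_true),
        "accuracy_minority": float(np.mean(minority_ok)),
        "n_pos": int(sum(y_true)),
    }
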