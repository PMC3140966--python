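"""Automatic annotation of expression patterns from factor loadings.

A gene in the corpus carries zero or more controlled-vocabulary anatomical
terms (e.g. "posterior midgut primordium"); every image of the gene
inherits its terms.  For each term a binary classifier is trained on the
sparse factor loadings of the images and evaluated under *gene-level*
leave-one-out cross-validation: all images of one gene are held out per
fold so a gene never contributes to its own training set.

Two classifiers are provided:

* SMLR — sparse multinomial logistic regression.  For the binary case the
  softmax with a shared-zero reference class reduces to logistic
  regression; the weights maximize the penalized log-likelihood
  l(w) - reg_lambda * sum_i |w_i| (a Laplacian MAP criterion), with the
  intercept unpenalized.  Optimized by FISTA proximal gradient on the
  exact objective.
* A polynomial-kernel SVM adapter (cost parameter 1) delegating to
  scikit-learn.

Because a gene has several images, image-level predictions are pooled:
majority voting assigns the predominant predicted label; minority voting
counts a gene correct if any image is predicted correctly.  The gene
score used for ROC analysis is the fraction of positively classified
images, so thresholding it at 1/2 reproduces majority voting and at 0
reproduces minority voting.  Metrics are rank-based AUC (Mann-Whitney,
ties counted half) and the absolute recognition rate (ARR, fraction
correct — inflated on unbalanced data).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "LabelSet",
    "SMLRModel",
    "EvalReport",
    "train_smlr",
    "predict_smlr",
    "smlr_objective",
    "train_svm_poly",
    "gene_loocv",
    "vote_majority",
    "vote_minority",
    "gene_score",
    "compute_auc",
    "compute_arr",
    "balanced_splits",
    "filter_terms",
    "concat_multires_features",
    "feature_relevance_histogram",
    "evaluation_report",
]


# --------------------------------------------------------------------------
# labels


@dataclass
class LabelSet:
    """Gene -> annotation-term assignments plus the image -> gene map."""

    gene_terms: dict[str, set[str]]
    image_gene: dict[str, str]

    @property
    def terms(self) -> list[str]:
        out: set[str] = set()
        for ts in self.gene_terms.values():
            out |= ts
        return sorted(out)

    def y_images(self, term: str, image_ids: Sequence[str]) -> np.ndarray:
        """Binary per-image labels for one term (image inherits gene's terms)."""
        return np.array(
            [1 if term in self.gene_terms.get(self.image_gene[i], set()) else 0 for i in image_ids],
            dtype=int,
        )

    def y_genes(self, term: str, gene_ids: Sequence[str]) -> np.ndarray:
        return np.array([1 if term in self.gene_terms.get(g, set()) else 0 for g in gene_ids], dtype=int)

    def genes_with_term(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}

    def to_tsv(self, path: str) -> None:
        rows = [(g, t) for g in sorted(self.gene_terms) for t in sorted(self.gene_terms[g])]
        pd.DataFrame(rows, columns=["gene_id", "term"]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, image_gene: Mapping[str, str]) -> "LabelSet":
        df = pd.read_csv(path, sep="\t")
        gene_terms: dict[str, set[str]] = {}
        for g, t in zip(df["gene_id"].astype(str), df["term"].astype(str)):
            gene_terms.setdefault(g, set()).add(t)
        for g in set(image_gene.values()):
            gene_terms.setdefault(g, set())
        return cls(gene_terms=gene_terms, image_gene=dict(image_gene))


# --------------------------------------------------------------------------
# SMLR: L1-MAP logistic regression


@dataclass
class SMLRModel:
    """Fitted sparse logistic classifier (binary softmax, zero reference class)."""

    weights: np.ndarray  # per-feature weights of the positive class
    intercept: float
    reg_lambda: float
    converged: bool
    objective: float

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(np.abs(self.weights) > 1e-8))


def smlr_objective(w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray, reg_lambda: float) -> float:
    """Penalized log-likelihood l(w) - reg_lambda * ||w||_1 (to maximize)."""
    z = X @ w + b
    # log-likelihood of logistic model: sum y*z - log(1+e^z), stable form
    ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
    return ll - reg_lambda * float(np.sum(np.abs(w)))


def train_smlr(
    features: np.ndarray,
    labels: np.ndarray,
    reg_lambda: float = 0.1,
    fit_intercept: bool = True,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> SMLRModel:
    """MAP estimate under a Laplacian (L1) prior on the feature weights.

    Maximizes the binary logistic log-likelihood minus
    ``reg_lambda * sum |w_i|``; the intercept is never penalized.  FISTA
    proximal gradient; converged when the objective change drops below
    ``tol``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be 2-D with one row per label")
    if reg_lambda < 0:
        raise ValueError("reg_lambda must be non-negative")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")

    n, p = X.shape
    w = np.zeros(p)
    b = 0.0
    # Lipschitz constant of the negative log-likelihood gradient
    L = max(np.linalg.norm(X, 2) ** 2, 1.0) / 4.0 + (0.25 * n if fit_intercept else 0.0)
    step = 1.0 / L

    def neg_ll_grad(w_: np.ndarray, b_: float) -> tuple[np.ndarray, float, float]:
        z = X @ w_ + b_
        mu = 1.0 / (1.0 + np.exp(-z))
        r = mu - y
        nll = -float(np.sum(y * z - np.logaddexp(0.0, z)))
        return X.T @ r, float(np.sum(r)) if fit_intercept else 0.0, nll

    # FISTA with momentum on (w, b)
    wv, bv = w.copy(), b
    t_mom = 1.0
    obj_prev = -smlr_objective(w, b, X, y, reg_lambda)
    converged = False
    for _ in range(max_iter):
        gw, gb, _ = neg_ll_grad(wv, bv)
        w_new = wv - step * gw
        # soft-thresholding proximal step for the L1 penalty
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step * reg_lambda, 0.0)
        b_new = bv - step * gb if fit_intercept else 0.0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        wv = w_new + ((t_mom - 1.0) / t_new) * (w_new - w)
        bv = b_new + ((t_mom - 1.0) / t_new) * (b_new - b)
        obj_new = -smlr_objective(w_new, b_new, X, y, reg_lambda)
        if obj_new > obj_prev:  # momentum overshoot: restart
            wv, bv, t_new = w_new.copy(), b_new, 1.0
        w, b, t_mom = w_new, b_new, t_new
        if abs(obj_prev - obj_new) < tol:
            converged = True
            obj_prev = obj_new
            break
        obj_prev = obj_new
    if not converged:
        logger.warning("SMLR did not converge in %d iterations", max_iter)
    return SMLRModel(
        weights=w,
        intercept=b,
        reg_lambda=reg_lambda,
        converged=converged,
        objective=smlr_objective(w, b, X, y, reg_lambda),
    )


def predict_smlr(model: SMLRModel, features: np.ndarray) -> np.ndarray:
    """Per-class probabilities, shape (n, 2), columns (P(y=0), P(y=1))."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.weights.size:
        raise ValueError(
            f"feature dimension {X.shape[1] if X.ndim == 2 else '?'} does not match model ({model.weights.size})"
        )
    z = X @ model.weights + model.intercept
    p1 = 1.0 / (1.0 + np.exp(-z))
    return np.column_stack([1.0 - p1, p1])


# --------------------------------------------------------------------------
# SVM adapter


class PolySVM:
    """Polynomial-kernel SVM with cost parameter 1 (scikit-learn backend)."""

    def __init__(self, degree: int = 2, coef0: float = 1.0):
        self._clf = SVC(kernel="poly", degree=degree, coef0=coef0, gamma="scale", C=1.0)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PolySVM":
        y = np.asarray(y).ravel()
        if np.unique(y).size < 2:
            raise ValueError("training data must contain both classes")
        self._clf.fit(np.asarray(X, dtype=float), y)
        return self

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self._clf.decision_function(np.asarray(X, dtype=float)), dtype=float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_values(X) > 0).astype(int)


def train_svm_poly(features: np.ndarray, labels: np.ndarray, degree: int = 2) -> PolySVM:
    """Fit the polynomial-kernel SVM adapter (C = 1)."""
    return PolySVM(degree=degree).fit(features, labels)


# --------------------------------------------------------------------------
# cross-validation protocol


def gene_loocv(
    features: np.ndarray,
    image_ids: Sequence[str],
    labels: LabelSet,
    term: str,
    classifier: str | Callable[[np.ndarray, np.ndarray], object] = "smlr",
    reg_lambda: float = 0.1,
    return_models: bool = False,
    standardize: bool = True,
):
    """Gene-level leave-one-out CV: per-fold, all images of one gene are
    held out and scored by a model trained on every other gene's images.

    Returns a DataFrame (image_id, gene_id, y_true, score, pred) with one
    row per image; every image is scored exactly once.  ``score`` is the
    decision value (log-odds for SMLR, margin for SVM); ``pred`` its sign.
    Folds iterate over genes in sorted order, so the protocol is
    deterministic.  With ``return_models`` the per-fold fitted models are
    returned as a second value (for feature-relevance histograms).

    ``standardize`` divides the whole feature matrix by its global
    standard deviation before CV — a label-free re-parameterization that
    gives ``reg_lambda`` a data-scale-independent meaning (loading
    matrices inherit the arbitrary intensity scale of the images).
    """
    X = np.asarray(features, dtype=float)
    if standardize:
        s = X.std()
        if s > 0:
            X = X / s
    image_ids = [str(i) for i in image_ids]
    genes = np.array([labels.image_gene[i] for i in image_ids])
    y = labels.y_images(term, image_ids)
    pos_genes = {g for g, lab in zip(genes, y) if lab == 1}
    neg_genes = set(genes) - pos_genes
    if len(pos_genes) < 2 or len(neg_genes) < 2:
        raise ValueError(f"term {term!r} needs >= 2 genes in each class for gene-level LOO-CV")

    def make_fit(Xtr, ytr):
        if callable(classifier):
            return classifier(Xtr, ytr)
        if classifier == "smlr":
            model = train_smlr(Xtr, ytr, reg_lambda=reg_lambda)
            return model
        if classifier == "svm":
            return train_svm_poly(Xtr, ytr)
        raise ValueError(f"unknown classifier {classifier!r}")

    def decision(model, Xte):
        if isinstance(model, SMLRModel):
            return Xte @ model.weights + model.intercept
        return model.decision_values(Xte)

    rows = []
    models = []
    ids_arr = np.array(image_ids)
    for g in sorted(set(genes)):
        test_mask = genes == g
        Xtr, ytr = X[~test_mask], y[~test_mask]
        model = make_fit(Xtr, ytr)
        models.append(model)
        scores = decision(model, X[test_mask])
        for i, yt, s in zip(ids_arr[test_mask], y[test_mask], scores):
            rows.append((i, g, int(yt), float(s), int(s > 0)))
    df = pd.DataFrame(rows, columns=["image_id", "gene_id", "y_true", "score", "pred"])
    return (df, models) if return_models else df


# --------------------------------------------------------------------------
# voting and metrics


def vote_majority(image_predictions: Sequence[int]) -> int:
    """1 iff strictly more than half the images are predicted positive.

    Exact ties go to the negative class (conservative)."""
    preds = list(image_predictions)
    if not preds:
        raise ValueError("empty prediction list")
    n_pos = sum(1 for p in preds if p == 1)
    if 2 * n_pos == len(preds):
        logger.debug("majority-vote tie (%d images); assigning negative class", len(preds))
    return int(2 * n_pos > len(preds))


def vote_minority(image_predictions: Sequence[int], true_label: int) -> bool:
    """Correct iff at least one image prediction equals the true label."""
    preds = list(image_predictions)
    if not preds:
        raise ValueError("empty prediction list")
    return any(p == true_label for p in preds)


def gene_score(image_scores: Sequence[float]) -> float:
    """Fraction of a gene's images with positive decision value.

    Thresholding at > 1/2 reproduces majority voting; at > 0, minority
    voting for a positive gene."""
    scores = list(image_scores)
    if not scores:
        raise ValueError("empty score list")
    return sum(1 for s in scores if s > 0) / len(scores)


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 1/2 P(equal) (Mann-Whitney)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: one class absent")
    ranks = rankdata(s)
    u = float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def compute_arr(predicted: Sequence[int], true: Sequence[int]) -> float:
    """Absolute recognition rate: fraction of samples classified correctly."""
    p = np.asarray(predicted)
    t = np.asarray(true)
    if p.size == 0 or p.size != t.size:
        raise ValueError("predicted and true labels must be non-empty and equal-length")
    return float(np.mean(p == t))


def balanced_splits(
    labels: LabelSet,
    term: str,
    n_per_class: int,
    repeats: int,
    rng_seed: int,
) -> list[tuple[list[str], list[str]]]:
    """Repeated balanced gene-level splits: each repeat draws n_per_class
    positive and negative genes (without replacement) for training; the
    remaining genes form the test set."""
    pos = sorted(labels.genes_with_term(term))
    neg = sorted(set(labels.gene_terms) - set(pos))
    if len(pos) <= n_per_class - 1 or len(neg) <= n_per_class - 1 or not pos or not neg:
        raise ValueError("not enough genes per class for the requested split")
    if len(pos) == n_per_class and len(neg) == n_per_class:
        raise ValueError("no genes left for testing")
    rng = np.random.default_rng(rng_seed)
    splits = []
    for _ in range(repeats):
        tr_pos = list(rng.choice(pos, size=n_per_class, replace=False))
        tr_neg = list(rng.choice(neg, size=n_per_class, replace=False))
        train = sorted(tr_pos + tr_neg)
        test = sorted(set(pos + neg) - set(train))
        splits.append((train, test))
    return splits


def filter_terms(labels: LabelSet, min_genes: int = 10) -> list[str]:
    """Terms with more than ``min_genes`` annotated genes, ordered by
    descending gene count then name; rarer terms are too weak to learn."""
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    counts = {t: len(labels.genes_with_term(t)) for t in labels.terms}
    kept = [t for t, c in counts.items() if c > min_genes]
    return sorted(kept, key=lambda t: (-counts[t], t))


def concat_multires_features(
    loading_frames: Sequence[pd.DataFrame],
    resolution_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Horizontally concatenate loading matrices from several grid
    resolutions, aligned on image_id; columns record their provenance as
    ``<resolution>:<original column>``.

    Each input frame must be indexed by image_id (or carry an image_id
    column) and all must cover the identical image set.
    """
    if not loading_frames:
        raise ValueError("no loading matrices given")
    names = list(resolution_names) if resolution_names is not None else [f"res{i}" for i in range(len(loading_frames))]
    if len(names) != len(loading_frames):
        raise ValueError("resolution_names length mismatch")
    prepared = []
    for name, df in zip(names, loading_frames):
        df = df.copy()
        if "image_id" in df.columns:
            df = df.set_index("image_id")
        df = df.sort_index()
        df.columns = [f"{name}:{c}" for c in df.columns]
        prepared.append(df)
    base = set(prepared[0].index)
    for name, df in zip(names[1:], prepared[1:]):
        if set(df.index) != base:
            offenders = sorted(set(df.index) ^ base)
            raise ValueError(f"image_id mismatch in {name}: {offenders[:10]}")
    return pd.concat(prepared, axis=1)


def feature_relevance_histogram(smlr_models: Sequence[SMLRModel], tolerance: float = 1e-8) -> pd.DataFrame:
    """Per-feature count of CV folds where |weight| > tolerance.

    Columns: feature, n_selected, always_selected, never_selected — the
    always/never sets mirror the relevance analysis of sparse classifiers
    across leave-one-out folds.
    """
    if not smlr_models:
        raise ValueError("no models given")
    W = np.stack([m.weights for m in smlr_models])
    counts = np.sum(np.abs(W) > tolerance, axis=0)
    n_folds = len(smlr_models)
    return pd.DataFrame(
        {
            "feature": np.arange(W.shape[1]),
            "n_selected": counts,
            "always_selected": counts == n_folds,
            "never_selected": counts == 0,
        }
    )


# --------------------------------------------------------------------------
# reporting


@dataclass
class EvalReport:
    """Per-term metric table plus the arithmetic mean over terms."""

    table: pd.DataFrame  # one row per term
    metric: str
    mean: float
    scheme: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "metric": self.metric,
            "mean": self.mean,
            "scheme": self.scheme,
            "per_term": self.table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def evaluation_report(
    per_term_metrics: Mapping[str, float] | pd.DataFrame,
    metric: str = "ARR",
    scheme: dict | None = None,
) -> EvalReport:
    """Assemble the per-term table and its mean over terms.

    ``per_term_metrics`` is either a term -> value mapping or a DataFrame
    with columns (term, value) plus optional count columns.
    """
    if isinstance(per_term_metrics, pd.DataFrame):
        table = per_term_metrics.copy()
        if "value" not in table.columns:
            raise ValueError("DataFrame input needs a 'value' column")
    else:
        if not per_term_metrics:
            raise ValueError("at least one term is required")
        table = pd.DataFrame(
            {"term": list(per_term_metrics.keys()), "value": list(per_term_metrics.values())}
        )
    mean = float(np.mean(table["value"].to_numpy(dtype=float)))
    return EvalReport(table=table, metric=metric, mean=mean, scheme=dict(scheme or {}))
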