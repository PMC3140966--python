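"""Analyses of the posterior loading matrix.

The sparse loadings double as a clustering: each gene is assigned to the
factor on which it loads most strongly in absolute value (the factors act
as cluster centroids).  Because a gene pattern may genuinely mix a few
domains, all entries within a fraction ``tau`` of the row's absolute
maximum are called *informative*; genes informative for two factors link
those factors in the cluster link graph (spatial co-expression).  Loading
rows also flag non-informative images — ubiquitous or empty patterns have
near-zero loading everywhere, so a small Euclidean norm of an image's
loading row marks it for removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "ClusterLinkGraph",
    "gene_loading_matrix",
    "gene_loading_row",
    "assign_clusters",
    "informative_entries",
    "cluster_link_graph",
    "top_loading_genes",
    "filter_noninformative",
    "suggest_filter_threshold",
]


@dataclass
class ClusterAssignment:
    """gene -> winning factor, with the winning |loading| and unassigned genes."""

    assignment: dict[str, int]
    winning_value: dict[str, float]
    unassigned: list[str]

    def genes_of_factor(self, k: int) -> list[str]:
        return sorted(g for g, f in self.assignment.items() if f == k)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, self.assignment[g], self.winning_value[g]) for g in sorted(self.assignment)]
        return pd.DataFrame(rows, columns=["gene_id", "factor", "winning_abs_loading"])


@dataclass
class ClusterLinkGraph:
    """Factors as nodes; edge weight = number of genes shared by two factors."""

    edges: dict[tuple[int, int], int] = field(default_factory=dict)

    def weight(self, j: int, k: int) -> int:
        return self.edges.get((min(j, k), max(j, k)), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [(j, k, w) for (j, k), w in sorted(self.edges.items())]
        return pd.DataFrame(rows, columns=["factor_a", "factor_b", "n_shared"])


def gene_loading_row(
    Lambda_mean: np.ndarray,
    row_meta: Sequence[tuple[str, str]],
    gene_id: str,
    reducer: Callable[[np.ndarray], np.ndarray] | str = "mean",
) -> np.ndarray:
    """Pool a gene's per-image loading rows into one length-K vector.

    The default reducer is the element-wise mean; ``"max_abs"`` keeps, per
    factor, the entry of largest absolute value (sign preserved); any
    callable mapping an (n_images, K) block to a length-K vector works.
    """
    rows = np.array([i for i, (_, g) in enumerate(row_meta) if g == gene_id])
    if rows.size == 0:
        raise KeyError(f"gene {gene_id!r} has no image rows")
    block = np.asarray(Lambda_mean)[rows]
    if callable(reducer):
        return np.asarray(reducer(block), dtype=float)
    if reducer == "mean":
        return block.mean(axis=0)
    if reducer == "max_abs":
        idx = np.argmax(np.abs(block), axis=0)
        return block[idx, np.arange(block.shape[1])]
    raise ValueError(f"unknown reducer {reducer!r}")


def gene_loading_matrix(
    Lambda_mean: np.ndarray,
    row_meta: Sequence[tuple[str, str]],
    reducer: Callable[[np.ndarray], np.ndarray] | str = "mean",
) -> tuple[np.ndarray, list[str]]:
    """Pool every gene: returns (G x K matrix, gene ids in first-seen order)."""
    genes = list(dict.fromkeys(g for _, g in row_meta))
    M = np.stack([gene_loading_row(Lambda_mean, row_meta, g, reducer) for g in genes])
    return M, genes


def assign_clusters(Lambda_gene: np.ndarray, gene_ids: Sequence[str] | None = None) -> ClusterAssignment:
    """Assign each gene to argmax_k |lambda_gk|; ties go to the lowest
    factor index; all-zero rows are left unassigned."""
    L = np.asarray(Lambda_gene, dtype=float)
    if L.ndim != 2 or L.shape[0] < 1:
        raise ValueError("Lambda_gene must be a non-empty 2-D matrix")
    ids = list(gene_ids) if gene_ids is not None else [f"g{i:04d}" for i in range(L.shape[0])]
    assignment: dict[str, int] = {}
    winning: dict[str, float] = {}
    unassigned: list[str] = []
    for g, row in zip(ids, np.abs(L)):
        if not row.any():
            unassigned.append(g)
            continue
        k = int(np.argmax(row))  # argmax returns the first (lowest) index on ties
        if np.sum(row == row[k]) > 1:
            logger.debug("gene %s: tie at max |loading|; lowest factor index %d chosen", g, k)
        assignment[g] = k
        winning[g] = float(row[k])
    return ClusterAssignment(assignment=assignment, winning_value=winning, unassigned=unassigned)


def informative_entries(loading_row: np.ndarray, tau: float = 0.1) -> set[int]:
    """Factor indices with |lambda_k| within a fraction tau of the row's
    absolute maximum: {k : |lambda_k| >= (1 - tau) * max_j |lambda_j|}."""
    if not (0.0 <= tau < 1.0):
        raise ValueError("tau must be in [0, 1)")
    row = np.abs(np.asarray(loading_row, dtype=float))
    m = row.max(initial=0.0)
    if m == 0.0:
        return set()
    return set(np.flatnonzero(row >= (1.0 - tau) * m).tolist())


def cluster_link_graph(Lambda_gene: np.ndarray, tau: float = 0.1) -> ClusterLinkGraph:
    """Edge (j, k) counts the genes whose informative set contains both
    factors; zero-weight edges are omitted."""
    L = np.asarray(Lambda_gene, dtype=float)
    edges: dict[tuple[int, int], int] = {}
    for row in L:
        info = sorted(informative_entries(row, tau))
        for i, j in enumerate(info):
            for k in info[i + 1 :]:
                edges[(j, k)] = edges.get((j, k), 0) + 1
    return ClusterLinkGraph(edges=edges)


def top_loading_genes(
    Lambda_gene: np.ndarray,
    gene_ids: Sequence[str],
    factor: int,
    q: int,
) -> list[str]:
    """The q genes with largest |loading| on one factor, descending;
    ties broken lexicographically by gene id."""
    L = np.asarray(Lambda_gene, dtype=float)
    G = L.shape[0]
    if not (1 <= q <= G):
        raise ValueError(f"q must be in [1, {G}]")
    col = np.abs(L[:, factor])
    order = sorted(range(G), key=lambda i: (-col[i], str(gene_ids[i])))
    return [str(gene_ids[i]) for i in order[:q]]


def filter_noninformative(
    Lambda_mean: np.ndarray,
    image_ids: Sequence[str],
    threshold: float,
) -> tuple[list[str], list[str]]:
    """Drop images whose loading row has Euclidean norm below ``threshold``.

    An informative pattern loads visibly on at least one factor; rows near
    the null vector belong to non-informative (e.g. ubiquitous) images.
    A norm exactly equal to the threshold is kept.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    norms = np.linalg.norm(np.asarray(Lambda_mean, dtype=float), axis=1)
    kept = [str(i) for i, nv in zip(image_ids, norms) if nv >= threshold]
    dropped = [str(i) for i, nv in zip(image_ids, norms) if nv < threshold]
    return kept, dropped


def suggest_filter_threshold(Lambda_mean: np.ndarray) -> float:
    """Valley of the loading-norm histogram, via Otsu's criterion on
    log-norms.

    Norms of non-informative images cluster tightly near zero while
    signal norms spread over orders of magnitude, so the histogram is
    bimodal on a log scale; Otsu's threshold there sits in the valley
    between the two modes.
    """
    norms = np.linalg.norm(np.asarray(Lambda_mean, dtype=float), axis=1)
    if norms.size < 2 or np.allclose(norms, norms[0]):
        raise ValueError("norm distribution is degenerate; no valley to find")
    log_norms = np.log10(np.maximum(norms, np.finfo(float).tiny))
    return float(10.0 ** threshold_otsu(log_norms))
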