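"""Gene-set enrichment of factor clusters.

Each factor's gene cluster (or top-loading gene list) is tested against
annotated gene sets — GO-style categories with the hypergeometric
upper-tail test, transcription-factor target sets with the 2x2 Pearson
chi-square test — relative to the universe of genes present in the
loading matrix.  P-values across the whole set x cluster matrix are
corrected jointly (Benjamini-Hochberg by default, Bonferroni available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "hypergeom_enrichment",
    "pearson_chi2",
    "chisq_enrichment",
    "adjust_pvalues",
    "enrichment_matrix",
]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a gene universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    @classmethod
    def from_sets(cls, sets: Mapping[str, Iterable[str]], universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with the universe on load (dropped genes logged)."""
        uni = set(universe)
        filtered: dict[str, set[str]] = {}
        for name, genes in sets.items():
            g = set(genes)
            outside = g - uni
            if outside:
                logger.debug("set %s: %d gene(s) outside the universe dropped", name, len(outside))
            filtered[name] = g & uni
        return cls(sets=filtered, universe=uni)


def hypergeom_enrichment(cluster: set[str], annotated: set[str], universe_size: int) -> float:
    """Upper-tail hypergeometric p-value of the cluster/set overlap.

    With M genes in the universe, K_set annotated, n in the cluster and
    x = |cluster & annotated|, returns P(X >= x) for
    X ~ Hypergeometric(M, K_set, n) as an exact tail sum.
    """
    n, K_set = len(cluster), len(annotated)
    if n > universe_size or K_set > universe_size:
        raise ValueError("cluster and annotated set must fit inside the universe")
    x = len(cluster & annotated)
    return float(stats.hypergeom.sf(x - 1, universe_size, K_set, n))


def pearson_chi2(table: np.ndarray) -> tuple[float, float, bool]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Returns (statistic, p-value from the chi-square_1 upper tail, ok);
    if any expected cell count is 0 the test is skipped (ok False,
    NaN statistic and p-value).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    total = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / total if total > 0 else np.zeros_like(obs)
    if np.any(expected == 0):
        logger.debug("chi-square skipped: zero expected cell count")
        return float("nan"), float("nan"), False
    statistic = float(np.sum((obs - expected) ** 2 / expected))
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p, True


def chisq_enrichment(
    targets: set[str], cluster: set[str], universe: set[str]
) -> tuple[float, float, bool]:
    """Pearson chi-square (no continuity correction) on the 2x2 table
    (in/out of cluster) x (target/non-target).

    Returns (statistic, p-value, ok).  If any expected cell count is 0 the
    test is skipped: ok is False and the p-value is NaN.
    """
    if not (targets <= universe and cluster <= universe):
        raise ValueError("targets and cluster must be subsets of the universe")
    M = len(universe)
    a = len(cluster & targets)
    b = len(cluster - targets)
    c = len(targets - cluster)
    d = M - a - b - c
    return pearson_chi2(np.array([[a, b], [c, d]], dtype=float))


def adjust_pvalues(pvalues: Sequence[float], method: str = "bh") -> list[float]:
    """Multiple-testing correction: Benjamini-Hochberg step-up or
    Bonferroni min(m*p, 1); input order preserved, values clipped to [0,1]."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        sm_method = "fdr_bh"
    elif method == "bonferroni":
        sm_method = "bonferroni"
    else:
        raise ValueError(f"unknown correction method {method!r}")
    _, adjusted, _, _ = multipletests(p, method=sm_method)
    return np.clip(adjusted, 0.0, 1.0).tolist()


def enrichment_matrix(
    clusters: Mapping[str | int, Iterable[str]],
    collection: GeneSetCollection,
    test: str = "hypergeom",
    alpha: float = 0.05,
    adjust: str = "bh",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjusted p-values for every gene set against every cluster.

    ``clusters`` maps a cluster key (e.g. factor index) to its gene list;
    each list is intersected with the universe.  Returns
    ``(matrix, significant)``: a (sets x clusters) DataFrame of adjusted
    p-values with deterministic ordering (set name, then cluster key), and
    the list of significant cells at level ``alpha``.  Chi-square cells
    skipped for zero expected counts carry NaN.
    """
    if not clusters or not collection.sets:
        raise ValueError("clusters and gene sets must be non-empty")
    set_names = sorted(collection.sets)
    cluster_keys = sorted(clusters, key=str)
    uni = collection.universe
    raw = np.full((len(set_names), len(cluster_keys)), np.nan)
    for j, ck in enumerate(cluster_keys):
        cl = set(clusters[ck]) & uni
        for i, sn in enumerate(set_names):
            ann = collection.sets[sn]
            if test == "hypergeom":
                raw[i, j] = hypergeom_enrichment(cl, ann, len(uni))
            elif test == "chisq":
                _, p, ok = chisq_enrichment(ann, cl, uni)
                raw[i, j] = p if ok else np.nan
            else:
                raise ValueError(f"unknown test {test!r}")
    flat = raw.ravel()
    valid = np.isfinite(flat)
    adjusted = np.full_like(flat, np.nan)
    if valid.any():
        adjusted[valid] = adjust_pvalues(flat[valid], method=adjust)
    matrix = pd.DataFrame(adjusted.reshape(raw.shape), index=set_names, columns=cluster_keys)
    matrix.index.name = "gene_set"
    sig_rows = [
        (sn, ck, matrix.iat[i, j])
        for i, sn in enumerate(set_names)
        for j, ck in enumerate(cluster_keys)
        if np.isfinite(matrix.iat[i, j]) and matrix.iat[i, j] <= alpha
    ]
    significant = pd.DataFrame(sig_rows, columns=["gene_set", "cluster", "adjusted_p"])
    return matrix, significant
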