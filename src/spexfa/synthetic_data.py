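"""Synthetic corpora with the exact statistical structure the model assumes.

The generator builds data matching the generative model X = Lambda F + E:
spatial factor templates F (image-shaped basis patterns inside an
elliptical embryo mask), sparse per-image loadings Lambda, and Gaussian
noise E with per-feature precision psi.  On top of the matrix it plants
the downstream ground truth — annotation labels derived from the true
loadings and gene sets enriched for each factor's top genes — so the
whole pipeline (Gibbs recovery, clustering, enrichment, classification,
filtering) is testable without any external image corpus.

Defaults emulate a desk-scale version of a two-stage in situ corpus:
100 genes x 2 images each (N = 200), K = 6 templates on a 40 x 20 grid
(P = 800), loading sparsity 0.8, signal-to-noise ratio 10.  Images of the
same gene share one true loading row (replicate assays of one probe);
only the additive noise differs between them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .annotation import LabelSet
from .imaging_features import FeatureMatrix, GridSpec, RegisteredImage

__all__ = [
    "GroundTruth",
    "SyntheticCorpus",
    "TEMPLATE_KINDS",
    "DEFAULT_TEMPLATE_KINDS",
    "make_spatial_templates",
    "sample_sparse_loadings",
    "psi_from_snr",
    "make_ground_truth",
    "render_corpus",
    "derive_labels",
    "plant_gene_sets",
    "make_default_corpus",
    "save_corpus",
    "write_gmt",
    "read_gmt",
]

TEMPLATE_KINDS = (
    "anterior",
    "posterior",
    "dorsal_band",
    "ventral_band",
    "ap_stripes",
    "shape_artifact",
)
DEFAULT_TEMPLATE_KINDS = list(TEMPLATE_KINDS)


@dataclass
class GroundTruth:
    """True loadings, factors, and noise precisions of a simulated corpus."""

    Lambda_true: np.ndarray  # N x K
    F_true: np.ndarray  # K x P, unit-norm row-major templates
    psi_true: np.ndarray  # P, noise precisions
    sparsity: float  # realized fraction of exactly-zero loadings
    seed: int
    gene_of_row: list[str] = field(default_factory=list)  # gene id per image row

    def __post_init__(self) -> None:
        realized = float(np.mean(self.Lambda_true == 0.0))
        if abs(realized - self.sparsity) > 1.0 / self.Lambda_true.size + 1e-12:
            raise ValueError("stored sparsity does not match the realized zero fraction")
        if np.any(self.psi_true <= 0):
            raise ValueError("psi_true must be strictly positive")


@dataclass
class SyntheticCorpus:
    """Rendered images + feature matrix + all planted ground truth."""

    images: list[RegisteredImage]
    fm: FeatureMatrix  # raw (uncentered) feature matrix, X = Lambda F + E
    truth: GroundTruth
    labels: LabelSet
    gene_sets: dict[str, set[str]]
    grid: GridSpec | None = None


def _ellipse_mask(grid: GridSpec) -> np.ndarray:
    """Elliptical embryo mask filling most of the (n_rows, n_cols) frame."""
    r = (np.arange(grid.n_rows) + 0.5) / grid.n_rows - 0.5
    c = (np.arange(grid.n_cols) + 0.5) / grid.n_cols - 0.5
    rr, cc = np.meshgrid(r, c, indexing="ij")
    return (rr / 0.45) ** 2 + (cc / 0.47) ** 2 <= 1.0


def make_spatial_templates(grid: GridSpec, kinds: list[str] | None = None) -> np.ndarray:
    """Prototypical lateral-view expression templates, one unit-norm row each.

    anterior/posterior: cap at the left/right end of the embryo ellipse
    (the leading 35% of the long axis, so the two caps and the full-mask
    shape factor stay linearly independent);
    dorsal_band/ventral_band: top/bottom strip inside the ellipse;
    ap_stripes: pair-rule-like periodic stripes along the long axis;
    shape_artifact: the ellipse mask itself (a non-expression factor that
    soaks up embryo-shape variation).
    """
    if grid.n_rows < 4 or grid.n_cols < 4:
        raise ValueError("grid must be at least 4 x 4 for templates")
    kinds = list(kinds) if kinds is not None else DEFAULT_TEMPLATE_KINDS
    mask = _ellipse_mask(grid)
    rows_idx = np.arange(grid.n_rows)[:, None]
    cols_idx = np.arange(grid.n_cols)[None, :]
    templates = []
    for kind in kinds:
        if kind == "anterior":
            t = (mask & (cols_idx < 0.35 * grid.n_cols)).astype(float)
        elif kind == "posterior":
            t = (mask & (cols_idx >= 0.65 * grid.n_cols)).astype(float)
        elif kind == "dorsal_band":
            t = (mask & (rows_idx < grid.n_rows / 3)).astype(float)
        elif kind == "ventral_band":
            t = (mask & (rows_idx >= 2 * grid.n_rows / 3)).astype(float)
        elif kind == "ap_stripes":
            phase = np.sin(2.0 * np.pi * 7.0 * (cols_idx + 0.5) / grid.n_cols)
            t = mask * np.clip(np.broadcast_to(phase, mask.shape), 0.0, None)
        elif kind == "shape_artifact":
            t = mask.astype(float)
        else:
            raise ValueError(f"unknown template kind {kind!r}")
        v = t.ravel()
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"template {kind!r} is empty on this grid")
        templates.append(v / norm)
    return np.stack(templates)


def sample_sparse_loadings(
    n_images: int,
    K: int,
    sparsity: float = 0.8,
    scale: float = 1.0,
    rng_seed: int = 0,
    positive: bool = False,
) -> np.ndarray:
    """Spike-and-slab loadings: each entry is exactly 0 with probability
    ``sparsity``, otherwise Normal(0, scale^2).

    With ``positive`` the nonzero entries are folded to |Normal(0,
    scale^2)| (half-normal) — staining is additive, so an expression
    pattern mixes its spatial domains with non-negative weights.
    """
    if not (0.0 <= sparsity < 1.0):
        raise ValueError("sparsity must be in [0, 1)")
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(rng_seed)
    mask = rng.random((n_images, K)) >= sparsity
    values = rng.normal(0.0, scale, size=(n_images, K))
    if positive:
        values = np.abs(values)
    return np.where(mask, values, 0.0)


def psi_from_snr(Lambda: np.ndarray, F: np.ndarray, snr: float, P: int) -> np.ndarray:
    """Noise precisions giving var(Lambda F) * psi = snr (uniform over features)."""
    signal_var = float(np.var(Lambda @ F))
    if signal_var == 0:
        raise ValueError("zero signal variance; cannot set noise from SNR")
    return np.full(P, snr / signal_var)


def make_ground_truth(
    n_genes: int = 100,
    images_per_gene: int = 2,
    grid: GridSpec = GridSpec(n_cols=40, n_rows=20),
    kinds: list[str] | None = None,
    sparsity: float = 0.8,
    snr: float = 10.0,
    loading_scale: float = 1.0,
    rng_seed: int = 0,
    frac_noninformative: float = 0.0,
    ensure_signal_rows: bool = True,
    positive_loadings: bool = True,
) -> GroundTruth:
    """Build the full ground truth for a corpus.

    Gene-level loadings are sampled once per gene and replicated across
    the gene's images.  Nonzero loadings are half-normal by default
    (additive staining mixes domains with non-negative weights), which
    also makes labels planted by a loading threshold linearly learnable.  With ``ensure_signal_rows`` a gene whose sampled
    row is entirely zero gets one entry redrawn, so "signal" genes are
    guaranteed a nonzero pattern.  ``frac_noninformative`` turns that
    fraction of genes into planted non-informative genes (all-zero
    loading rows — pure-noise images mimicking ubiquitous/maternal
    staining); they are drawn deterministically as the last genes.
    """
    F = make_spatial_templates(grid, kinds)
    K = F.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 17]))
    lam_gene = sample_sparse_loadings(n_genes, K, sparsity, loading_scale, rng_seed, positive=positive_loadings)
    if ensure_signal_rows:
        for g in range(n_genes):
            if not lam_gene[g].any():
                k = int(rng.integers(K))
                v = rng.normal(0.0, loading_scale)
                lam_gene[g, k] = abs(v) if positive_loadings else v
    n_noise = int(round(frac_noninformative * n_genes))
    if n_noise:
        lam_gene[n_genes - n_noise :, :] = 0.0
    Lambda = np.repeat(lam_gene, images_per_gene, axis=0)
    gene_ids = [f"g{g:04d}" for g in range(n_genes)]
    gene_of_row = [g for g in gene_ids for _ in range(images_per_gene)]
    psi = psi_from_snr(Lambda, F, snr, F.shape[1])
    return GroundTruth(
        Lambda_true=Lambda,
        F_true=F,
        psi_true=psi,
        sparsity=float(np.mean(Lambda == 0.0)),
        seed=rng_seed,
        gene_of_row=gene_of_row,
    )


def render_corpus(truth: GroundTruth, grid: GridSpec, rng_seed: int) -> SyntheticCorpus:
    """Realize X = Lambda F + E and fold the rows back into raster images.

    E[n, p] ~ Normal(0, 1 / psi_true[p]).  The feature matrix keeps the
    unmapped values; the raster images are the same rows affinely mapped
    to [0, 1] with one map shared by the whole corpus, preserving relative
    intensities.  Labels and gene sets are left empty here; use
    :func:`derive_labels` / :func:`plant_gene_sets` or
    :func:`make_default_corpus`.
    """
    N, K = truth.Lambda_true.shape
    if truth.F_true.shape != (K, grid.n_features):
        raise ValueError(
            f"factor matrix shape {truth.F_true.shape} inconsistent with K={K}, P={grid.n_features}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 29]))
    signal = truth.Lambda_true @ truth.F_true
    noise_sd = 1.0 / np.sqrt(truth.psi_true)
    X = signal + rng.standard_normal((N, grid.n_features)) * noise_sd[None, :]

    lo, hi = float(X.min()), float(X.max())
    span = hi - lo if hi > lo else 1.0
    gene_of_row = truth.gene_of_row or [f"g{n:04d}" for n in range(N)]
    counters: dict[str, int] = {}
    images = []
    row_meta = []
    for n in range(N):
        g = gene_of_row[n]
        idx = counters.get(g, 0)
        counters[g] = idx + 1
        image_id = f"{g}_im{idx}"
        pixels = ((X[n] - lo) / span).reshape(grid.n_rows, grid.n_cols)
        images.append(RegisteredImage(image_id=image_id, gene_id=g, pixels=pixels))
        row_meta.append((image_id, g))
    fm = FeatureMatrix(X=X, row_meta=row_meta, grid=grid, centered=False)
    labels = LabelSet(
        gene_terms={g: set() for g in dict.fromkeys(gene_of_row)},
        image_gene={m[0]: m[1] for m in row_meta},
    )
    return SyntheticCorpus(images=images, fm=fm, truth=truth, labels=labels, gene_sets={}, grid=grid)


def derive_labels(truth: GroundTruth, term_rules: dict[str, tuple[int, float]]) -> LabelSet:
    """Plant annotation terms from the true loadings.

    ``term_rules`` maps a term name to (factor index k, threshold t): gene
    g carries the term iff |Lambda_true[g, k]| > t, and every image of the
    gene inherits it.
    """
    K = truth.Lambda_true.shape[1]
    for term, (k, _) in term_rules.items():
        if not (0 <= k < K):
            raise ValueError(f"term {term!r}: factor index {k} out of range (K={K})")
    gene_of_row = truth.gene_of_row
    gene_ids = list(dict.fromkeys(gene_of_row))
    first_row = {g: gene_of_row.index(g) for g in gene_ids}
    gene_terms: dict[str, set[str]] = {g: set() for g in gene_ids}
    for term, (k, t) in term_rules.items():
        for g in gene_ids:
            if abs(truth.Lambda_true[first_row[g], k]) > t:
                gene_terms[g].add(term)
    counters: dict[str, int] = {}
    image_gene = {}
    for g in gene_of_row:
        idx = counters.get(g, 0)
        counters[g] = idx + 1
        image_gene[f"{g}_im{idx}"] = g
    return LabelSet(gene_terms=gene_terms, image_gene=image_gene)


def plant_gene_sets(
    truth: GroundTruth,
    per_factor_overlap: float = 0.8,
    background_size: int = 10,
    top_q: int = 15,
    rng_seed: int = 0,
) -> dict[str, set[str]]:
    """One enriched gene set per factor: a fraction of the factor's
    top-|loading| genes plus random background genes."""
    if not (0.0 < per_factor_overlap <= 1.0):
        raise ValueError("per_factor_overlap must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 41]))
    gene_ids = list(dict.fromkeys(truth.gene_of_row))
    first_row = {g: truth.gene_of_row.index(g) for g in gene_ids}
    lam_gene = np.stack([truth.Lambda_true[first_row[g]] for g in gene_ids])
    K = lam_gene.shape[1]
    sets: dict[str, set[str]] = {}
    for k in range(K):
        order = sorted(range(len(gene_ids)), key=lambda i: (-abs(lam_gene[i, k]), gene_ids[i]))
        top = [gene_ids[i] for i in order[:top_q]]
        n_take = max(1, int(round(per_factor_overlap * len(top))))
        chosen = set(rng.choice(top, size=n_take, replace=False))
        pool = sorted(set(gene_ids) - chosen)
        if background_size and pool:
            chosen |= set(rng.choice(pool, size=min(background_size, len(pool)), replace=False))
        sets[f"set_factor{k}"] = chosen
    return sets


def make_default_corpus(
    rng_seed: int = 0,
    n_genes: int = 100,
    images_per_gene: int = 2,
    grid: GridSpec = GridSpec(n_cols=40, n_rows=20),
    sparsity: float = 0.8,
    snr: float = 10.0,
    frac_noninformative: float = 0.0,
    label_factor: int = 0,
    label_threshold: float = 0.0,
) -> SyntheticCorpus:
    """The study-conditions corpus: labels planted from |loading| on one
    factor, one enriched gene set per factor."""
    truth = make_ground_truth(
        n_genes=n_genes,
        images_per_gene=images_per_gene,
        grid=grid,
        sparsity=sparsity,
        snr=snr,
        rng_seed=rng_seed,
        frac_noninformative=frac_noninformative,
    )
    corpus = render_corpus(truth, grid, rng_seed)
    corpus.labels = derive_labels(truth, {f"term_factor{label_factor}": (label_factor, label_threshold)})
    corpus.gene_sets = plant_gene_sets(truth, rng_seed=rng_seed)
    return corpus


# --------------------------------------------------------------------------
# serialization


def write_gmt(gene_sets: dict[str, set[str]], path: str | os.PathLike, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def save_corpus(corpus: SyntheticCorpus, out_dir: str | os.PathLike) -> None:
    """Write PNG images, X.tsv, truth arrays, labels.tsv and sets.gmt."""
    from .imaging_features import save_feature_matrix

    os.makedirs(out_dir, exist_ok=True)
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    meta_rows = []
    for im in corpus.images:
        fname = f"{im.image_id}.png"
        iio.imwrite(os.path.join(img_dir, fname), (im.pixels * 255).round().astype(np.uint8))
        meta_rows.append((im.image_id, im.gene_id, fname, im.orientation_tag))
    pd.DataFrame(meta_rows, columns=["image_id", "gene_id", "file", "orientation"]).to_csv(
        os.path.join(out_dir, "meta.tsv"), sep="\t", index=False
    )
    save_feature_matrix(corpus.fm, os.path.join(out_dir, "X.tsv"))
    np.savetxt(os.path.join(out_dir, "Lambda_true.tsv"), corpus.truth.Lambda_true, delimiter="\t")
    np.savetxt(os.path.join(out_dir, "F_true.tsv"), corpus.truth.F_true, delimiter="\t")
    np.savetxt(os.path.join(out_dir, "psi_true.tsv"), corpus.truth.psi_true, delimiter="\t")
    corpus.labels.to_tsv(os.path.join(out_dir, "labels.tsv"))
    write_gmt(corpus.gene_sets, os.path.join(out_dir, "sets.gmt"))
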