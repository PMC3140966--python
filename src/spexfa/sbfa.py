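"""Sparse Bayesian factor analysis (sBFA) by Gibbs sampling.

Model
-----
The centered feature matrix is decomposed as

    X = Lambda F + E,          X: N x P,  Lambda: N x K,  F: K x P

where each row of F is a *factor* (an image-shaped spatial template),
each entry of F has a standard-normal prior, and E is additive Gaussian
noise with per-feature precision psi_p ~ Gamma(c, rate d).  Sparseness of
the loadings (mixing weights) lambda_nk comes from a Student-t prior in
Gamma-hierarchy form:

    lambda_nk | alpha_nk ~ Normal(0, 1 / alpha_nk)
    alpha_nk            ~ Gamma(a, rate b)

Marginalizing alpha_nk gives a heavy-tailed Student-t density on each
loading, which shrinks most of them toward zero (automatic relevance
determination) while letting a few stay large — the biological assumption
that each expression pattern uses only a few spatial domains.

Inference cycles through the four exact conditionals (F, Lambda, alpha,
psi).  All four are conjugate:

* columns of F:   Normal(mu_p, Sigma_p), Sigma_p = (I_K + psi_p L'L)^-1,
                  mu_p = psi_p Sigma_p L' x_p
* rows of Lambda: Normal(mu_n, Sigma_n),
                  Sigma_n = (diag(alpha_n) + F Psi F')^-1,
                  mu_n = Sigma_n F Psi x_n
* alpha_nk:       Gamma(a + 1/2, rate b + lambda_nk^2 / 2)
* psi_p:          Gamma(c + N/2, rate d + RSS_p / 2)

Gamma distributions are parameterized by shape and *rate* throughout
(scale = 1 / rate); the conjugate updates are additive in that form.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging_features import FeatureMatrix, GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "SBFAHyperParams",
    "SBFAState",
    "PosteriorSummary",
    "init_state",
    "sample_factor_columns",
    "sample_loading_rows",
    "sample_loading_precisions",
    "sample_noise_precisions",
    "run_gibbs",
    "reconstruct",
    "align_factors",
    "save_summary",
    "load_summary",
]


@dataclass(frozen=True)
class SBFAHyperParams:
    """Number of factors and the two Gamma priors (shape-rate form).

    a, b govern the loading precisions alpha_nk (the Student-t shrinkage);
    c, d govern the noise precisions psi_p.  The marginal prior on a
    loading behaves like 1/|lambda| only for |lambda| >> sqrt(2 b), so b
    sets the scale below which loadings are indistinguishable from zero;
    the default b = 1e-6 keeps that spike two orders of magnitude below
    the O(1) loading scale of standardized data, which is what pins the
    factor rotation to the sparse axes.
    """

    K: int = 20
    a: float = 1e-3
    b: float = 1e-6
    c: float = 1e-3
    d: float = 1e-3
    scalar_psi: bool = False

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be strictly positive")


@dataclass
class SBFAState:
    """Current Gibbs state: loadings, factors, and both precision sets."""

    Lambda: np.ndarray  # N x K
    F: np.ndarray  # K x P
    alpha: np.ndarray  # N x K, loading precisions
    psi: np.ndarray  # P, noise precisions

    def validate(self) -> None:
        if not (np.all(np.isfinite(self.Lambda)) and np.all(np.isfinite(self.F))):
            raise FloatingPointError("non-finite entries in Lambda or F")
        if np.any(self.alpha <= 0) or np.any(self.psi <= 0):
            raise ValueError("precisions must be strictly positive")


@dataclass
class PosteriorSummary:
    """Post-burn-in means of Lambda and F plus run metadata."""

    Lambda_mean: np.ndarray
    F_mean: np.ndarray
    n_iterations: int
    burn_in: int
    seed: int
    trace: np.ndarray  # reconstruction MSE per iteration
    row_meta: list[tuple[str, str]] = field(default_factory=list)
    grid: GridSpec | None = None
    hyperparams: SBFAHyperParams | None = None


def init_state(fm: FeatureMatrix, hp: SBFAHyperParams, rng_seed: int) -> SBFAState:
    """Draw the initial state: F ~ N(0,1), Lambda ~ N(0, 0.01), precisions at prior means."""
    if not fm.centered:
        raise ValueError("feature matrix must be centered before fitting")
    rng = np.random.default_rng(rng_seed)
    N, P = fm.X.shape
    K = hp.K
    F = rng.standard_normal((K, P))
    Lambda = rng.normal(0.0, 0.1, size=(N, K))  # variance 0.01
    alpha = np.full((N, K), hp.a / hp.b)
    psi = np.full(P, hp.c / hp.d)
    return SBFAState(Lambda=Lambda, F=F, alpha=alpha, psi=psi)


def init_state_svd(fm: FeatureMatrix, hp: SBFAHyperParams) -> SBFAState:
    """Deterministic initialization at the varimax-rotated truncated SVD.

    The sparse factor posterior is multimodal: rotations of the factor
    basis are separated by low-density barriers, and a randomly
    initialized chain can settle in a rotated mode.  Varimax rotates the
    leading-K SVD loadings toward maximal sparsity, which places the
    chain in the basin of the sparse mode the Student-t prior favors; the
    sampler then refines loadings, factors and precisions jointly.
    Precisions start at their prior means, as in :func:`init_state`.
    """
    if not fm.centered:
        raise ValueError("feature matrix must be centered before fitting")
    from statsmodels.multivariate.factor_rotation import rotate_factors

    N, P = fm.X.shape
    K = hp.K
    U, S, Vt = np.linalg.svd(fm.X, full_matrices=False)
    K_eff = min(K, S.size)
    L0 = U[:, :K_eff] * S[:K_eff]
    F0 = Vt[:K_eff]
    if K_eff > 1:
        L0, R = rotate_factors(L0, "varimax")
        F0 = R.T @ F0
    Lambda = np.zeros((N, K))
    F = np.zeros((K, P))
    Lambda[:, :K_eff] = L0
    F[:K_eff] = F0
    # split the scale so F rows start near the unit-variance prior scale
    row_norm = np.linalg.norm(F, axis=1, keepdims=True)
    scale = np.where(row_norm > 0, row_norm / np.sqrt(P), 1.0)
    F = F / scale
    Lambda = Lambda * scale.T
    alpha = np.full((N, K), hp.a / hp.b)
    psi = np.full(P, hp.c / hp.d)
    return SBFAState(Lambda=Lambda, F=F, alpha=alpha, psi=psi)


def sample_factor_columns(state: SBFAState, fm: FeatureMatrix, rng: np.random.Generator) -> np.ndarray:
    """Draw every column f_p of F from its Gaussian conditional.

    Sigma_p = (I_K + psi_p Lambda' Lambda)^-1 and
    mu_p = psi_p Sigma_p Lambda' x_p.  Because only the scalar psi_p varies
    with p, one symmetric eigendecomposition Lambda'Lambda = Q diag(s) Q'
    diagonalizes every Sigma_p simultaneously, so all P columns are drawn
    in a single vectorized pass: with t_p = 1 + psi_p s,
    Sigma_p = Q diag(1/t_p) Q' and Sigma_p^{1/2} = Q diag(t_p^{-1/2}).
    """
    Lam, psi, X = state.Lambda, state.psi, fm.X
    K = Lam.shape[1]
    G = Lam.T @ Lam  # K x K, PSD
    s, Q = np.linalg.eigh(G)
    s = np.clip(s, 0.0, None)
    t = 1.0 + s[:, None] * psi[None, :]  # K x P
    B = Q.T @ (Lam.T @ X)  # K x P, rotated information vectors
    mu = Q @ ((psi[None, :] * B) / t)
    z = rng.standard_normal((K, X.shape[1]))
    F_new = mu + Q @ (z / np.sqrt(t))
    state.F = F_new
    return F_new


def _batched_chol_sample(prec: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw x_i ~ N(prec_i^-1 b_i, prec_i^-1) for a batch of KxK precisions.

    Uses the Cholesky factor of each precision matrix; on factorization
    failure a 1e-10 jitter is added to the diagonal (logged).
    """
    try:
        L = np.linalg.cholesky(prec)
    except np.linalg.LinAlgError:
        logger.warning("Cholesky failed; adding 1e-10 jitter to precision diagonals")
        K = prec.shape[-1]
        L = np.linalg.cholesky(prec + 1e-10 * np.eye(K))
    # mean: prec mu = b  =>  solve L (L' mu) = b by two triangular solves
    y = np.linalg.solve(L, b[..., None])
    mu = np.linalg.solve(np.transpose(L, (0, 2, 1)), y)[..., 0]
    z = rng.standard_normal(mu.shape)
    dev = np.linalg.solve(np.transpose(L, (0, 2, 1)), z[..., None])[..., 0]
    return mu + dev


def sample_loading_rows(state: SBFAState, fm: FeatureMatrix, rng: np.random.Generator) -> np.ndarray:
    """Draw every row lambda_n of Lambda from its Gaussian conditional.

    Sigma_n = (diag(alpha_n) + F Psi F')^-1, mu_n = Sigma_n F Psi x_n; the
    shared K x K term F Psi F' is formed once and the N rows are sampled by
    batched Cholesky factorizations.
    """
    F, psi, alpha, X = state.F, state.psi, state.alpha, fm.X
    N, K = alpha.shape
    FPsi = F * psi[None, :]
    G = FPsi @ F.T  # K x K
    B = X @ FPsi.T  # N x K information vectors
    prec = G[None, :, :] + alpha[:, None, :] * np.eye(K)[None, :, :]
    Lam_new = _batched_chol_sample(prec, B, rng)
    state.Lambda = Lam_new
    return Lam_new


def sample_loading_precisions(state: SBFAState, hp: SBFAHyperParams, rng: np.random.Generator) -> np.ndarray:
    """alpha_nk ~ Gamma(a + 1/2, rate b + lambda_nk^2 / 2), entrywise."""
    shape = hp.a + 0.5
    rate = hp.b + 0.5 * state.Lambda**2
    alpha_new = rng.gamma(shape, 1.0 / rate)
    alpha_new = np.maximum(alpha_new, np.finfo(float).tiny)
    state.alpha = alpha_new
    return alpha_new


def sample_noise_precisions(
    state: SBFAState, fm: FeatureMatrix, hp: SBFAHyperParams, rng: np.random.Generator
) -> np.ndarray:
    """psi_p ~ Gamma(c + N/2, rate d + RSS_p / 2) with RSS_p the residual
    sum of squares of feature column p; with ``scalar_psi`` a single
    precision is drawn from the pooled residual."""
    resid = fm.X - state.Lambda @ state.F
    N, P = resid.shape
    if hp.scalar_psi:
        rss = float(np.sum(resid**2))
        psi_val = rng.gamma(hp.c + N * P / 2.0, 1.0 / (hp.d + 0.5 * rss))
        psi_new = np.full(P, max(psi_val, np.finfo(float).tiny))
    else:
        rss = np.sum(resid**2, axis=0)
        psi_new = rng.gamma(hp.c + N / 2.0, 1.0 / (hp.d + 0.5 * rss))
        psi_new = np.maximum(psi_new, np.finfo(float).tiny)
    state.psi = psi_new
    return psi_new


def run_gibbs(
    fm: FeatureMatrix,
    hp: SBFAHyperParams,
    n_iter: int = 1000,
    burn_in: int = 300,
    rng_seed: int = 0,
    standardize: bool = True,
    init: str = "svd",
) -> PosteriorSummary:
    """Run the Gibbs sampler and return post-burn-in means of Lambda and F.

    Each sweep updates F, Lambda, alpha, psi in that fixed order.  The
    trace records the reconstruction MSE ||X - Lambda F||^2 / (N P) after
    every sweep (on the original data scale).  Fully reproducible from
    ``rng_seed``.

    With ``standardize`` (the default) X is divided by its global
    standard deviation before sampling and the loadings are mapped back
    afterwards.  The Gamma hyperparameters fix an absolute scale
    (loadings below ~sqrt(2 b) are invisible to the Student-t spike), so
    fitting on unit-variance data makes the defaults meaningful for any
    input scale; the factors F are unaffected.

    ``init`` is ``"svd"`` (deterministic varimax-rotated SVD, the
    default — see :func:`init_state_svd`) or ``"random"`` (random
    restart per :func:`init_state`, useful for mixing diagnostics).
    """
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    s = float(fm.X.std()) if standardize else 1.0
    if s == 0.0:
        raise ValueError("feature matrix is constant; nothing to fit")
    work = FeatureMatrix(X=fm.X / s, row_meta=list(fm.row_meta), grid=fm.grid, centered=fm.centered)
    if init == "svd":
        state = init_state_svd(work, hp)
    elif init == "random":
        state = init_state(work, hp, rng_seed)
    else:
        raise ValueError(f"unknown init {init!r}")
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 1]))
    trace = np.empty(n_iter)
    Lambda_sum = np.zeros_like(state.Lambda)
    F_sum = np.zeros_like(state.F)
    for it in range(n_iter):
        sample_factor_columns(state, work, rng)
        sample_loading_rows(state, work, rng)
        sample_loading_precisions(state, hp, rng)
        sample_noise_precisions(state, work, hp, rng)
        resid = work.X - state.Lambda @ state.F
        mse = float(np.mean(resid**2)) * s * s
        if not np.isfinite(mse):
            raise FloatingPointError(f"Gibbs sampler diverged at iteration {it}")
        trace[it] = mse
        if it >= burn_in:
            Lambda_sum += state.Lambda
            F_sum += state.F
    n_kept = n_iter - burn_in
    return PosteriorSummary(
        Lambda_mean=Lambda_sum * (s / n_kept),
        F_mean=F_sum / n_kept,
        n_iterations=n_iter,
        burn_in=burn_in,
        seed=rng_seed,
        trace=trace,
        row_meta=list(fm.row_meta),
        grid=fm.grid,
        hyperparams=hp,
    )


def reconstruct(summary: PosteriorSummary) -> np.ndarray:
    """Posterior-mean reconstruction Lambda_mean @ F_mean (N x P)."""
    return summary.Lambda_mean @ summary.F_mean


def align_factors(estimated: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match estimated factor rows to reference rows up to sign and order.

    Factor models are identified only up to permutation and sign of the
    factors.  Greedy one-to-one matching maximizes |Pearson correlation|
    between rows; the sign makes each matched correlation positive.

    Returns ``(perm, signs, corrs)`` where ``estimated[perm[j]] * signs[j]``
    is the best match for ``reference[j]`` and ``corrs[j]`` is the signed
    correlation after flipping (so non-negative except for zero-variance
    rows, which match with correlation 0).
    """
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("estimated and reference must have equal shapes")
    K = est.shape[0]
    est_c = est - est.mean(axis=1, keepdims=True)
    ref_c = ref - ref.mean(axis=1, keepdims=True)
    est_n = np.linalg.norm(est_c, axis=1)
    ref_n = np.linalg.norm(ref_c, axis=1)
    denom = np.outer(ref_n, est_n)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (ref_c @ est_c.T) / denom
    C = np.where(denom > 0, C, 0.0)  # zero-variance rows: correlation 0
    if np.any(denom == 0):
        logger.warning("zero-variance factor row(s); matched with correlation 0")

    perm = np.full(K, -1, dtype=int)
    signs = np.ones(K)
    corrs = np.zeros(K)
    absC = np.abs(C)
    remaining_ref = set(range(K))
    remaining_est = set(range(K))
    for _ in range(K):
        best = max(
            ((absC[j, k], j, k) for j in remaining_ref for k in remaining_est),
            key=lambda t: t[0],
        )
        _, j, k = best
        perm[j] = k
        corrs[j] = absC[j, k]
        signs[j] = 1.0 if C[j, k] >= 0 else -1.0
        remaining_ref.remove(j)
        remaining_est.remove(k)
    return perm, signs, corrs


# --- persistence ----------------------------------------------------------

def save_summary(summary: PosteriorSummary, out_dir: str | os.PathLike) -> None:
    """Write Lambda_mean.tsv, F_mean.tsv, trace.tsv and a JSON run manifest."""
    os.makedirs(out_dir, exist_ok=True)
    K = summary.F_mean.shape[0]
    lam = pd.DataFrame(summary.Lambda_mean, columns=[f"factor_{k}" for k in range(K)])
    if summary.row_meta:
        lam.insert(0, "image_id", [m[0] for m in summary.row_meta])
        lam.insert(1, "gene_id", [m[1] for m in summary.row_meta])
    lam.to_csv(os.path.join(out_dir, "Lambda_mean.tsv"), sep="\t", index=False, float_format="%.10g")
    fmat = pd.DataFrame(summary.F_mean)
    fmat.insert(0, "factor_id", [f"factor_{k}" for k in range(K)])
    fmat.to_csv(os.path.join(out_dir, "F_mean.tsv"), sep="\t", index=False, float_format="%.10g")
    pd.DataFrame({"iteration": np.arange(summary.n_iterations), "mse": summary.trace}).to_csv(
        os.path.join(out_dir, "trace.tsv"), sep="\t", index=False
    )
    hp = summary.hyperparams
    manifest = {
        "n_iterations": summary.n_iterations,
        "burn_in": summary.burn_in,
        "seed": summary.seed,
        "K": K,
        "hyperparams": None
        if hp is None
        else {"a": hp.a, "b": hp.b, "c": hp.c, "d": hp.d, "scalar_psi": hp.scalar_psi},
        "grid": None if summary.grid is None else {"n_rows": summary.grid.n_rows, "n_cols": summary.grid.n_cols},
        "factor_stacking": "row-major",
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_summary(out_dir: str | os.PathLike) -> PosteriorSummary:
    with open(os.path.join(out_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    lam = pd.read_csv(os.path.join(out_dir, "Lambda_mean.tsv"), sep="\t")
    row_meta: list[tuple[str, str]] = []
    if "image_id" in lam.columns:
        row_meta = list(zip(lam.pop("image_id").astype(str), lam.pop("gene_id").astype(str)))
    fmat = pd.read_csv(os.path.join(out_dir, "F_mean.tsv"), sep="\t").drop(columns=["factor_id"])
    trace = pd.read_csv(os.path.join(out_dir, "trace.tsv"), sep="\t")["mse"].to_numpy()
    hp = manifest.get("hyperparams")
    grid = manifest.get("grid")
    return PosteriorSummary(
        Lambda_mean=lam.to_numpy(dtype=float),
        F_mean=fmat.to_numpy(dtype=float),
        n_iterations=manifest["n_iterations"],
        burn_in=manifest["burn_in"],
        seed=manifest["seed"],
        trace=trace,
        row_meta=row_meta,
        grid=None if grid is None else GridSpec(n_cols=grid["n_cols"], n_rows=grid["n_rows"]),
        hyperparams=None if hp is None else SBFAHyperParams(K=manifest["K"], **hp),
    )
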