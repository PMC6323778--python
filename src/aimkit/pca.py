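"""Genotype normalization, PCA and SNP weights (EIGENSTRAT conventions).

The genotype matrix is column-standardized: x_ij = (g_ij - mu_j) /
sqrt(p_j (1 - p_j)) with p_j = mu_j / 2, missing entries mean-imputed to
zero after centering. PCA is an exact decomposition of the normalized
matrix; sample scores are left singular vectors scaled by singular values
and eigenvalue_k = s_k^2 / n_variants. SNP weights are the
score-projections of each normalized variant column, scaled by the sample
count and sqrt(eigenvalue) — a correlation-like quantity whose ranks (all
the selection logic uses) are invariant to the overall scale.

For small matrices the SVD is computed directly; for tall-skinny inputs
(many more variants than samples) the same factorization is obtained from
the eigendecomposition of the n x n Gram matrix, which is algebraically
identical and far cheaper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .genodata import CohortDataset

__all__ = [
    "MonomorphicError",
    "PCAResult",
    "normalize_genotypes",
    "compute_pca",
    "compute_snp_weights",
    "pca_cohort",
    "ancestry_index",
]


class MonomorphicError(ValueError):
    """A variant column carries no variation and cannot be normalized."""


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending, >= 0
    scores: np.ndarray  # individuals x components
    snp_weights: np.ndarray  # variants x components
    freq_used: np.ndarray  # normalization frequencies p_j
    n_components: int

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if (np.diff(ev) > 1e-9 * max(1.0, ev.max(initial=0.0))).any():
            raise ValueError("eigenvalues must be sorted descending")
        if (ev < -1e-12).any():
            raise ValueError("eigenvalues must be non-negative")


def normalize_genotypes(
    cohort: CohortDataset, bayesian_freq: bool = False
) -> np.ndarray:
    """Standardize dosages per variant; mean-impute missing entries to zero.

    ``bayesian_freq`` switches the variance denominator to the posterior
    frequency (1 + sum g) / (2 + 2n) instead of p = mu/2; off by default
    since rank-based selection is invariant to this choice.
    """
    geno = cohort.genotypes
    n_obs = np.sum(~np.isnan(geno), axis=0)
    if (n_obs == 0).any():
        bad = cohort.variant_ids[n_obs == 0]
        raise MonomorphicError(f"variant(s) with no calls: {list(bad)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(geno, axis=0)
        col_var = np.nanvar(geno, axis=0)
    p = mu / 2.0
    mono = (p <= 0.0) | (p >= 1.0) | (col_var == 0.0)
    if mono.any():
        bad = cohort.variant_ids[mono]
        raise MonomorphicError(f"monomorphic variant(s): {list(bad)}")
    if bayesian_freq:
        n_eff = n_obs
        p_var = (1.0 + np.nansum(geno, axis=0)) / (2.0 + 2.0 * n_eff)
    else:
        p_var = p
    x = (geno - mu) / np.sqrt(p_var * (1.0 - p_var))
    x[np.isnan(x)] = 0.0
    return x


def _sign_fix(scores: np.ndarray, weights: np.ndarray) -> None:
    """Flip each component so the largest-|score| entry is positive (in place)."""
    for k in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, k])))
        if scores[i, k] < 0:
            scores[:, k] *= -1.0
            weights[:, k] *= -1.0


def compute_pca(
    normalized: np.ndarray,
    n_components: int,
    freq_used: np.ndarray | None = None,
) -> PCAResult:
    """Exact PCA of the normalized matrix.

    scores = U s (samples in PC space); eigenvalue_k = s_k^2 / n_variants;
    deterministic up to per-component sign, which is fixed so the
    largest-|entry| score of each component is positive. Rank-deficient
    inputs are truncated to their numerical rank with a warning.
    """
    x = np.asarray(normalized, dtype=float)
    n, m = x.shape
    # columns are centered, so the rank is at most min(n - 1, m)
    if n_components > min(n - 1, m):
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, m)={min(n - 1, m)}"
        )
    # tall-skinny: the n x n Gram eigendecomposition gives the same factors
    if m > 4 * n and n * m > 4_000_000:
        gram = x @ x.T
        evals, u = scipy.linalg.eigh(gram)
        order = np.argsort(evals)[::-1]
        evals = np.maximum(evals[order], 0.0)
        s = np.sqrt(evals)
        u = u[:, order]
    else:
        u, s, _ = np.linalg.svd(x, full_matrices=False)

    tol = s[0] * max(n, m) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    k = n_components
    if rank < n_components:
        warnings.warn(
            f"rank-deficient input: truncating to {rank} component(s)"
        )
        k = rank
    u = u[:, :k]
    s = s[:k]
    scores = u * s
    eigenvalues = s**2 / m
    weights = _weights_from_scores(x, scores, eigenvalues)
    _sign_fix(scores, weights)
    if freq_used is None:
        freq_used = np.full(m, np.nan)
    return PCAResult(
        eigenvalues=eigenvalues,
        scores=scores,
        snp_weights=weights,
        freq_used=np.asarray(freq_used, dtype=float),
        n_components=k,
    )


def _weights_from_scores(
    x: np.ndarray, scores: np.ndarray, eigenvalues: np.ndarray
) -> np.ndarray:
    n = x.shape[0]
    proj = x.T @ scores  # variants x components
    w = np.zeros_like(proj)
    nz = eigenvalues > 0
    if not nz.all():
        warnings.warn("zero-eigenvalue component(s): weights set to zero")
    w[:, nz] = proj[:, nz] / (n * np.sqrt(eigenvalues[nz]))
    return w


def compute_snp_weights(pca: PCAResult, normalized: np.ndarray) -> np.ndarray:
    """Per-variant loadings: w_jk = (x_.j · score_.k) / (n sqrt(eigenvalue_k))."""
    x = np.asarray(normalized, dtype=float)
    if x.shape[0] != pca.scores.shape[0]:
        raise ValueError("normalized matrix and scores have different sample counts")
    return _weights_from_scores(x, pca.scores, pca.eigenvalues)


def pca_cohort(
    cohort: CohortDataset,
    n_components: int = 2,
    drop_monomorphic: bool = False,
) -> PCAResult:
    """Normalize a cohort and run PCA in one step.

    With ``drop_monomorphic`` (used when PCA is rerun inside subsamples,
    where a variant can lose its variation), monomorphic columns are dropped
    and their weight rows returned as zero so variant alignment is kept.
    """
    if not drop_monomorphic:
        x = normalize_genotypes(cohort)
        freq = np.nanmean(cohort.genotypes, axis=0) / 2.0
        return compute_pca(x, n_components, freq_used=freq)
    geno = cohort.genotypes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(geno, axis=0)
        var = np.nanvar(geno, axis=0)
    p = mu / 2.0
    keep = (p > 0) & (p < 1) & (var > 0) & np.isfinite(p)
    sub = cohort.subset_variants(np.flatnonzero(keep))
    x = normalize_genotypes(sub)
    k = max(1, min(n_components, x.shape[0] - 1, x.shape[1]))
    res = compute_pca(x, k, freq_used=p[keep])
    weights = np.zeros((cohort.n_variants, res.n_components))
    weights[np.flatnonzero(keep), :] = res.snp_weights
    freq = np.full(cohort.n_variants, np.nan)
    freq[keep] = res.freq_used
    return PCAResult(
        eigenvalues=res.eigenvalues,
        scores=res.scores,
        snp_weights=weights,
        freq_used=freq,
        n_components=res.n_components,
    )


def ancestry_index(
    cohort: CohortDataset, panel, n_components: int = 2
) -> PCAResult:
    """Recompute PCA on the panel's variants only — the per-panel ancestry index.

    The cohort is subset to the panel's variant ids (an absent variant is an
    error; no silent proxy substitution) and normalization + PCA rerun with
    the same conventions as the genome-wide analysis.
    """
    sub = cohort.subset_by_variant_ids([v.variant_id for v in panel.variants])
    k = max(1, min(n_components, sub.n_samples - 1, sub.n_variants))
    return pca_cohort(sub, n_components=k)
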