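"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a different route than the package
(dense eigendecomposition, exhaustive subset search, grid search, textbook
estimators) so agreement is evidence, not tautology.
"""

from itertools import combinations

import numpy as np


def brute_force_pca(x: np.ndarray):
    """Eigendecomposition of the dense sample 'covariance' X X^T / m.

    Returns (eigenvalues descending, |score| matrix) where scores are
    eigenvectors scaled to u * sqrt(lambda * m), matching an SVD-based PCA
    up to per-component sign.
    """
    n, m = x.shape
    c = x @ x.T / m
    evals, evecs = np.linalg.eigh(c)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    scores_abs = np.abs(evecs * np.sqrt(np.maximum(evals, 0.0) * m))
    return evals, scores_abs


def exhaustive_allocation(
    ranked: dict,
    size: int,
    caps_by_chrom: dict,
    weights: np.ndarray,
    ld_fn,
    ld_r2_max: float,
    require_all: bool = True,
):
    """Best cap-/coverage-/LD-feasible subset maximizing sum |weight|.

    Enumerates every ``size``-subset of the candidate union; only usable on
    toys (<= ~15 candidates).
    """
    chrom_of = {}
    pool = []
    for chrom, idx in ranked.items():
        for i in idx:
            pool.append(i)
            chrom_of[i] = chrom
    best, best_sum = None, -np.inf
    covered_needed = {c for c, idx in ranked.items() if idx} if require_all else set()
    for subset in combinations(sorted(pool), size):
        counts: dict = {}
        for i in subset:
            counts[chrom_of[i]] = counts.get(chrom_of[i], 0) + 1
        if any(counts[c] > caps_by_chrom[c] for c in counts):
            continue
        if require_all and len(covered_needed) <= size:
            if not covered_needed <= set(counts):
                continue
        if any(
            ld_fn(a, b) >= ld_r2_max for a, b in combinations(subset, 2)
        ):
            continue
        s = float(np.sum(np.abs(weights[list(subset)])))
        if s > best_sum:
            best_sum, best = s, set(subset)
    return best, best_sum


def grid_search_ancestry(g: np.ndarray, p: np.ndarray, step: float = 0.001):
    """K=2 supervised-likelihood maximizer by brute grid over q_1.

    ``g`` is one individual's dosage vector (nan = missing), ``p`` the
    2 x J parental frequency matrix. Returns (q1_hat, best loglik).
    """
    obs = ~np.isnan(g)
    g = g[obs]
    p = p[:, obs]
    grid = np.arange(0.0, 1.0 + step / 2, step)
    pi = grid[:, None] * p[0][None, :] + (1 - grid)[:, None] * p[1][None, :]
    pi = np.clip(pi, 1e-12, 1 - 1e-12)
    ll = (g[None, :] * np.log(pi) + (2 - g)[None, :] * np.log1p(-pi)).sum(axis=1)
    j = int(np.argmax(ll))
    return float(grid[j]), float(ll[j])


def hudson_fst(g1: np.ndarray, g2: np.ndarray) -> float:
    """Hudson's Fst estimator (ratio of averages) from two dosage matrices."""
    n1 = g1.shape[0]
    n2 = g2.shape[0]
    p1 = g1.mean(axis=0) / 2.0
    p2 = g2.mean(axis=0) / 2.0
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n1 - 1) - p2 * (1 - p2) / (2 * n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.mean() / den.mean())
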