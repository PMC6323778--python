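"""Supervised global-ancestry estimation from an AIM panel.

Given fixed parental allele frequencies (estimated from labelled reference
samples, e.g. European and Native American reference panels), each
individual's ancestry vector q maximizes the binomial genotype likelihood

    L(q) = sum_j [ g_j log pi_j + (2 - g_j) log(1 - pi_j) ],
    pi_j = sum_k q_k p_kj,

over the simplex. The maximizer is found by EM with the supervised
ADMIXTURE update

    q_k <- q_k * (1 / 2J) * sum_j [ g_j p_kj / pi_j
                                    + (2 - g_j)(1 - p_kj) / (1 - pi_j) ],

which preserves the simplex and never decreases the likelihood. Missing
genotypes simply drop out of the sums. The per-individual problem is
concave for K=2, so uniform initialization suffices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genodata import CohortDataset, SampleRecord, VariantRecord

__all__ = [
    "AncestryEstimate",
    "estimate_parental_freqs",
    "estimate_ancestry",
    "ancestry_recovery_report",
    "read_parental_genotypes",
    "write_parental_genotypes",
]


@dataclass
class AncestryEstimate:
    proportions: np.ndarray  # individuals x populations, rows on the simplex
    loglik: np.ndarray
    n_iter: np.ndarray
    converged: np.ndarray
    population_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        q = np.asarray(self.proportions, dtype=float)
        if (q < -1e-12).any() or not np.allclose(q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("proportion rows must lie on the simplex")
        if not np.isfinite(self.loglik[self.converged]).all():
            raise ValueError("converged rows must have finite log-likelihood")


def estimate_parental_freqs(
    cohort: CohortDataset,
    population_labels: Optional[Sequence[str]] = None,
    pseudocount: bool = True,
) -> tuple[np.ndarray, list]:
    """Per-population counted-allele frequencies from labelled reference samples.

    With the default add-one pseudocount over alleles the estimate is
    (1 + sum g) / (2 + 2n), which keeps frequencies off the 0/1 boundary so
    the ancestry likelihood stays finite. Returns (populations x variants
    matrix, population label list).
    """
    labels = [s.population_label for s in cohort.samples]
    present = [l for l in labels if l is not None]
    if not present:
        raise ValueError("no samples carry a population_label")
    if population_labels is None:
        population_labels = sorted(set(present))
    freqs = np.empty((len(population_labels), cohort.n_variants))
    for k, pop in enumerate(population_labels):
        idx = [i for i, l in enumerate(labels) if l == pop]
        if not idx:
            raise ValueError(f"population {pop!r} has no samples")
        geno = cohort.genotypes[idx, :]
        n_obs = np.sum(~np.isnan(geno), axis=0)
        if (n_obs == 0).any():
            raise ValueError(f"population {pop!r}: variant with no calls")
        total = np.nansum(geno, axis=0)
        if pseudocount:
            freqs[k] = (1.0 + total) / (2.0 + 2.0 * n_obs)
        else:
            freqs[k] = total / (2.0 * n_obs)
    return freqs, list(population_labels)


def estimate_ancestry(
    cohort: CohortDataset,
    parental_freqs: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 1000,
    population_labels: Optional[Sequence[str]] = None,
    return_trace: bool = False,
):
    """Maximum-likelihood ancestry proportions with fixed parental frequencies.

    All individuals are iterated jointly (vectorized EM); an individual
    converges when its log-likelihood gain drops below ``tol``. Convergence
    failures are reported, not raised.
    """
    p = np.asarray(parental_freqs, dtype=float)  # K x J
    if (p <= 0.0).any() or (p >= 1.0).any():
        raise ValueError(
            "parental frequencies must lie strictly in (0, 1); "
            "use the pseudocount estimator"
        )
    k_pop, n_var = p.shape
    if cohort.n_variants != n_var:
        raise ValueError("parental frequency matrix does not match cohort variants")
    if n_var < k_pop:
        raise ValueError("need at least as many panel variants as populations")

    g = cohort.genotypes  # n x J, nan for missing
    obs = ~np.isnan(g)
    g0 = np.nan_to_num(g)
    two_minus = np.where(obs, 2.0 - g0, 0.0)
    g_obs = np.where(obs, g0, 0.0)
    n = cohort.n_samples
    n_terms = obs.sum(axis=1)  # loci observed per individual

    q = np.full((n, k_pop), 1.0 / k_pop)
    loglik = np.full(n, -np.inf)
    n_iter = np.zeros(n, dtype=int)
    active = np.ones(n, dtype=bool)
    # an individual with no observed loci has a flat likelihood: done at once
    loglik[n_terms == 0] = 0.0
    active[n_terms == 0] = False
    trace = []

    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        qa = q[idx]
        pi = qa @ p
        pi = np.clip(pi, 1e-12, 1 - 1e-12)
        ll = (g_obs[idx] * np.log(pi) + two_minus[idx] * np.log1p(-pi)).sum(axis=1)
        gain = ll - loglik[idx]
        loglik[idx] = ll
        n_iter[idx] = it
        if return_trace:
            trace.append(loglik.copy())
        done = gain < tol
        # EM update for the still-active individuals
        move = idx[~done]
        if move.size:
            qa = q[move]
            pi = np.clip(qa @ p, 1e-12, 1 - 1e-12)
            a = g_obs[move] / pi  # n' x J
            b = two_minus[move] / (1.0 - pi)
            upd = qa * ((a @ p.T) + (b @ (1.0 - p).T)) / (
                2.0 * n_terms[move][:, None]
            )
            upd /= upd.sum(axis=1, keepdims=True)
            q[move] = upd
        active[idx[done]] = False

    converged = ~active
    # final log-likelihood for non-converged rows reflects the last iterate
    est = AncestryEstimate(
        proportions=q,
        loglik=loglik,
        n_iter=n_iter,
        converged=converged,
        population_labels=list(population_labels) if population_labels else None,
    )
    if return_trace:
        return est, np.array(trace)
    return est


def ancestry_recovery_report(
    estimate: AncestryEstimate, truth_ancestry: np.ndarray
) -> dict:
    """Recovery diagnostics of q-hat against true ancestry.

    Returns per-population squared Pearson correlation (NA when the truth is
    constant), mean absolute error and bias (mean of q-hat minus truth).
    """
    q_hat = estimate.proportions
    q_true = np.asarray(truth_ancestry, dtype=float)
    if q_hat.shape != q_true.shape:
        raise ValueError("estimate/truth shapes differ")
    out = {"r2": [], "mae": [], "bias": []}
    for k in range(q_true.shape[1]):
        x, y = q_hat[:, k], q_true[:, k]
        if np.std(y) == 0 or np.std(x) == 0:
            out["r2"].append(float("nan"))
        else:
            r = np.corrcoef(x, y)[0, 1]
            out["r2"].append(float(r * r))
        out["mae"].append(float(np.mean(np.abs(x - y))))
        out["bias"].append(float(np.mean(x - y)))
    return out


# ---------------------------------------------------------------------------
# Parental genotype file (variant rows, sample columns, population header)
# ---------------------------------------------------------------------------


def read_parental_genotypes(path: Union[str, Path]) -> CohortDataset:
    """Read a reference parental genotype table.

    Layout: line 1 is ``variant_id`` followed by sample ids; line 2 is
    ``population`` followed by each sample's population label; remaining
    lines are a variant id followed by counted-allele dosages (0/1/2, NA
    missing). Variant metadata beyond the id is not carried by this format;
    placeholder chromosome/position records are created.
    """
    with open(path) as fh:
        header = fh.readline().split()
        pops = fh.readline().split()
    if not header or header[0] != "variant_id" or pops[0] != "population":
        raise ValueError(
            f"{path}: expected 'variant_id' and 'population' header lines"
        )
    sample_ids = header[1:]
    pop_labels = pops[1:]
    if len(pop_labels) != len(sample_ids):
        raise ValueError(f"{path}: population line does not match sample count")
    df = pd.read_csv(
        path, sep=r"\s+", skiprows=2, header=None, na_values=["NA"],
        names=["variant_id"] + sample_ids,
    )
    geno = df[sample_ids].to_numpy(dtype=float).T  # samples x variants
    variants = [
        VariantRecord(str(vid), "1", j + 1, "A", "B")
        for j, vid in enumerate(df["variant_id"])
    ]
    samples = [
        SampleRecord(sample_id=s, population_label=p)
        for s, p in zip(sample_ids, pop_labels)
    ]
    return CohortDataset(genotypes=geno, variants=variants, samples=samples)


def write_parental_genotypes(cohort: CohortDataset, path: Union[str, Path]) -> None:
    """Write the reference parental genotype layout read by
    :func:`read_parental_genotypes`."""
    with open(path, "w") as fh:
        fh.write("variant_id " + " ".join(cohort.sample_ids) + "\n")
        fh.write(
            "population "
            + " ".join(s.population_label or "NA" for s in cohort.samples)
            + "\n"
        )
        for j, v in enumerate(cohort.variants):
            col = cohort.genotypes[:, j]
            vals = " ".join(
                "NA" if np.isnan(x) else str(int(x)) for x in col
            )
            fh.write(f"{v.variant_id} {vals}\n")
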