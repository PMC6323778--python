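"""Association testing with PC covariates and genomic-control diagnostics.

Per-variant models are additive in the counted-allele dosage: logistic
regression (Newton/IRLS) for case-control phenotypes, ordinary least
squares for quantitative traits, each with optional covariates and
principal-component scores as stratification adjustments. Tests are Wald:
chi2 = (beta/se)^2 against chi-square with 1 df.

The genomic inflation factor is the classic genomic-control statistic
lambda = median(chi2) / 0.4549364231 (the chi2_1 median); lambda ≈ 1 means
the test statistics are calibrated, lambda >> 1 flags uncorrected
stratification. QQ data uses plotting positions (i - 0.5)/n and P values
unadjusted for lambda.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .genodata import CohortDataset

__all__ = [
    "CHI2_1_MEDIAN",
    "AssocResult",
    "LambdaReport",
    "SeparationWarning",
    "fit_logistic",
    "fit_linear",
    "genome_scan",
    "lambda_gc",
    "qq_data",
]

logger = logging.getLogger(__name__)

#: Median of the chi-square distribution with one degree of freedom.
CHI2_1_MEDIAN = 0.4549364231

#: |beta| beyond which a logistic fit is treated as (quasi-)separated.
_SEPARATION_BETA = 20.0


class SeparationWarning(UserWarning):
    pass


class RankError(ValueError):
    """Design matrix is rank deficient (collinear columns)."""


@dataclass
class AssocResult:
    variant_id: str
    beta: float
    se: float
    chi2: float
    pvalue: float
    n_used: int
    model_tag: str  # uncorrected | pc_corrected | gold_standard

    @classmethod
    def from_beta_se(
        cls, variant_id: str, beta: float, se: float, n_used: int, model_tag: str
    ) -> "AssocResult":
        if math.isfinite(se) and se > 0:
            chi2 = (beta / se) ** 2
            pvalue = float(stats.chi2.sf(chi2, df=1))
        else:
            chi2, pvalue = 0.0, 1.0
        return cls(variant_id, beta, se, chi2, max(pvalue, 5e-324), n_used, model_tag)


@dataclass
class LambdaReport:
    lambda_gc: float
    n_tests: int
    median_chi2: float

    def __post_init__(self) -> None:
        if self.lambda_gc <= 0:
            raise ValueError("lambda must be positive")


def _check_rank(design: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(design.shape[1]) if diag[i] <= tol]
        raise RankError(f"design matrix rank deficient; offending column(s): {bad}")


def _assemble(
    y: np.ndarray,
    genotype: np.ndarray,
    covariates: Optional[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, list]:
    """Build [intercept | genotype | covariates], dropping incomplete rows."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(genotype, dtype=float)
    cols = [np.ones_like(g), g]
    names = ["intercept", "genotype"]
    if covariates is not None and covariates.size:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            names.append(f"covariate_{j}")
    design = np.column_stack(cols)
    ok = np.isfinite(y) & np.isfinite(design).all(axis=1)
    return y[ok], design[ok], names


def fit_logistic(
    y: np.ndarray,
    genotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    variant_id: str = "",
    model_tag: str = "uncorrected",
    max_iter: int = 100,
    grad_tol: float = 1e-8,
) -> AssocResult:
    """Logistic regression Wald test on the genotype term.

    Newton-Raphson with step halving to gradient norm < 1e-8. A diverging
    genotype coefficient (|beta| > 20, i.e. separation) yields a flagged
    result with an infinite-SE sentinel instead of an exception.
    """
    yv, X, names = _assemble(y, genotype, covariates)
    if np.unique(yv).size < 2:
        raise ValueError("phenotype is constant")
    _check_rank(X, names)

    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (yv - mu)
        if np.linalg.norm(grad) < grad_tol:
            break
        w = mu * (1.0 - mu)
        h = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(h, grad)
        except np.linalg.LinAlgError:
            break
        # step halving against likelihood decrease / overflow
        ll0 = _bernoulli_ll(yv, eta)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            if _bernoulli_ll(yv, X @ cand) >= ll0:
                break
            scale *= 0.5
        beta = beta + scale * step
        if abs(beta[1]) > _SEPARATION_BETA:
            logger.warning("separation detected for variant %s", variant_id)
            return AssocResult(
                variant_id, float(beta[1]), math.inf, 0.0, 1.0, len(yv), model_tag
            )

    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = math.sqrt(cov[1, 1])
    return AssocResult.from_beta_se(variant_id, float(beta[1]), se, len(yv), model_tag)


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_linear(
    y: np.ndarray,
    genotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    variant_id: str = "",
    model_tag: str = "uncorrected",
) -> AssocResult:
    """OLS Wald test (large-sample chi2 from t^2) on the genotype term."""
    yv, X, names = _assemble(y, genotype, covariates)
    _check_rank(X, names)
    beta, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    dof = len(yv) - X.shape[1]
    if dof <= 0:
        raise ValueError("not enough observations")
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0))
    if se == 0.0:
        # perfect fit: infinite evidence, P underflows to the minimum float
        return AssocResult(
            variant_id, float(beta[1]), 0.0, math.inf, 5e-324, len(yv), model_tag
        )
    return AssocResult.from_beta_se(variant_id, float(beta[1]), se, len(yv), model_tag)


def _covariate_matrix(
    cohort: CohortDataset, covariate_names: Sequence[str]
) -> np.ndarray:
    cols = []
    for name in covariate_names:
        cols.append(
            [s.covariates.get(name, np.nan) for s in cohort.samples]
        )
    return np.array(cols, dtype=float).T if cols else np.empty((cohort.n_samples, 0))


def genome_scan(
    cohort: CohortDataset,
    model: str,
    pcs: Optional[np.ndarray] = None,
    covariate_names: Sequence[str] = (),
    model_tag: Optional[str] = None,
) -> list:
    """One Wald test per variant; monomorphic variants are skipped with a log entry.

    ``pcs`` (row-aligned PC scores) are appended to the covariates; missing
    genotypes are handled complete-case per variant, while a missing
    covariate drops the sample from the whole scan.
    """
    if model not in ("binary", "quantitative"):
        raise ValueError("model must be 'binary' or 'quantitative'")
    if model == "binary":
        y = np.array(
            [
                np.nan if s.phenotype_binary is None else float(s.phenotype_binary)
                for s in cohort.samples
            ]
        )
        fit = fit_logistic
    else:
        y = np.array(
            [
                np.nan
                if s.phenotype_quantitative is None
                else s.phenotype_quantitative
                for s in cohort.samples
            ]
        )
        fit = fit_linear
    if np.isnan(y).all():
        raise ValueError(f"no {model} phenotype present")

    cov = _covariate_matrix(cohort, covariate_names)
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        if pcs.ndim == 1:
            pcs = pcs[:, None]
        if pcs.shape[0] != cohort.n_samples:
            raise ValueError("PC scores not row-aligned with samples")
        # a zero-variance PC column carries no adjustment; drop it rather
        # than letting it break the design rank
        keep_pc = np.nanstd(pcs, axis=0) > 0
        cov = np.hstack([cov, pcs[:, keep_pc]])
    if model_tag is None:
        model_tag = "pc_corrected" if pcs is not None else "uncorrected"

    # drop samples with any missing covariate from the whole scan
    keep = ~np.isnan(cov).any(axis=1) & ~np.isnan(y)
    y = y[keep]
    cov = cov[keep]
    geno = cohort.genotypes[keep]

    results = []
    for j, v in enumerate(cohort.variants):
        g = geno[:, j]
        finite = g[np.isfinite(g)]
        if np.unique(finite).size < 2:
            logger.info("genome_scan: skipping monomorphic variant %s", v.variant_id)
            continue
        results.append(
            fit(y, g, cov, variant_id=v.variant_id, model_tag=model_tag)
        )
    return results


def lambda_gc(results: Sequence[AssocResult]) -> LambdaReport:
    """Genomic inflation factor: median observed chi2 over the chi2_1 median."""
    if not results:
        raise ValueError("no association results")
    chi2 = np.array([r.chi2 for r in results], dtype=float)
    med = float(np.median(chi2))
    return LambdaReport(
        lambda_gc=med / CHI2_1_MEDIAN, n_tests=len(results), median_chi2=med
    )


def qq_data(results: Sequence[AssocResult]) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) -log10 P pairs for a QQ plot.

    Observed P sorted ascending; expected quantiles (i - 0.5)/n. P values of
    zero are clamped to the smallest positive float with a warning.
    """
    import warnings

    if not results:
        raise ValueError("no association results")
    p = np.array([r.pvalue for r in results], dtype=float)
    if (p <= 0).any():
        warnings.warn("P value(s) of zero clamped to the machine minimum")
        p = np.maximum(p, 5e-324)
    p.sort()
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return -np.log10(expected), -np.log10(p)
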