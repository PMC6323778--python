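"""Panel evaluation battery.

A candidate AIM panel is judged against the genome-wide "gold standard":
(1) squared correlation between the gold PC1 and the panel PC1 (the
ancestry index concordance), (2) squared correlation of -log10 association
P values between the gold-PC-corrected scan and the panel-PC-corrected
scan, (3) genomic inflation factors before and after correction, and
robustness of (1) under random subsampling and within geographic-region
strata. PCs are always recomputed inside each subsample/region, mimicking
an analyst who only has that sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .assoc import AssocResult, genome_scan, lambda_gc
from .genodata import CohortDataset
from .pca import PCAResult, ancestry_index, pca_cohort

__all__ = [
    "PanelEvaluation",
    "pc_concordance",
    "pvalue_concordance",
    "subsample_eval",
    "region_eval",
    "compare_panels",
]


@dataclass
class PanelEvaluation:
    panel_id: str
    pc1_r2: float
    pvalue_r2: Optional[float] = None
    lambda_uncorrected: Optional[float] = None
    lambda_corrected: Optional[float] = None
    per_region: dict = field(default_factory=dict)
    per_subsample: dict = field(default_factory=dict)


def pc_concordance(gold: np.ndarray, panel_scores: np.ndarray) -> float:
    """Squared Pearson correlation of two PC score vectors (sign-aligned).

    The PC sign is arbitrary, so the panel vector is flipped when the raw
    correlation is negative; squaring makes the result sign-invariant
    anyway. Constant input yields NaN with a warning.
    """
    x = np.asarray(gold, dtype=float)
    y = np.asarray(panel_scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("score vectors must be aligned and equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant score vector: concordance undefined")
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pvalue_concordance(
    gold: Sequence[AssocResult],
    other: Sequence[AssocResult],
    log_scale: bool = True,
) -> float:
    """Squared Pearson correlation of association P values across shared variants.

    Computed on the -log10 scale by default (tail behaviour is what panel
    evaluation cares about); ``log_scale=False`` correlates raw P.
    """
    gold_map = {r.variant_id: r.pvalue for r in gold}
    pairs = [
        (gold_map[r.variant_id], r.pvalue)
        for r in other
        if r.variant_id in gold_map
    ]
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} shared variants; need >= 3")
    a = np.array([p for p, _ in pairs])
    b = np.array([p for _, p in pairs])
    if log_scale:
        a, b = -np.log10(a), -np.log10(b)
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _panel_vs_gold_pc1(cohort: CohortDataset, panel) -> float:
    gold = pca_cohort(cohort, n_components=1, drop_monomorphic=True)
    panel_pca = ancestry_index(cohort, panel, n_components=1)
    return pc_concordance(gold.scores[:, 0], panel_pca.scores[:, 0])


def subsample_eval(
    cohort: CohortDataset,
    panel,
    sizes: Sequence[int] = (1500, 1000, 500),
    seed: int = 0,
) -> dict:
    """Gold-vs-panel PC1 concordance on random subsamples of the cohort.

    One draw without replacement per size; gold and panel PCAs are both
    recomputed inside the subsample.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for n in sizes:
        if n > cohort.n_samples:
            raise ValueError(f"subsample {n} exceeds cohort size {cohort.n_samples}")
        if n < 3:
            raise ValueError("subsample size must be >= 3")
        idx = np.sort(rng.choice(cohort.n_samples, size=n, replace=False))
        out[n] = _panel_vs_gold_pc1(cohort.subset_samples(idx), panel)
    return out


def region_eval(cohort: CohortDataset, panel, region_field: str = "region_label") -> dict:
    """Per-region gold-vs-panel PC1 concordance (PCAs recomputed within region)."""
    labels = [getattr(s, region_field) for s in cohort.samples]
    if all(l is None for l in labels):
        raise ValueError("no region labels present")
    out = {}
    for region in sorted({l for l in labels if l is not None}):
        idx = [i for i, l in enumerate(labels) if l == region]
        if len(idx) < 3:
            warnings.warn(f"region {region!r} has < 3 samples; skipped")
            continue
        out[region] = _panel_vs_gold_pc1(cohort.subset_samples(idx), panel)
    return out


def compare_panels(
    cohort: CohortDataset,
    panels: Sequence,
    gold: PCAResult,
    model: str = "binary",
    covariate_names: Sequence[str] = (),
    n_pcs: int = 2,
) -> list:
    """Evaluate each panel: PC1 concordance, P-value concordance, lambdas.

    The gold scan (corrected by genome-wide PCs) and the uncorrected scan are
    computed once; each panel then gets its own corrected scan using its
    recomputed ancestry-index PCs. Output is ranked by pc1_r2 descending.
    """
    if not panels:
        return []
    gold_scan = genome_scan(
        cohort,
        model,
        pcs=gold.scores[:, :n_pcs],
        covariate_names=covariate_names,
        model_tag="gold_standard",
    )
    uncorrected = genome_scan(
        cohort, model, pcs=None, covariate_names=covariate_names
    )
    lam_un = lambda_gc(uncorrected).lambda_gc

    evaluations = []
    for i, panel in enumerate(panels):
        panel_pca = ancestry_index(cohort, panel, n_components=n_pcs)
        scan = genome_scan(
            cohort,
            model,
            pcs=panel_pca.scores[:, : min(n_pcs, panel_pca.n_components)],
            covariate_names=covariate_names,
        )
        evaluations.append(
            PanelEvaluation(
                panel_id=f"panel_{panel.size}aims_{i}",
                pc1_r2=pc_concordance(gold.scores[:, 0], panel_pca.scores[:, 0]),
                pvalue_r2=pvalue_concordance(gold_scan, scan),
                lambda_uncorrected=lam_un,
                lambda_corrected=lambda_gc(scan).lambda_gc,
            )
        )
    evaluations.sort(key=lambda e: -e.pc1_r2)
    return evaluations
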