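"""AIM panel selection from PCA SNP weights.

The selection pipeline: keep variants in the extreme tails of the PC1
SNP-weight distribution; rank candidates per chromosome by |weight| and keep
the top 20; allocate panel slots in two phases — first one AIM per
chromosome (genome-wide coverage), then fill by global |weight| subject to
per-chromosome quotas derived from the Denver size classification of the
autosomes (large chromosomes get more AIMs than small ones) — skipping any
candidate in linkage disequilibrium with an already-accepted member.
Panels come in nested sizes (multiples of 16 by default): the largest is
built first and each smaller one is re-allocated from within its parent's
members, which guarantees nestedness.

Deltas (absolute parental allele-frequency differences) quantify how
ancestry-informative each selected marker is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .genodata import CohortDataset
from .pca import PCAResult

__all__ = [
    "DENVER_GROUPS",
    "denver_group",
    "SelectionConfig",
    "AIMPanel",
    "tail_filter",
    "rank_per_chromosome",
    "allocate_panel",
    "select_nested_panels",
    "compute_delta",
    "pairwise_ld_r2",
]

#: Denver size/centromere classification of the 22 human autosomes.
DENVER_GROUPS = {
    "A": ("1", "2", "3"),
    "B": ("4", "5"),
    "C": ("6", "7", "8", "9", "10", "11", "12"),
    "D": ("13", "14", "15"),
    "E": ("16", "17", "18"),
    "F": ("19", "20"),
    "G": ("21", "22"),
}

_CHROM_TO_GROUP = {c: g for g, chroms in DENVER_GROUPS.items() for c in chroms}


def denver_group(chromosome: str) -> str:
    """Denver group (A–G) of an autosome label."""
    return _CHROM_TO_GROUP[str(chromosome)]


#: Per-chromosome AIM quota at the largest panel size. Large chromosomes
#: (groups A/B) take more markers than medium (C–E) or small (F/G) ones;
#: the quotas must jointly supply the largest panel across the 22 autosomes
#: (these sum to 67 slots, enough for a 64-marker panel).
DEFAULT_GROUP_CAPS = {"A": 5, "B": 4, "C": 3, "D": 3, "E": 2, "F": 2, "G": 2}


@dataclass
class SelectionConfig:
    panel_sizes: Sequence[int] = (16, 32, 48, 64)
    tail_quantile: float = 0.01
    top_m_per_chromosome: int = 20
    group_caps: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_CAPS))
    ld_r2_max: float = 0.05
    require_all_chromosomes: bool = True

    def __post_init__(self) -> None:
        sizes = list(self.panel_sizes)
        if sizes != sorted(sizes) or len(set(sizes)) != len(sizes):
            raise ValueError("panel_sizes must be strictly increasing")
        if not (0 < self.tail_quantile < 0.5):
            raise ValueError("tail_quantile must lie in (0, 0.5)")
        if any(self.group_caps.get(g, 0) < 1 for g in DENVER_GROUPS):
            raise ValueError("every Denver group needs a cap >= 1")


@dataclass
class AIMPanel:
    """An ordered AIM list: variants with their PC1 weights, largest |weight| first."""

    variants: list  # VariantRecord
    weights: np.ndarray
    parent_panel: Optional["AIMPanel"] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.variants) != self.weights.size:
            raise ValueError("variants and weights lengths differ")
        order = np.argsort(-np.abs(self.weights), kind="stable")
        self.variants = [self.variants[i] for i in order]
        self.weights = self.weights[order]

    @property
    def size(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list:
        return [v.variant_id for v in self.variants]

    @property
    def ranks(self) -> np.ndarray:
        """1-based rank by descending |weight|."""
        return np.arange(1, self.size + 1)

    def is_nested_in(self, other: "AIMPanel") -> bool:
        return set(self.variant_ids) <= set(other.variant_ids)


def tail_filter(weights: np.ndarray, tail_quantile: float) -> np.ndarray:
    """Indices of weights in the lower/upper ``tail_quantile`` tails.

    Quantiles use linear interpolation; keeps w <= Q(q) or w >= Q(1-q).
    """
    w = np.asarray(weights, dtype=float)
    if not np.isfinite(w).all():
        raise ValueError("weights must be finite")
    lo = np.quantile(w, tail_quantile)
    hi = np.quantile(w, 1.0 - tail_quantile)
    idx = np.flatnonzero((w <= lo) | (w >= hi))
    if idx.size == 0:
        raise ValueError(
            f"no variants in the {tail_quantile} tails; increase tail_quantile"
        )
    return idx


def rank_per_chromosome(
    candidates: np.ndarray,
    weights: np.ndarray,
    variants: Sequence,
    top_m: int = 20,
) -> dict:
    """Per chromosome, candidates sorted by |weight| descending, truncated at top_m.

    Ties in |weight| break by (chromosome, position) ascending so selection
    is deterministic.
    """
    w = np.asarray(weights, dtype=float)
    by_chrom: dict[str, list] = {}
    for i in candidates:
        by_chrom.setdefault(variants[i].chromosome, []).append(int(i))
    ranked = {}
    for chrom, idx in by_chrom.items():
        idx.sort(
            key=lambda i: (-abs(w[i]), int(variants[i].chromosome), variants[i].position)
        )
        ranked[chrom] = idx[:top_m]
    return ranked


def pairwise_ld_r2(cohort: CohortDataset, i: int, j: int) -> float:
    """Squared Pearson correlation of two variants' dosages (shared non-missing)."""
    gi = cohort.genotypes[:, i]
    gj = cohort.genotypes[:, j]
    ok = ~np.isnan(gi) & ~np.isnan(gj)
    gi, gj = gi[ok], gj[ok]
    if np.unique(gi).size < 2 or np.unique(gj).size < 2:
        raise ValueError("constant dosage vector: correlation undefined")
    r = np.corrcoef(gi, gj)[0, 1]
    return float(r * r)


def _cohort_ld_provider(cohort: CohortDataset) -> Callable[[int, int], float]:
    def provider(i: int, j: int) -> float:
        try:
            return pairwise_ld_r2(cohort, i, j)
        except ValueError:
            return 0.0  # a constant column cannot be correlated with anything

    return provider


class InfeasibleSelectionError(ValueError):
    """Quotas / LD constraints / candidate supply cannot fill the panel."""


def allocate_panel(
    ranked: dict,
    size: int,
    group_caps: dict,
    ld_matrix_provider: Callable[[int, int], float],
    ld_r2_max: float,
    require_all: bool = True,
    variants: Optional[Sequence] = None,
    weights: Optional[np.ndarray] = None,
) -> list:
    """Two-phase greedy slot allocation; returns selected variant indices.

    Phase 1 (if ``require_all``): the best not-in-LD candidate of every
    chromosome that has any, chromosomes in numeric order. Phase 2: fill
    remaining slots by global descending |weight| subject to per-chromosome
    caps (cap of a chromosome = cap of its Denver group); candidates in LD
    (r^2 >= ``ld_r2_max``) with an accepted member are skipped. Fully
    deterministic; ties break by (chromosome, position).
    """
    if weights is None:
        raise ValueError("weights vector required")
    w = np.asarray(weights, dtype=float)
    caps = {c: group_caps[denver_group(c)] for c in ranked}
    supply = sum(min(caps[c], len(ranked[c])) for c in ranked)
    if supply < size:
        raise InfeasibleSelectionError(
            f"caps/candidates supply {supply} < panel size {size}"
        )

    chosen: list[int] = []
    per_chrom: dict[str, int] = {c: 0 for c in ranked}

    def in_ld(cand: int) -> bool:
        return any(ld_matrix_provider(cand, c) >= ld_r2_max for c in chosen)

    if require_all:
        # cover chromosomes strongest-first so that when size < number of
        # chromosomes the slots go to the most informative ones
        order = sorted(
            (c for c in ranked if ranked[c]),
            key=lambda c: (-max(abs(w[i]) for i in ranked[c]), int(c)),
        )
        for chrom in order:
            if len(chosen) >= size:
                break
            for cand in ranked[chrom]:
                if not in_ld(cand):
                    chosen.append(cand)
                    per_chrom[chrom] += 1
                    break

    pool = []
    for chrom, idx in ranked.items():
        for cand in idx:
            if cand not in chosen:
                pool.append((chrom, cand))
    if variants is not None:
        pool.sort(
            key=lambda t: (-abs(w[t[1]]), int(t[0]), variants[t[1]].position)
        )
    else:
        pool.sort(key=lambda t: (-abs(w[t[1]]), int(t[0]), t[1]))

    for chrom, cand in pool:
        if len(chosen) >= size:
            break
        if per_chrom[chrom] >= caps[chrom]:
            continue
        if in_ld(cand):
            continue
        chosen.append(cand)
        per_chrom[chrom] += 1

    if len(chosen) < size:
        raise InfeasibleSelectionError(
            f"allocated {len(chosen)} of {size} slots "
            "(caps too tight or candidates exhausted by the LD rule)"
        )
    return chosen[:size]


def _scaled_caps(group_caps: dict, size: int, largest: int) -> dict:
    """Scale the largest-panel caps to a smaller size (ceiling, minimum 1).

    Ceiling rather than floor: flooring leaves too few slots to fill the
    intermediate panel sizes once every chromosome must be covered.
    """
    return {
        g: max(1, -((-cap * size) // largest)) for g, cap in group_caps.items()
    }


def select_nested_panels(
    cohort: CohortDataset,
    pca: PCAResult,
    config: SelectionConfig = SelectionConfig(),
    parental_freqs: Optional[dict] = None,
) -> list:
    """Run the full selection: tail filter, per-chromosome ranking, nested allocation.

    The largest panel is built first with the full Denver-group caps; each
    smaller panel is re-allocated from within the larger panel's members
    (with floor-scaled caps), guaranteeing the nested chain. Panels are
    returned smallest to largest, each linked to its parent.

    ``parental_freqs`` (population label -> frequency vector over cohort
    variants) attaches parental frequencies to the selected records so
    deltas can be computed downstream.
    """
    weights = pca.snp_weights[:, 0]
    candidates = tail_filter(weights, config.tail_quantile)
    ranked = rank_per_chromosome(
        candidates, weights, cohort.variants, config.top_m_per_chromosome
    )
    provider = _cohort_ld_provider(cohort)
    sizes = sorted(config.panel_sizes)
    largest = sizes[-1]

    chosen_large = allocate_panel(
        ranked,
        largest,
        config.group_caps,
        provider,
        config.ld_r2_max,
        require_all=config.require_all_chromosomes,
        variants=cohort.variants,
        weights=weights,
    )

    def build(indices: Sequence[int], parent) -> AIMPanel:
        recs = []
        for i in indices:
            v = cohort.variants[i]
            if parental_freqs is not None:
                freqs = {pop: float(vec[i]) for pop, vec in parental_freqs.items()}
                from .genodata import VariantRecord

                v = VariantRecord(
                    v.variant_id,
                    v.chromosome,
                    v.position,
                    v.counted_allele,
                    v.other_allele,
                    freq_parental=freqs,
                )
            recs.append(v)
        return AIMPanel(
            variants=recs, weights=weights[list(indices)], parent_panel=parent
        )

    panels = {largest: chosen_large}
    for size in reversed(sizes[:-1]):
        next_larger = min(s for s in panels if s > size)
        members = set(panels[next_larger])
        restricted = {
            chrom: [i for i in idx if i in members]
            for chrom, idx in ranked.items()
        }
        restricted = {c: idx for c, idx in restricted.items() if idx}
        panels[size] = allocate_panel(
            restricted,
            size,
            _scaled_caps(config.group_caps, size, largest),
            provider,
            config.ld_r2_max,
            require_all=config.require_all_chromosomes,
            variants=cohort.variants,
            weights=weights,
        )

    built: dict[int, AIMPanel] = {}
    for size in reversed(sizes):
        larger = [s for s in sizes if s > size]
        parent = built[larger[0]] if larger else None  # immediate parent
        built[size] = build(panels[size], parent)
    return [built[s] for s in sizes]


def compute_delta(panel: AIMPanel, pop_a: str, pop_b: str) -> np.ndarray:
    """|p_a - p_b| per panel variant; symmetric and allele-swap invariant."""
    deltas = []
    for v in panel.variants:
        freqs = v.freq_parental or {}
        for pop in (pop_a, pop_b):
            if pop not in freqs:
                raise ValueError(
                    f"variant {v.variant_id}: no parental frequency for {pop!r}"
                )
        deltas.append(abs(freqs[pop_a] - freqs[pop_b]))
    return np.array(deltas)
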