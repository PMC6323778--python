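"""Synthetic admixed cohorts with known truth.

The generator emulates the statistical structure of a Mexican-mestizo-like
cohort: two (optionally three) parental populations diverged from a common
ancestor under the Balding–Nichols drift model, individuals with Dirichlet
admixture proportions centred near 43% European / 57% Native American (a
small third component when K=3), and phenotypes whose risk or mean depends
on individual ancestry — creating exactly the confounding that PC-based
stratification correction must remove.

Per locus, the ancestral frequency is uniform on ``ancestral_freq_range``
and each population's frequency is Beta-distributed around it with drift
parameter F (the per-population Fst). Genotypes are independent Binomial(2,
q_i · p_j) draws — loci are unlinked, matching the requirement that an AIM
panel be mutually uncorrelated. An optional duplicate-locus mode copies
genotype columns with a little noise to give the LD pruner something to do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genodata import CohortDataset, SampleRecord, VariantRecord

__all__ = [
    "SimulationConfig",
    "PhenotypeSpec",
    "SimTruth",
    "draw_parental_freqs",
    "draw_high_delta_freqs",
    "simulate_admixed_cohort",
    "simulate_phenotypes",
    "plant_aim_panel",
    "simulate_validation_cohort",
]

#: Default Dirichlet concentrations: mean ancestry 43/57 (K=2) or 42/55/3
#: (K=3) with total concentration 6, giving realistic individual spread.
_DEFAULT_ALPHA = {2: (2.58, 3.42), 3: (2.52, 3.30, 0.18)}


@dataclass
class PhenotypeSpec:
    """How to turn ancestry and genotypes into a phenotype.

    ``ancestry_effect`` is the log-odds (binary) or trait-unit
    (quantitative) change per unit of population-1 ancestry. ``baseline``
    defaults to the value that centres a binary phenotype at ~50%
    prevalence given the configured mean ancestry.
    """

    kind: str = "binary"
    ancestry_effect: float = 2.0
    causal_variants: Sequence[tuple[int, float]] = ()
    baseline: Optional[float] = None
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "quantitative"):
            raise ValueError("phenotype kind must be 'binary' or 'quantitative'")


@dataclass
class SimulationConfig:
    n_individuals: int = 1000
    n_variants: int = 10_000
    n_populations: int = 2
    fst_per_population: Sequence[float] = (0.15, 0.15)
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    admixture_alpha: Optional[Sequence[float]] = None
    seed: int = 0
    phenotype: Optional[PhenotypeSpec] = None
    #: region label -> mean population-2 (Native-like) ancestry; when set,
    #: individuals are split evenly across regions and q is drawn per region.
    region_native_means: Optional[dict] = None
    #: number of locus pairs copied (with 2% resampling noise) to create LD.
    n_duplicate_pairs: int = 0

    def __post_init__(self) -> None:
        if self.n_populations not in (2, 3):
            raise ValueError("n_populations must be 2 or 3")
        if self.admixture_alpha is None:
            self.admixture_alpha = _DEFAULT_ALPHA[self.n_populations]
        if len(self.admixture_alpha) != self.n_populations:
            raise ValueError("admixture_alpha length must equal n_populations")
        if any(a <= 0 for a in self.admixture_alpha):
            raise ValueError("admixture_alpha entries must be > 0")
        if len(self.fst_per_population) != self.n_populations:
            raise ValueError("fst_per_population length must equal n_populations")
        if any(not (0 < f < 1) for f in self.fst_per_population):
            raise ValueError("fst values must lie in (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("ancestral_freq_range must be within (0, 1)")
        if self.region_native_means is not None and self.n_populations != 2:
            raise ValueError("region_native_means is only supported for K=2")


@dataclass
class SimTruth:
    """The simulator's hidden state, kept for parameter-recovery tests."""

    parental_freqs: np.ndarray  # populations x variants
    individual_ancestry: np.ndarray  # individuals x populations, simplex rows
    causal_effects: Sequence[tuple[int, float]] = ()

    def __post_init__(self) -> None:
        q = np.asarray(self.individual_ancestry, dtype=float)
        if not np.allclose(q.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("ancestry rows must sum to 1")
        p = np.asarray(self.parental_freqs, dtype=float)
        if (p < 0).any() or (p > 1).any():
            raise ValueError("parental frequencies must lie in [0, 1]")


def draw_parental_freqs(config: SimulationConfig) -> np.ndarray:
    """Balding–Nichols parental frequencies, populations x variants.

    Ancestral p_j ~ Uniform(ancestral_freq_range); population k draws
    Beta(p(1-F)/F, (1-p)(1-F)/F), so E[p_k | p] = p and Var = F p(1-p).
    """
    rng = np.random.default_rng(config.seed)
    return _draw_parental_freqs(config, rng)


def _draw_parental_freqs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.ancestral_freq_range
    ancestral = rng.uniform(lo, hi, size=config.n_variants)
    pops = np.empty((config.n_populations, config.n_variants))
    for k, fst in enumerate(config.fst_per_population):
        a = ancestral * (1.0 - fst) / fst
        b = (1.0 - ancestral) * (1.0 - fst) / fst
        pops[k] = rng.beta(a, b)
    return pops


def draw_high_delta_freqs(
    n_variants: int,
    rng: np.random.Generator,
    delta_range: tuple[float, float] = (0.78, 0.92),
) -> np.ndarray:
    """Two-population frequencies with |p1 - p2| in ``delta_range`` at every locus.

    Emulates the informativeness of a designed AIM panel, where every marker
    has a large parental allele-frequency difference; the allele with the
    higher frequency in population 1 is randomised per locus.
    """
    delta = rng.uniform(*delta_range, size=n_variants)
    margin = (1.0 - delta) / 2.0
    centre = rng.uniform(0.5 - 0.9 * margin, 0.5 + 0.9 * margin)
    p1 = centre + delta / 2.0
    p2 = centre - delta / 2.0
    flip = rng.random(n_variants) < 0.5
    out = np.vstack([np.where(flip, p2, p1), np.where(flip, p1, p2)])
    return np.clip(out, 1e-4, 1 - 1e-4)


def _draw_ancestry(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_individuals
    if config.region_native_means is None:
        q = rng.dirichlet(config.admixture_alpha, size=n)
        regions = [None] * n
        return q, regions
    conc = float(np.sum(config.admixture_alpha))
    names = list(config.region_native_means)
    # even split, remainder to the first regions
    counts = np.full(len(names), n // len(names))
    counts[: n % len(names)] += 1
    qs, regions = [], []
    for name, cnt in zip(names, counts):
        m = config.region_native_means[name]
        if not (0 < m < 1):
            raise ValueError(f"region {name!r}: mean ancestry must be in (0, 1)")
        qs.append(rng.dirichlet((conc * (1 - m), conc * m), size=cnt))
        regions.extend([name] * cnt)
    return np.vstack(qs), regions


def _variant_table(n_variants: int) -> list:
    """Round-robin chromosome assignment over the 22 autosomes."""
    variants = []
    for j in range(n_variants):
        chrom = str(j % 22 + 1)
        pos = (j // 22 + 1) * 5000
        variants.append(
            VariantRecord(f"snp{j:06d}", chrom, pos, "A", "B")
        )
    return variants


def simulate_admixed_cohort(
    config: SimulationConfig,
) -> tuple[CohortDataset, SimTruth]:
    """Draw a cohort: q ~ Dirichlet, genotypes ~ Binomial(2, q · p) per locus.

    Variants are assigned round-robin to chromosomes "1".."22" with synthetic
    positions so chromosome-aware selection is exercised. All randomness
    flows from ``config.seed``; identical configs give identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    parental = _draw_parental_freqs(config, rng)
    q, regions = _draw_ancestry(config, rng)
    pi = q @ parental  # individuals x variants, per-locus allele probability
    geno = rng.binomial(2, pi).astype(float)

    if config.n_duplicate_pairs:
        d = config.n_duplicate_pairs
        if 2 * d > config.n_variants:
            raise ValueError("too many duplicate pairs for n_variants")
        # copy the first d columns into the last d, resampling 2% of entries
        for i in range(d):
            src, dst = i, config.n_variants - d + i
            col = geno[:, src].copy()
            noise = rng.random(config.n_individuals) < 0.02
            col[noise] = rng.binomial(2, pi[noise, src])
            geno[:, dst] = col
            parental[:, dst] = parental[:, src]

    variants = _variant_table(config.n_variants)
    samples = [
        SampleRecord(sample_id=f"ind{i:05d}", region_label=regions[i])
        for i in range(config.n_individuals)
    ]
    cohort = CohortDataset(genotypes=geno, variants=variants, samples=samples)
    truth = SimTruth(parental_freqs=parental, individual_ancestry=q)
    if config.phenotype is not None:
        cohort = simulate_phenotypes(cohort, truth, config.phenotype, config.seed + 1)
    return cohort, truth


def plant_aim_panel(
    cohort: CohortDataset,
    truth: SimTruth,
    n_aims: int = 32,
    seed: int = 0,
    delta_range: tuple[float, float] = (0.78, 0.92),
    pop_labels: tuple[str, str] = ("pop1", "pop2"),
):
    """Append ``n_aims`` designed-AIM-grade loci to a K=2 cohort.

    The new loci have parental allele-frequency differences in
    ``delta_range`` (emulating a validated AIM panel's informativeness) and
    genotypes drawn from the same individual ancestries as the rest of the
    cohort. Returns (extended cohort, extended truth, AIMPanel of the new
    loci with parental frequencies attached and delta used as the weight).
    """
    from .aim_select import AIMPanel

    if truth.parental_freqs.shape[0] != 2:
        raise ValueError("planted AIM panels are only defined for K=2")
    rng = np.random.default_rng(seed)
    p_aim = draw_high_delta_freqs(n_aims, rng, delta_range)
    q = truth.individual_ancestry
    geno = rng.binomial(2, q @ p_aim).astype(float)

    records = []
    for i in range(n_aims):
        chrom = str(i % 22 + 1)
        records.append(
            VariantRecord(
                f"aim{i:03d}",
                chrom,
                100_000_000 + (i // 22 + 1) * 5000,
                "A",
                "B",
                freq_parental={
                    pop_labels[0]: float(p_aim[0, i]),
                    pop_labels[1]: float(p_aim[1, i]),
                },
            )
        )
    extended = CohortDataset(
        genotypes=np.hstack([cohort.genotypes, geno]),
        variants=list(cohort.variants) + records,
        samples=list(cohort.samples),
    )
    truth2 = SimTruth(
        parental_freqs=np.hstack([truth.parental_freqs, p_aim]),
        individual_ancestry=q,
        causal_effects=truth.causal_effects,
    )
    panel = AIMPanel(variants=records, weights=np.abs(p_aim[0] - p_aim[1]))
    return extended, truth2, panel


def simulate_validation_cohort(
    n_total: int = 500,
    n_ref_pop1: int = 95,
    n_ref_pop2: int = 38,
    n_aims: int = 32,
    seed: int = 0,
    delta_range: tuple[float, float] = (0.78, 0.92),
    admixture_alpha: Sequence[float] = _DEFAULT_ALPHA[2],
    ref_concentration: float = 60.0,
):
    """An ancestry-validation cohort: admixed individuals plus parental references.

    Mirrors the standard validation design for AIM-based ancestry estimation,
    where reference individuals from both parental populations (here 95
    population-1-like and 38 population-2-like, the reference panel sizes
    typical for European and Native American panels) are analysed alongside
    the admixed samples. Reference individuals carry ``population_label``
    ("pop1"/"pop2"); genotypes cover ``n_aims`` designed-grade AIM loci with
    parental deltas in ``delta_range``. Returns (cohort, SimTruth, AIMPanel).
    """
    from .aim_select import AIMPanel

    n_admixed = n_total - n_ref_pop1 - n_ref_pop2
    if n_admixed <= 0:
        raise ValueError("n_total must exceed the reference sample counts")
    rng = np.random.default_rng(seed)
    c = ref_concentration
    q = np.vstack(
        [
            rng.dirichlet(admixture_alpha, size=n_admixed),
            rng.dirichlet((0.98 * c, 0.02 * c), size=n_ref_pop1),
            rng.dirichlet((0.02 * c, 0.98 * c), size=n_ref_pop2),
        ]
    )
    p_aim = draw_high_delta_freqs(n_aims, rng, delta_range)
    geno = rng.binomial(2, q @ p_aim).astype(float)
    records = []
    for i in range(n_aims):
        records.append(
            VariantRecord(
                f"aim{i:03d}",
                str(i % 22 + 1),
                (i // 22 + 1) * 5000,
                "A",
                "B",
                freq_parental={
                    "pop1": float(p_aim[0, i]),
                    "pop2": float(p_aim[1, i]),
                },
            )
        )
    labels = (
        [None] * n_admixed + ["pop1"] * n_ref_pop1 + ["pop2"] * n_ref_pop2
    )
    samples = [
        SampleRecord(sample_id=f"ind{i:05d}", population_label=labels[i])
        for i in range(n_total)
    ]
    cohort = CohortDataset(genotypes=geno, variants=records, samples=samples)
    truth = SimTruth(parental_freqs=p_aim, individual_ancestry=q)
    panel = AIMPanel(
        variants=records, weights=np.abs(p_aim[0] - p_aim[1])
    )
    return cohort, truth, panel


def simulate_phenotypes(
    cohort: CohortDataset,
    truth: SimTruth,
    spec: PhenotypeSpec,
    seed: int,
) -> CohortDataset:
    """Attach ancestry-dependent phenotypes plus independent age/sex/BMI.

    Binary: logit P(case) = baseline + ancestry_effect * q_1 + sum(beta * g).
    Quantitative: the same linear predictor plus Normal(0, noise_sd) noise.
    Covariates are drawn independently of genotype (non-confounded). Existing
    phenotypes are overwritten with a warning.
    """
    import warnings

    if truth.individual_ancestry.shape[0] != cohort.n_samples:
        raise ValueError("truth/cohort sample dimensions do not match")
    for j, _ in spec.causal_variants:
        if not (0 <= j < cohort.n_variants):
            raise ValueError(f"causal variant index {j} out of range")
    if any(
        s.phenotype_binary is not None or s.phenotype_quantitative is not None
        for s in cohort.samples
    ):
        warnings.warn("phenotype already present; overwriting")

    rng = np.random.default_rng(seed)
    q1 = truth.individual_ancestry[:, 0]
    lin = spec.ancestry_effect * q1
    for j, beta in spec.causal_variants:
        g = np.nan_to_num(cohort.genotypes[:, j])
        lin = lin + beta * g
    baseline = spec.baseline
    if baseline is None:
        baseline = -spec.ancestry_effect * float(q1.mean())
    lin = lin + baseline

    age = rng.normal(50.0, 10.0, cohort.n_samples)
    bmi = rng.normal(28.0, 4.0, cohort.n_samples)
    sex = rng.integers(0, 2, cohort.n_samples)

    samples = []
    for i, s in enumerate(cohort.samples):
        cov = dict(s.covariates)
        cov.update(age=float(age[i]), bmi=float(bmi[i]), sex=float(sex[i]))
        new = SampleRecord(
            sample_id=s.sample_id,
            sex="female" if sex[i] else "male",
            covariates=cov,
            region_label=s.region_label,
            population_label=s.population_label,
        )
        samples.append(new)

    if spec.kind == "binary":
        prob = 1.0 / (1.0 + np.exp(-lin))
        y = rng.binomial(1, prob)
        for i, s in enumerate(samples):
            s.phenotype_binary = int(y[i])
    else:
        y = lin + rng.normal(0.0, spec.noise_sd, cohort.n_samples)
        for i, s in enumerate(samples):
            s.phenotype_quantitative = float(y[i])

    return CohortDataset(
        genotypes=cohort.genotypes,
        variants=list(cohort.variants),
        samples=samples,
    )
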