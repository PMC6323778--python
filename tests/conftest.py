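import numpy as np
import pytest

from aimkit.aim_select import SelectionConfig, select_nested_panels
from aimkit.genodata import qc_filter
from aimkit.pca import ancestry_index, pca_cohort
from aimkit.simulate import PhenotypeSpec, SimulationConfig, simulate_admixed_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def stratified_sim():
    """A shared ancestry-confounded case-control cohort with selected panels.

    500 individuals x 4,000 unlinked loci, two-way admixture (F = 0.15 per
    side), binary phenotype driven by ancestry only (no causal loci) — the
    canonical stratification scenario. Computed once per session: includes
    QC, the genome-wide ("gold") PCA, nested 16/32 AIM panels and the
    uncorrected / gold-corrected / panel-corrected genome scans.
    """
    from aimkit.assoc import genome_scan

    cfg = SimulationConfig(
        n_individuals=500,
        n_variants=4000,
        seed=20,
        phenotype=PhenotypeSpec(kind="binary", ancestry_effect=2.0),
    )
    cohort, truth = simulate_admixed_cohort(cfg)
    cohort, _ = qc_filter(cohort)
    kept = [int(v.variant_id[3:]) for v in cohort.variants]
    parental = truth.parental_freqs[:, kept]

    gold = pca_cohort(cohort, n_components=2)
    panels = select_nested_panels(
        cohort,
        gold,
        SelectionConfig(panel_sizes=(16, 32), tail_quantile=0.02),
        parental_freqs={"pop1": parental[0], "pop2": parental[1]},
    )
    panel32 = panels[-1]
    idx32 = ancestry_index(cohort, panel32, n_components=2)

    covars = ["age", "sex", "bmi"]
    scans = {
        "uncorrected": genome_scan(cohort, "binary", covariate_names=covars),
        "gold": genome_scan(
            cohort,
            "binary",
            pcs=gold.scores[:, :2],
            covariate_names=covars,
            model_tag="gold_standard",
        ),
        "panel32": genome_scan(
            cohort,
            "binary",
            pcs=idx32.scores[:, :2],
            covariate_names=covars,
        ),
    }
    return {
        "cohort": cohort,
        "truth_q": truth.individual_ancestry,
        "parental": parental,
        "gold": gold,
        "panels": panels,
        "panel32": panel32,
        "idx32": idx32,
        "scans": scans,
    }
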