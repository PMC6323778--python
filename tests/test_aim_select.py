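import numpy as np
import pytest

from _oracles import exhaustive_allocation
from aimkit.aim_select import (
    DENVER_GROUPS,
    AIMPanel,
    InfeasibleSelectionError,
    SelectionConfig,
    allocate_panel,
    compute_delta,
    denver_group,
    pairwise_ld_r2,
    rank_per_chromosome,
    select_nested_panels,
    tail_filter,
)
from aimkit.genodata import CohortDataset, SampleRecord, VariantRecord


def make_cohort(geno, chroms, positions=None):
    geno = np.asarray(geno, dtype=float)
    n, m = geno.shape
    positions = positions or [100 * (j + 1) for j in range(m)]
    return CohortDataset(
        genotypes=geno,
        variants=[
            VariantRecord(f"v{j}", chroms[j], positions[j], "A", "G")
            for j in range(m)
        ],
        samples=[SampleRecord(sample_id=f"s{i}") for i in range(n)],
    )


class TestDenver:
    def test_groups_partition_autosomes(self):
        all_chroms = [c for chroms in DENVER_GROUPS.values() for c in chroms]
        assert sorted(all_chroms, key=int) == [str(c) for c in range(1, 23)]
        assert denver_group("1") == "A"
        assert denver_group(18) == "E"
        assert denver_group("22") == "G"


class TestTailFilter:
    def test_interpolated_quantile_hand_computation(self):
        # Q(0.01) of 1..100 = 1.99, Q(0.99) = 99.01: keeps exactly {1, 100}
        weights = np.arange(1.0, 101.0)
        idx = tail_filter(weights, 0.01)
        assert sorted(weights[idx]) == [1.0, 100.0]

    def test_retention_close_to_two_tails(self, rng):
        w = rng.standard_normal(10_000)
        idx = tail_filter(w, 0.01)
        assert abs(len(idx) - 200) <= 50

    def test_symmetric_under_negation(self, rng):
        w = rng.standard_normal(501)
        a = set(tail_filter(w, 0.05))
        b = set(tail_filter(-w, 0.05))
        assert a == b

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            tail_filter(np.array([1.0, np.nan]), 0.1)


class TestRankPerChromosome:
    def test_few_candidates_all_kept(self):
        variants = [VariantRecord(f"v{j}", "5", j + 1, "A", "G") for j in range(3)]
        w = np.array([0.5, -2.0, 1.0])
        ranked = rank_per_chromosome(np.arange(3), w, variants, top_m=20)
        assert ranked["5"] == [1, 2, 0]  # by |weight| descending

    def test_truncates_at_top_m(self):
        variants = [VariantRecord(f"v{j}", "7", j + 1, "A", "G") for j in range(25)]
        w = np.linspace(0.1, 2.5, 25)
        ranked = rank_per_chromosome(np.arange(25), w, variants, top_m=20)
        assert len(ranked["7"]) == 20
        assert ranked["7"][0] == 24  # largest |weight| first

    def test_ties_break_by_position(self):
        variants = [
            VariantRecord("a", "3", 500, "A", "G"),
            VariantRecord("b", "3", 100, "A", "G"),
        ]
        w = np.array([1.5, -1.5])
        ranked = rank_per_chromosome(np.arange(2), w, variants, top_m=5)
        assert ranked["3"] == [1, 0]  # equal |weight|: lower position first


class TestPairwiseLd:
    def test_identical_vectors(self, rng):
        g = rng.integers(0, 3, size=(50, 1)).astype(float)
        cohort = make_cohort(np.hstack([g, g]), ["1", "2"])
        assert pairwise_ld_r2(cohort, 0, 1) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        cohort = make_cohort(
            np.array([[0, 2], [1, 1], [2, 0], [0, 2]], dtype=float), ["1", "2"]
        )
        assert pairwise_ld_r2(cohort, 0, 1) == pytest.approx(1.0)

    def test_constant_vector_errors(self):
        cohort = make_cohort(
            np.array([[1, 0], [1, 1], [1, 2]], dtype=float), ["1", "2"]
        )
        with pytest.raises(ValueError, match="constant"):
            pairwise_ld_r2(cohort, 0, 1)

    def test_independent_loci_mostly_uncorrelated(self, rng):
        g = rng.binomial(2, 0.4, size=(1000, 200)).astype(float)
        cohort = make_cohort(g, ["1"] * 200)
        small = [
            pairwise_ld_r2(cohort, 2 * k, 2 * k + 1) < 0.02 for k in range(100)
        ]
        assert np.mean(small) >= 0.95


def _toy_selection(seed, n_samples=500, duplicate_pair=True):
    # n_samples large enough that incidental r^2 between independent loci
    # stays far below the 0.05 pruning threshold; the planted duplicate is
    # then the only LD conflict and greedy allocation is provably optimal
    """12 candidates on chromosomes 1 (A), 6 (C), 21 (G) with distinct weights."""
    rng = np.random.default_rng(seed)
    chroms = ["1"] * 5 + ["6"] * 4 + ["21"] * 3
    g = rng.binomial(2, rng.uniform(0.2, 0.8, 12), size=(n_samples, 12)).astype(float)
    if duplicate_pair:
        g[:, 1] = g[:, 0]  # r^2 = 1 pair inside chromosome 1
    w = rng.normal(size=12)
    w += np.linspace(0, 1e-3, 12)  # enforce distinct |weights|
    cohort = make_cohort(g, chroms)
    ranked = rank_per_chromosome(np.arange(12), w, cohort.variants, top_m=20)
    return cohort, ranked, w


class TestAllocatePanel:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_oracle(self, seed):
        cohort, ranked, w = _toy_selection(seed)
        caps = {"A": 3, "B": 3, "C": 2, "D": 2, "E": 2, "F": 1, "G": 1}

        def ld(i, j):
            try:
                return pairwise_ld_r2(cohort, i, j)
            except ValueError:
                return 0.0

        chosen = allocate_panel(
            ranked, 6, caps, ld, ld_r2_max=0.05, require_all=True,
            variants=cohort.variants, weights=w,
        )
        caps_by_chrom = {"1": 3, "6": 2, "21": 1}
        best, best_sum = exhaustive_allocation(
            ranked, 6, caps_by_chrom, w, ld, 0.05, require_all=True
        )
        assert set(chosen) == best
        assert np.abs(w[chosen]).sum() == pytest.approx(best_sum)

    def test_duplicate_pair_yields_one_member(self):
        cohort, ranked, w = _toy_selection(7)

        def ld(i, j):
            try:
                return pairwise_ld_r2(cohort, i, j)
            except ValueError:
                return 0.0

        caps = {"A": 5, "B": 4, "C": 3, "D": 3, "E": 2, "F": 2, "G": 2}
        chosen = allocate_panel(
            ranked, 6, caps, ld, 0.05, True, cohort.variants, w
        )
        assert not ({0, 1} <= set(chosen))

    def test_size_equals_covered_chromosomes(self):
        cohort, ranked, w = _toy_selection(3, duplicate_pair=False)
        chosen = allocate_panel(
            ranked,
            3,
            {"A": 1, "B": 1, "C": 1, "D": 1, "E": 1, "F": 1, "G": 1},
            lambda i, j: 0.0,
            0.05,
            True,
            cohort.variants,
            w,
        )
        assert {cohort.variants[i].chromosome for i in chosen} == {"1", "6", "21"}
        # each is its chromosome's best
        for i in chosen:
            peers = ranked[cohort.variants[i].chromosome]
            assert i == peers[0]

    def test_infeasible_caps_raise(self):
        cohort, ranked, w = _toy_selection(5)
        with pytest.raises(InfeasibleSelectionError):
            allocate_panel(
                ranked,
                10,
                {"A": 1, "B": 1, "C": 1, "D": 1, "E": 1, "F": 1, "G": 1},
                lambda i, j: 0.0,
                0.05,
                True,
                cohort.variants,
                w,
            )

    def test_tightening_ld_never_increases_weight_sum(self):
        cohort, ranked, w = _toy_selection(11)

        def ld(i, j):
            try:
                return pairwise_ld_r2(cohort, i, j)
            except ValueError:
                return 0.0

        caps_by_chrom = {"1": 3, "6": 2, "21": 1}
        sums = []
        for r2max in (1.01, 0.3, 0.05):
            _, s = exhaustive_allocation(
                ranked, 5, caps_by_chrom, w, ld, r2max, require_all=True
            )
            sums.append(s)
        assert sums[0] >= sums[1] >= sums[2]


class TestSelectNestedPanels:
    def test_nested_chain_on_simulation(self, stratified_sim):
        panels = stratified_sim["panels"]
        assert [p.size for p in panels] == [16, 32]
        assert panels[0].is_nested_in(panels[1])
        assert panels[0].parent_panel is panels[1]
        # LD constraint holds pairwise within the largest panel
        cohort = stratified_sim["cohort"]
        ids = panels[1].variant_ids
        lookup = {v: i for i, v in enumerate(cohort.variant_ids)}
        idx = [lookup[i] for i in ids]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                assert pairwise_ld_r2(cohort, idx[a], idx[b]) < 0.05

    def test_all_chromosomes_covered_at_32(self, stratified_sim):
        panel32 = stratified_sim["panel32"]
        assert {v.chromosome for v in panel32.variants} == {
            str(c) for c in range(1, 23)
        }

    def test_deterministic(self, stratified_sim):
        cohort = stratified_sim["cohort"]
        gold = stratified_sim["gold"]
        cfg = SelectionConfig(panel_sizes=(16, 32), tail_quantile=0.02)
        a = select_nested_panels(cohort, gold, cfg)
        b = select_nested_panels(cohort, gold, cfg)
        assert [p.variant_ids for p in a] == [p.variant_ids for p in b]

    def test_selection_enriches_delta(self, stratified_sim):
        parental = stratified_sim["parental"]
        panel32 = stratified_sim["panel32"]
        deltas = compute_delta(panel32, "pop1", "pop2")
        genome_wide_mean = np.abs(parental[0] - parental[1]).mean()
        assert deltas.mean() > genome_wide_mean


class TestComputeDelta:
    def _panel(self, fa, fb):
        v = VariantRecord(
            "v", "1", 1, "A", "G", freq_parental={"EUR": fa, "NAT": fb}
        )
        return AIMPanel(variants=[v], weights=np.array([1.0]))

    def test_arithmetic(self):
        assert compute_delta(self._panel(0.95, 0.10), "EUR", "NAT")[0] == (
            pytest.approx(0.85)
        )

    def test_equal_freqs_zero(self):
        assert compute_delta(self._panel(0.4, 0.4), "EUR", "NAT")[0] == 0.0

    def test_symmetry_and_allele_swap_invariance(self):
        p = self._panel(0.9, 0.2)
        swapped = self._panel(1 - 0.9, 1 - 0.2)
        assert compute_delta(p, "EUR", "NAT")[0] == compute_delta(p, "NAT", "EUR")[0]
        assert compute_delta(p, "EUR", "NAT")[0] == pytest.approx(
            compute_delta(swapped, "EUR", "NAT")[0]
        )

    def test_missing_population_errors(self):
        with pytest.raises(ValueError, match="AFR"):
            compute_delta(self._panel(0.9, 0.2), "EUR", "AFR")
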