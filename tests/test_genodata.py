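import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aimkit.genodata import (
    MISSING,
    CohortDataset,
    EmptyCohortError,
    SampleRecord,
    VariantRecord,
    allele_freq,
    qc_filter,
    read_dosage_tsv,
    read_panel,
    read_plink,
    read_vcf,
    write_dosage_tsv,
    write_panel,
    write_plink,
)


def make_cohort(geno, chroms=None):
    geno = np.asarray(geno, dtype=float)
    n, m = geno.shape
    chroms = chroms or ["1"] * m
    variants = [
        VariantRecord(f"v{j}", chroms[j], 100 * (j + 1), "A", "G") for j in range(m)
    ]
    samples = [SampleRecord(sample_id=f"s{i}") for i in range(n)]
    return CohortDataset(genotypes=geno, variants=variants, samples=samples)


class TestDataModel:
    def test_rejects_non_autosomal_variant(self):
        with pytest.raises(ValueError, match="autosome"):
            VariantRecord("v", "X", 100, "A", "G")

    def test_rejects_identical_alleles(self):
        with pytest.raises(ValueError, match="alleles"):
            VariantRecord("v", "1", 100, "A", "A")

    def test_rejects_bad_dosage(self):
        with pytest.raises(ValueError, match="dosages"):
            make_cohort([[0, 3]])

    def test_rejects_duplicate_sample_ids(self):
        geno = np.zeros((2, 1))
        variants = [VariantRecord("v", "1", 1, "A", "G")]
        samples = [SampleRecord(sample_id="s"), SampleRecord(sample_id="s")]
        with pytest.raises(ValueError, match="unique"):
            CohortDataset(genotypes=geno, variants=variants, samples=samples)

    def test_subset_by_variant_ids_errors_on_absent(self):
        cohort = make_cohort([[0, 1], [1, 2], [2, 0]])
        with pytest.raises(KeyError, match="v9"):
            cohort.subset_by_variant_ids(["v0", "v9"])


class TestPlink:
    def test_roundtrip_with_missing(self, tmp_path, rng):
        geno = rng.integers(0, 3, size=(7, 5)).astype(float)
        geno[2, 3] = MISSING
        cohort = make_cohort(geno, chroms=["1", "2", "5", "11", "22"])
        write_plink(cohort, tmp_path / "toy")
        back = read_plink(tmp_path / "toy")
        np.testing.assert_array_equal(back.genotypes, geno)
        assert list(back.variant_ids) == list(cohort.variant_ids)
        assert list(back.chromosomes) == list(cohort.chromosomes)
        assert list(back.positions) == list(cohort.positions)
        assert list(back.sample_ids) == list(cohort.sample_ids)

    def test_small_fixture_shape(self, tmp_path):
        cohort = make_cohort([[0, 1], [1, 2], [2, 0]])
        write_plink(cohort, tmp_path / "t")
        assert read_plink(tmp_path / "t").genotypes.shape == (3, 2)

    def test_non_autosomal_variant_excluded(self, tmp_path, caplog):
        cohort = make_cohort([[0, 1, 2], [1, 1, 0], [2, 0, 1]])
        write_plink(cohort, tmp_path / "t")
        bim = (tmp_path / "t.bim").read_text().splitlines()
        bim[2] = bim[2].replace("1\tv2", "X\tv2", 1)
        (tmp_path / "t.bim").write_text("\n".join(bim) + "\n")
        import logging

        with caplog.at_level(logging.INFO):
            back = read_plink(tmp_path / "t")
        assert back.n_variants == 2
        assert "1 non-autosomal" in caplog.text


VCF_BODY = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
##contig=<ID=X>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1
1\t300\trs3\tG\tA,C\t.\tPASS\t.\tGT\t0/1\t0/0\t0/2
X\t400\trs4\tT\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
"""


class TestVcf:
    def test_read_vcf(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(VCF_BODY)
        with pytest.warns(UserWarning, match="multi-allelic"):
            cohort = read_vcf(path)
        # tri-allelic rs3 skipped, chrX rs4 excluded
        assert list(cohort.variant_ids) == ["rs1", "rs2"]
        np.testing.assert_array_equal(cohort.genotypes[:, 0], [0, 1, 2])
        assert np.isnan(cohort.genotypes[0, 1])
        # ALT is the counted allele
        assert cohort.variants[0].counted_allele == "G"


class TestQcFilter:
    def test_variant_at_exact_missing_threshold_removed(self):
        # 1 of 50 calls missing = exactly 2%: inclusive cut removes variant 0,
        # while the affected sample (1/60 missing) survives the sample filter
        geno = np.tile(np.arange(60) % 2, (50, 1)).astype(float)
        geno[::2, :] = 2.0 - geno[::2, :]  # keep every variant polymorphic
        geno[0, 0] = MISSING
        filtered, report = qc_filter(make_cohort(geno))
        assert report.n_samples_removed == 0
        assert report.n_variants_removed_missing == 1
        assert "v0" not in filtered.variant_ids

    def test_maf_boundary(self):
        # 500 samples: dosage sums 9 and 10 give MAF 0.009 (drop), 0.010 (keep)
        geno = np.zeros((500, 3))
        geno[:9, 0] = 1.0
        geno[:10, 1] = 1.0
        geno[:250, 2] = 2.0
        filtered, report = qc_filter(make_cohort(geno))
        assert list(filtered.variant_ids) == ["v1", "v2"]
        assert report.n_variants_removed_maf == 1

    def test_clean_cohort_unchanged(self, rng):
        geno = rng.integers(0, 3, size=(40, 6)).astype(float)
        geno[:20] = 0.0
        geno[20:] = 2.0  # every variant at MAF 0.5
        cohort = make_cohort(geno)
        filtered, report = qc_filter(cohort)
        np.testing.assert_array_equal(filtered.genotypes, cohort.genotypes)
        assert (
            report.n_samples_removed
            == report.n_variants_removed_missing
            == report.n_variants_removed_maf
            == 0
        )

    def test_sample_filter_precedes_variant_filter(self):
        # one terrible sample is the sole source of variant missingness:
        # removing it first rescues every variant
        geno = np.tile([0.0, 2.0], (30, 5))[:30, :5] % 3
        geno = np.ones((30, 5))
        geno[::2] = 2.0
        geno[1::2] = 0.0
        geno[0, :] = MISSING
        filtered, report = qc_filter(make_cohort(geno))
        assert report.n_samples_removed == 1
        assert report.n_variants_removed_missing == 0
        assert filtered.n_variants == 5

    def test_idempotent(self, rng):
        geno = rng.integers(0, 3, size=(60, 30)).astype(float)
        mask = rng.random(geno.shape) < 0.03
        geno[mask] = MISSING
        once, _ = qc_filter(make_cohort(geno))
        twice, report = qc_filter(once)
        np.testing.assert_array_equal(once.genotypes, twice.genotypes)
        assert report.n_samples_removed == 0
        assert report.n_variants_removed_missing == 0
        assert report.n_variants_removed_maf == 0

    def test_all_variants_removed_raises(self):
        geno = np.zeros((20, 2))  # monomorphic: MAF 0 everywhere
        with pytest.raises(EmptyCohortError):
            qc_filter(make_cohort(geno))


class TestAlleleFreq:
    @pytest.mark.parametrize(
        "dosages, expected",
        [
            ([0, 1, 2], 0.5),
            ([2, 2, MISSING], 1.0),
            ([0, 0, 1, 1], 0.25),
        ],
    )
    def test_hand_counts(self, dosages, expected):
        cohort = make_cohort(np.array(dosages, dtype=float)[:, None])
        assert allele_freq(cohort)[0] == pytest.approx(expected)

    def test_zero_calls_error_names_variant(self):
        cohort = make_cohort([[MISSING], [MISSING]])
        with pytest.raises(ValueError, match="v0"):
            allele_freq(cohort)

    def test_sample_subset_by_id(self):
        cohort = make_cohort([[0], [2], [2]])
        assert allele_freq(cohort, ["s1", "s2"])[0] == 1.0

    @given(
        st.integers(2, 20),
        st.integers(1, 8),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_complement_symmetry(self, n, m, seed):
        # swapping the counted allele (g -> 2 - g) complements the frequency
        g = np.random.default_rng(seed).integers(0, 3, size=(n, m)).astype(float)
        f = allele_freq(make_cohort(g))
        f_swapped = allele_freq(make_cohort(2.0 - g))
        np.testing.assert_allclose(f + f_swapped, 1.0, atol=1e-12)


class TestDosageTsv:
    def test_roundtrip(self, tmp_path, rng):
        geno = rng.integers(0, 3, size=(9, 4)).astype(float)
        geno[1, 2] = MISSING
        cohort = make_cohort(geno)
        write_dosage_tsv(cohort, tmp_path / "d.tsv")
        back = read_dosage_tsv(tmp_path / "d.tsv")
        np.testing.assert_array_equal(back.genotypes, geno)
        assert list(back.variant_ids) == list(cohort.variant_ids)
        assert list(back.sample_ids) == list(cohort.sample_ids)


class TestPanelTsv:
    def _panel(self, n=32, with_freqs=True):
        from aimkit.aim_select import AIMPanel

        rng = np.random.default_rng(7)
        variants = []
        for j in range(n):
            freqs = None
            if with_freqs:
                f = rng.uniform(0.05, 0.95)
                freqs = {"EUR": round(f, 4), "NAT": round(1 - f, 4)}
            variants.append(
                VariantRecord(
                    f"rs{j}", str(j % 22 + 1), 1000 + j, "A", "G", freq_parental=freqs
                )
            )
        return AIMPanel(variants=variants, weights=rng.normal(size=n))

    def test_row_count(self, tmp_path):
        write_panel(self._panel(), tmp_path / "p.tsv")
        lines = (tmp_path / "p.tsv").read_text().splitlines()
        assert len(lines) == 33  # header + 32 rows

    def test_roundtrip(self, tmp_path):
        panel = self._panel()
        write_panel(panel, tmp_path / "p.tsv")
        back = read_panel(tmp_path / "p.tsv")
        assert back.variant_ids == panel.variant_ids
        np.testing.assert_allclose(back.weights, panel.weights)
        for a, b in zip(back.variants, panel.variants):
            assert a.freq_parental == pytest.approx(b.freq_parental)
            assert (a.chromosome, a.position) == (b.chromosome, b.position)

    def test_missing_freqs_gives_na_delta(self, tmp_path):
        import pandas as pd

        with pytest.warns(UserWarning, match="delta"):
            write_panel(self._panel(with_freqs=False), tmp_path / "p.tsv")
        df = pd.read_csv(tmp_path / "p.tsv", sep="\t")
        assert df["delta"].isna().all()
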