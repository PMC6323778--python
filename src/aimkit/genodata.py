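"""Genotype data model, file I/O and quality control.

The universal carrier is :class:`CohortDataset`: an individuals x variants
dosage matrix (counted-allele dosage 0/1/2, ``numpy.nan`` for missing calls)
plus ordered variant and sample tables. Readers exist for PLINK
.bed/.bim/.fam triples, VCF (GT field, via cyvcf2) and a plain dosage TSV.
Only autosomal bi-allelic variants are retained; anything else is dropped
with a logged count.

QC follows the conventional array pipeline: drop samples with >= 2% missing
calls, then variants with >= 2% missing calls, then variants with minor
allele frequency below 1% — thresholds inclusive at the missing-rate cut.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "AUTOSOMES",
    "FormatError",
    "EmptyCohortError",
    "VariantRecord",
    "SampleRecord",
    "CohortDataset",
    "QCReport",
    "read_plink",
    "write_plink",
    "read_vcf",
    "qc_filter",
    "allele_freq",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "write_panel",
    "read_panel",
]

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call (dosage matrices are float arrays).
MISSING = np.nan

#: Human autosome labels accepted in variant tables.
AUTOSOMES = tuple(str(c) for c in range(1, 23))


class FormatError(ValueError):
    """A genotype file is malformed or internally inconsistent."""


class EmptyCohortError(ValueError):
    """A filtering step removed every variant (or every sample)."""


@dataclass
class VariantRecord:
    """One bi-allelic autosomal SNP.

    ``freq_parental`` maps a parental-population label to the frequency of
    the counted allele in that population (used for delta computation).
    """

    variant_id: str
    chromosome: str
    position: int
    counted_allele: str
    other_allele: str
    freq_parental: Optional[dict] = None

    def __post_init__(self) -> None:
        self.chromosome = str(self.chromosome)
        if self.chromosome not in AUTOSOMES:
            raise ValueError(
                f"variant {self.variant_id}: chromosome {self.chromosome!r} "
                "is not an autosome ('1'..'22')"
            )
        if self.position < 1:
            raise ValueError(f"variant {self.variant_id}: position must be >= 1")
        if self.counted_allele == self.other_allele:
            raise ValueError(f"variant {self.variant_id}: alleles identical")
        if self.freq_parental is not None:
            for pop, f in self.freq_parental.items():
                if not (0.0 <= f <= 1.0):
                    raise ValueError(
                        f"variant {self.variant_id}: frequency {f} for "
                        f"population {pop!r} outside [0, 1]"
                    )


@dataclass
class SampleRecord:
    """One individual: identifiers, phenotypes, covariates and labels."""

    sample_id: str
    sex: Optional[str] = None
    phenotype_binary: Optional[int] = None
    phenotype_quantitative: Optional[float] = None
    covariates: dict = field(default_factory=dict)
    region_label: Optional[str] = None
    population_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.phenotype_binary is not None and self.phenotype_binary not in (0, 1):
            raise ValueError(
                f"sample {self.sample_id}: binary phenotype must be 0/1"
            )


@dataclass
class CohortDataset:
    """Dosage matrix plus aligned variant and sample tables.

    ``genotypes`` is a float array of shape (n_samples, n_variants) with
    entries in {0, 1, 2} or ``nan`` for missing.
    """

    genotypes: np.ndarray
    variants: list
    samples: list

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        n, m = self.genotypes.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        finite = self.genotypes[np.isfinite(self.genotypes)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be in {0, 1, 2}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id values must be unique within a cohort")

    # -- convenience views -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        return np.array([s.sample_id for s in self.samples])

    @property
    def variant_ids(self) -> np.ndarray:
        return np.array([v.variant_id for v in self.variants])

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([v.chromosome for v in self.variants])

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.position for v in self.variants], dtype=int)

    def variants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "chromosome": self.chromosomes,
                "position": self.positions,
                "counted_allele": [v.counted_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
            }
        )

    def subset_samples(self, index: Union[Sequence[int], np.ndarray]) -> "CohortDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CohortDataset(
            genotypes=self.genotypes[index, :],
            variants=list(self.variants),
            samples=[self.samples[i] for i in index],
        )

    def subset_variants(self, index: Union[Sequence[int], np.ndarray]) -> "CohortDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CohortDataset(
            genotypes=self.genotypes[:, index],
            variants=[self.variants[i] for i in index],
            samples=list(self.samples),
        )

    def subset_by_variant_ids(self, ids: Iterable[str]) -> "CohortDataset":
        """Subset to the given variant ids, in the given order.

        Raises ``KeyError`` listing every id absent from the cohort — a
        requested marker is never silently replaced by a proxy.
        """
        lookup = {v.variant_id: i for i, v in enumerate(self.variants)}
        ids = list(ids)
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise KeyError(f"variants absent from cohort: {missing}")
        return self.subset_variants([lookup[i] for i in ids])


@dataclass
class QCReport:
    """Counts of removals performed by :func:`qc_filter`."""

    n_samples_removed: int
    n_variants_removed_missing: int
    n_variants_removed_maf: int
    thresholds_used: dict

    def __post_init__(self) -> None:
        if min(
            self.n_samples_removed,
            self.n_variants_removed_missing,
            self.n_variants_removed_maf,
        ) < 0:
            raise ValueError("removal counts must be non-negative")


# ---------------------------------------------------------------------------
# PLINK .bed/.bim/.fam
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"  # SNP-major bed

# 2-bit codes -> dosage of allele 1 (the counted allele).
_BED_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: MISSING, 0b10: 1.0, 0b11: 0.0}
_DOSAGE_TO_BED_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def read_plink(prefix: Union[str, Path]) -> CohortDataset:
    """Read a PLINK .bed/.bim/.fam triple (SNP-major bed).

    Dosage counts .bim allele 1. Non-autosomal variants are excluded with a
    logged count; missing calls become ``nan``.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chromosome", "variant_id", "cm", "position", "allele1", "allele2"],
        dtype={"chromosome": str, "variant_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not SNP-major bed)")
    bytes_per_variant = (n + 3) // 4
    if len(raw) - 3 != bytes_per_variant * m:
        raise FormatError(
            f"{prefix}.bed: size {len(raw) - 3} does not match "
            f"{n} samples x {m} variants"
        )
    codes = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_variant)
    # unpack 2-bit fields, sample index runs along bit pairs within a byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    two_bit = two_bit.reshape(m, -1)[:, :n]
    lut = np.array(
        [_BED_CODE_TO_DOSAGE[c] for c in range(4)], dtype=float
    )
    geno = lut[two_bit].T  # samples x variants

    keep = bim["chromosome"].isin(AUTOSOMES).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_plink: excluded %d non-autosomal variant(s)", n_dropped)
    bim = bim.loc[keep].reset_index(drop=True)
    geno = geno[:, keep]

    variants = [
        VariantRecord(
            variant_id=r.variant_id,
            chromosome=r.chromosome,
            position=int(r.position),
            counted_allele=r.allele1,
            other_allele=r.allele2,
        )
        for r in bim.itertuples()
    ]
    sex_map = {1: "male", 2: "female"}
    samples = []
    for r in fam.itertuples():
        # PLINK phenotype column: 1/2 = control/case, -9/0 = missing,
        # anything else is a quantitative trait value
        pheno = float(r.phenotype)
        binary = quant = None
        if pheno == 1.0:
            binary = 0
        elif pheno == 2.0:
            binary = 1
        elif pheno not in (-9.0, 0.0):
            quant = pheno
        samples.append(
            SampleRecord(
                sample_id=r.iid,
                sex=sex_map.get(r.sex),
                phenotype_binary=binary,
                phenotype_quantitative=quant,
            )
        )
    return CohortDataset(genotypes=geno, variants=variants, samples=samples)


def write_plink(cohort: CohortDataset, prefix: Union[str, Path]) -> None:
    """Write a cohort as a PLINK .bed/.bim/.fam triple (SNP-major)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in cohort.variants:
            fh.write(
                f"{v.chromosome}\t{v.variant_id}\t0\t{v.position}"
                f"\t{v.counted_allele}\t{v.other_allele}\n"
            )
    sex_code = {"male": 1, "female": 2}
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in cohort.samples:
            if s.phenotype_binary is not None:
                pheno = str(s.phenotype_binary + 1)  # PLINK 1/2 coding
            elif s.phenotype_quantitative is not None:
                pheno = repr(s.phenotype_quantitative)
            else:
                pheno = "-9"
            fh.write(
                f"{s.sample_id} {s.sample_id} 0 0 {sex_code.get(s.sex, 0)} {pheno}\n"
            )
    n, m = cohort.n_samples, cohort.n_variants
    bytes_per_variant = (n + 3) // 4
    geno = cohort.genotypes
    two_bit = np.full((m, bytes_per_variant * 4), 0b00, dtype=np.uint8)
    col = geno.T  # variants x samples
    code = np.where(
        np.isnan(col),
        0b01,
        np.select([col == 2.0, col == 1.0, col == 0.0], [0b00, 0b10, 0b11]),
    ).astype(np.uint8)
    two_bit[:, :n] = code
    packed = (
        two_bit.reshape(m, bytes_per_variant, 4)
        << np.array([0, 2, 4, 6], dtype=np.uint8)[None, None, :]
    )
    packed = np.bitwise_or.reduce(packed, axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: Union[str, Path]) -> CohortDataset:
    """Read a VCF (v4.x, GT field) into a cohort; dosage counts the ALT allele.

    Multi-allelic and non-autosomal records are skipped with a warning/log.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    variants: list = []
    rows: list = []
    n_multi = 0
    n_nonauto = 0
    saw_gt = False
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        chrom = rec.CHROM.removeprefix("chr")
        if chrom not in AUTOSOMES:
            n_nonauto += 1
            continue
        gt = rec.gt_types  # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        saw_gt = True
        dose = gt.astype(float)
        dose[gt == 3] = MISSING
        rows.append(dose)
        variants.append(
            VariantRecord(
                variant_id=rec.ID or f"{chrom}:{rec.POS}",
                chromosome=chrom,
                position=rec.POS,
                counted_allele=rec.ALT[0],
                other_allele=rec.REF,
            )
        )
    if variants and not saw_gt:
        raise FormatError(f"{path}: no GT genotypes found")
    if n_multi:
        warnings.warn(f"{path}: skipped {n_multi} multi-allelic record(s)")
    if n_nonauto:
        logger.info("read_vcf: excluded %d non-autosomal record(s)", n_nonauto)
    geno = (
        np.array(rows, dtype=float).T
        if rows
        else np.empty((len(sample_ids), 0))
    )
    samples = [SampleRecord(sample_id=s) for s in sample_ids]
    return CohortDataset(genotypes=geno, variants=variants, samples=samples)


# ---------------------------------------------------------------------------
# QC and allele frequencies
# ---------------------------------------------------------------------------


def qc_filter(
    cohort: CohortDataset,
    max_missing_rate: float = 0.02,
    min_maf: float = 0.01,
) -> tuple[CohortDataset, QCReport]:
    """Apply the standard array QC: sample missingness, variant missingness, MAF.

    Order is fixed for determinism: (1) samples with missing rate >=
    ``max_missing_rate`` are dropped, (2) then variants with missing rate >=
    ``max_missing_rate``, (3) then variants with MAF < ``min_maf`` computed on
    the remaining samples. Thresholds are inclusive at the missing-rate cut
    and exclusive at the MAF cut.
    """
    if not (0 < max_missing_rate < 1) or not (0 < min_maf < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    geno = cohort.genotypes
    miss = np.isnan(geno)

    sample_keep = miss.mean(axis=1) < max_missing_rate
    n_samples_removed = int((~sample_keep).sum())
    geno = geno[sample_keep]
    miss = miss[sample_keep]
    if geno.shape[0] == 0:
        raise EmptyCohortError("sample missingness filter removed every sample")

    var_keep_miss = miss.mean(axis=0) < max_missing_rate
    n_removed_missing = int((~var_keep_miss).sum())
    geno2 = geno[:, var_keep_miss]

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(geno2, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    var_keep_maf = maf >= min_maf
    n_removed_maf = int((~var_keep_maf).sum())

    variant_index = np.flatnonzero(var_keep_miss)[var_keep_maf]
    if variant_index.size == 0:
        raise EmptyCohortError("QC removed every variant")

    filtered = CohortDataset(
        genotypes=geno[:, variant_index],
        variants=[cohort.variants[i] for i in variant_index],
        samples=[s for s, k in zip(cohort.samples, sample_keep) if k],
    )
    report = QCReport(
        n_samples_removed=n_samples_removed,
        n_variants_removed_missing=n_removed_missing,
        n_variants_removed_maf=n_removed_maf,
        thresholds_used={"max_missing_rate": max_missing_rate, "min_maf": min_maf},
    )
    return filtered, report


def allele_freq(
    cohort: CohortDataset,
    sample_subset: Optional[Union[Sequence[int], Sequence[str], np.ndarray]] = None,
) -> np.ndarray:
    """Counted-allele frequency per variant: sum(dosages) / (2 * n non-missing).

    ``sample_subset`` may be integer indices, a boolean mask or sample ids.
    """
    geno = cohort.genotypes
    if sample_subset is not None:
        subset = np.asarray(sample_subset)
        if subset.dtype == bool:
            idx = np.flatnonzero(subset)
        elif subset.dtype.kind in "iu":
            idx = subset
        else:
            lookup = {s.sample_id: i for i, s in enumerate(cohort.samples)}
            idx = np.array([lookup[s] for s in subset])
        geno = geno[idx, :]
    n_obs = np.sum(~np.isnan(geno), axis=0)
    if (n_obs == 0).any():
        bad = cohort.variant_ids[n_obs == 0]
        raise ValueError(f"no non-missing calls for variant(s): {list(bad)}")
    return np.nansum(geno, axis=0) / (2.0 * n_obs)


# ---------------------------------------------------------------------------
# Dosage TSV (plain-text interchange)
# ---------------------------------------------------------------------------


def write_dosage_tsv(cohort: CohortDataset, path: Union[str, Path]) -> None:
    """Write the dosage matrix as TSV: header ``sample_id`` then variant ids."""
    df = pd.DataFrame(cohort.genotypes, columns=cohort.variant_ids)
    df.insert(0, "sample_id", cohort.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%g")


def read_dosage_tsv(
    path: Union[str, Path], variants: Optional[list] = None
) -> CohortDataset:
    """Read a dosage TSV written by :func:`write_dosage_tsv`.

    The TSV carries dosages only; pass ``variants`` to attach real metadata,
    otherwise placeholder records (chromosome "1", sequential positions) are
    created.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id'")
    sample_ids = df["sample_id"].astype(str).tolist()
    geno = df.drop(columns="sample_id").to_numpy(dtype=float)
    ids = [str(c) for c in df.columns[1:]]
    if variants is None:
        variants = [
            VariantRecord(vid, "1", j + 1, "A", "B") for j, vid in enumerate(ids)
        ]
    else:
        if [v.variant_id for v in variants] != ids:
            raise FormatError(f"{path}: variant ids do not match supplied metadata")
    return CohortDataset(
        genotypes=geno,
        variants=variants,
        samples=[SampleRecord(sample_id=s) for s in sample_ids],
    )


# ---------------------------------------------------------------------------
# AIM panel TSV
# ---------------------------------------------------------------------------


def write_panel(panel, path: Union[str, Path]) -> None:
    """Write an AIM panel as TSV (variant metadata, weight, parental freqs, delta).

    Column layout: variant_id, chromosome, position, counted_allele,
    other_allele, weight, freq_<POP> per parental population, delta. Without
    parental frequencies the delta column is written as NA with a warning.
    """
    if panel.size == 0:
        raise ValueError("refusing to write an empty panel")
    pops: list[str] = []
    for v in panel.variants:
        if v.freq_parental:
            for p in v.freq_parental:
                if p not in pops:
                    pops.append(p)
    rows = []
    have_freqs = len(pops) >= 2
    if not have_freqs:
        warnings.warn("panel lacks parental frequencies; delta written as NA")
    for v, w in zip(panel.variants, panel.weights):
        row = {
            "variant_id": v.variant_id,
            "chromosome": v.chromosome,
            "position": v.position,
            "counted_allele": v.counted_allele,
            "other_allele": v.other_allele,
            "weight": w,
        }
        for p in pops:
            row[f"freq_{p}"] = (v.freq_parental or {}).get(p, np.nan)
        if have_freqs:
            f = [(v.freq_parental or {}).get(p, np.nan) for p in pops[:2]]
            row["delta"] = abs(f[0] - f[1])
        else:
            row["delta"] = np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_panel(path: Union[str, Path]):
    """Read a panel TSV written by :func:`write_panel` back into an AIMPanel."""
    from .aim_select import AIMPanel

    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    pops = [c.removeprefix("freq_") for c in df.columns if c.startswith("freq_")]
    variants = []
    for r in df.itertuples():
        freqs = {
            p: getattr(r, f"freq_{p}")
            for p in pops
            if np.isfinite(getattr(r, f"freq_{p}"))
        }
        variants.append(
            VariantRecord(
                variant_id=str(r.variant_id),
                chromosome=str(r.chromosome),
                position=int(r.position),
                counted_allele=str(r.counted_allele),
                other_allele=str(r.other_allele),
                freq_parental=freqs or None,
            )
        )
    return AIMPanel(variants=variants, weights=df["weight"].to_numpy(dtype=float))
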