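"""Variant- and sample-level quality control for case-control genotype data.

Variant filters (each applied to every variant, one pass):

* call rate below a minimum (default 99%);
* minor allele frequency (MAF) below a minimum (default 5%);
* Hardy-Weinberg equilibrium (HWE) chi-square p-value below a minimum
  (default 1e-4).

Sample filters (one pass, after variant filtering in :func:`apply_qc`):

* missing genotyping rate above a maximum (default 5%);
* heterozygosity rate more than ``het_sd`` (default 3) standard deviations
  from the cohort mean, with mean/SD computed once on the pre-removal cohort.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .data import MISSING, Dataset, PhenotypeVector

__all__ = [
    "VariantQCStats",
    "SampleQCStats",
    "variant_stats",
    "sample_stats",
    "hwe_test",
    "filter_variants",
    "filter_samples",
    "apply_qc",
]


@dataclasses.dataclass
class VariantQCStats:
    """Per-variant call rate, MAF and HWE p-value."""

    variant_ids: list[str]
    call_rate: np.ndarray
    maf: np.ndarray
    hwe_p: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"call_rate": self.call_rate, "maf": self.maf, "hwe_p": self.hwe_p},
            index=self.variant_ids,
        )


@dataclasses.dataclass
class SampleQCStats:
    """Per-sample missing rate and heterozygosity rate."""

    subject_ids: list[str]
    missing_rate: np.ndarray
    het_rate: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"missing_rate": self.missing_rate, "het_rate": self.het_rate},
            index=self.subject_ids,
        )


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value against HWE proportions.

    Expected counts are n*(p^2, 2pq, q^2) with p the sample reference-allele
    frequency. Monomorphic variants return 1.0 by convention.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n <= 0:
        raise ValueError("hwe_test requires at least one genotyped sample")
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    statistic = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(statistic, df=1))


def variant_stats(dataset: Dataset) -> VariantQCStats:
    """Call rate, MAF and HWE p-value for every variant.

    A variant with zero non-missing calls gets NaN maf/hwe_p; it necessarily
    fails the call-rate filter downstream.
    """
    codes = dataset.genotypes.codes
    if codes.shape[0] == 0:
        raise ValueError("variant_stats requires at least one subject")
    observed = codes != MISSING
    n_obs = observed.sum(axis=0)
    call_rate = n_obs / codes.shape[0]

    m = codes.shape[1]
    maf = np.full(m, np.nan)
    hwe_p = np.full(m, np.nan)
    for j in range(m):
        if n_obs[j] == 0:
            continue
        col = codes[observed[:, j], j]
        alt_freq = col.sum() / (2 * n_obs[j])
        maf[j] = min(alt_freq, 1.0 - alt_freq)
        counts = np.bincount(col, minlength=3)
        hwe_p[j] = hwe_test(int(counts[0]), int(counts[1]), int(counts[2]))
    return VariantQCStats(list(dataset.variant_ids), call_rate, maf, hwe_p)


def sample_stats(dataset: Dataset) -> SampleQCStats:
    codes = dataset.genotypes.codes
    observed = codes != MISSING
    n_obs = observed.sum(axis=1)
    missing_rate = 1.0 - n_obs / codes.shape[1] if codes.shape[1] else np.zeros(len(n_obs))
    with np.errstate(invalid="ignore"):
        het_rate = np.where(n_obs > 0, (codes == 1).sum(axis=1) / np.maximum(n_obs, 1), 0.0)
    return SampleQCStats(list(dataset.subject_ids), missing_rate, het_rate)


def filter_variants(
    dataset: Dataset,
    min_call_rate: float = 0.99,
    min_maf: float = 0.05,
    min_hwe_p: float = 1e-4,
) -> tuple[Dataset, pd.DataFrame]:
    """Remove variants failing any filter; return the dataset and a report.

    The report lists each removed variant with the rules it failed and its
    statistics. Surviving genotype values are untouched.
    """
    st = variant_stats(dataset)
    fail_call = st.call_rate < min_call_rate
    with np.errstate(invalid="ignore"):
        fail_maf = np.nan_to_num(st.maf, nan=0.0) < min_maf
        fail_hwe = np.nan_to_num(st.hwe_p, nan=1.0) < min_hwe_p
    removed = fail_call | fail_maf | fail_hwe
    rows = []
    for j in np.flatnonzero(removed):
        rules = [
            name
            for name, flag in (("call_rate", fail_call[j]), ("maf", fail_maf[j]), ("hwe", fail_hwe[j]))
            if flag
        ]
        rows.append(
            {
                "id": st.variant_ids[j],
                "failed_rules": ";".join(rules),
                "call_rate": st.call_rate[j],
                "maf": st.maf[j],
                "hwe_p": st.hwe_p[j],
            }
        )
    report = pd.DataFrame(rows, columns=["id", "failed_rules", "call_rate", "maf", "hwe_p"])
    keep = [v for v, r in zip(dataset.variant_ids, removed) if not r]
    if not keep:
        import warnings

        warnings.warn("all variants removed by QC filters", stacklevel=2)
    return dataset.subset_variants(keep), report


def filter_samples(
    dataset: Dataset,
    max_missing: float = 0.05,
    het_sd: float = 3.0,
) -> tuple[Dataset, pd.DataFrame]:
    """Remove samples with high missingness or outlying heterozygosity.

    The heterozygosity mean/SD are computed once over all samples before any
    removal; a zero SD disables the heterozygosity rule.
    """
    if dataset.n_subjects < 2:
        raise ValueError("filter_samples requires at least two subjects")
    st = sample_stats(dataset)
    fail_miss = st.missing_rate > max_missing
    mu = float(st.het_rate.mean())
    sd = float(st.het_rate.std(ddof=0))
    if sd > 0:
        fail_het = np.abs(st.het_rate - mu) > het_sd * sd
    else:
        fail_het = np.zeros(len(st.het_rate), dtype=bool)
    removed = fail_miss | fail_het
    rows = []
    for i in np.flatnonzero(removed):
        rules = [
            name for name, flag in (("missing", fail_miss[i]), ("heterozygosity", fail_het[i])) if flag
        ]
        rows.append(
            {
                "id": st.subject_ids[i],
                "failed_rules": ";".join(rules),
                "missing_rate": st.missing_rate[i],
                "het_rate": st.het_rate[i],
            }
        )
    report = pd.DataFrame(rows, columns=["id", "failed_rules", "missing_rate", "het_rate"])
    keep_rows = np.flatnonzero(~removed)
    return dataset.subset_subjects(keep_rows), report


def apply_qc(
    dataset: Dataset,
    min_call_rate: float = 0.99,
    min_maf: float = 0.05,
    min_hwe_p: float = 1e-4,
    max_missing: float = 0.05,
    het_sd: float = 3.0,
) -> tuple[Dataset, pd.DataFrame, pd.DataFrame]:
    """Variant filters followed by sample filters, each in a single pass."""
    ds, variant_report = filter_variants(dataset, min_call_rate, min_maf, min_hwe_p)
    ds, sample_report = filter_samples(ds, max_missing, het_sd)
    return ds, variant_report, sample_report
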