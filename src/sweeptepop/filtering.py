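"""Variant curation: per-site allele statistics and threshold filters.

The curation rules mirror standard resequencing practice for structured
cohorts: drop sites with minor allele frequency below 0.05, observed
heterozygosity above 0.1 (in a predominantly selfing species high
heterozygosity flags paralogous mis-mapping rather than true
heterozygotes), and fewer than 40 genotyped samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import GenotypeMatrix


@dataclass
class SiteStatsTable:
    """Vectorized per-site statistics.

    maf and obs_het are NaN for sites with zero genotyped accessions
    (such sites automatically fail every filter).
    """

    n_genotyped: np.ndarray
    maf: np.ndarray
    obs_het: np.ndarray


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_excluded: int
    by_rule: dict[str, int] = field(default_factory=dict)


def site_stats(matrix: GenotypeMatrix) -> SiteStatsTable:
    """MAF, observed heterozygosity and genotyped count per site.

    Allele counts come from genotyped diploids only: a heterozygote
    contributes one copy of each allele.
    """
    if matrix.n_sites == 0:
        raise ValueError("empty genotype matrix")
    g = matrix.genotypes
    genotyped = g >= 0
    n_genotyped = genotyped.sum(axis=0)
    alt = np.where(genotyped, g, 0).sum(axis=0)
    total = 2 * n_genotyped
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = alt / total
        maf = np.minimum(p_alt, 1.0 - p_alt)
        obs_het = (g == 1).sum(axis=0) / n_genotyped
    maf = np.where(n_genotyped == 0, np.nan, maf)
    obs_het = np.where(n_genotyped == 0, np.nan, obs_het)
    return SiteStatsTable(n_genotyped=n_genotyped, maf=maf, obs_het=obs_het)


def filter_variants(
    matrix: GenotypeMatrix,
    min_maf: float = 0.05,
    max_het: float = 0.1,
    min_genotyped: int = 40,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the MAF / heterozygosity / genotyped-count curation rules.

    A site is kept iff maf >= min_maf, obs_het <= max_het and
    n_genotyped >= min_genotyped. The report counts exclusions per rule
    (a site failing several rules is counted once under each) and once in
    total. Sites with zero genotyped accessions fail unconditionally.
    """
    if min_genotyped > matrix.n_accessions:
        raise ValueError(
            f"min_genotyped={min_genotyped} exceeds cohort size "
            f"{matrix.n_accessions}")
    stats = site_stats(matrix)
    no_data = stats.n_genotyped == 0
    with np.errstate(invalid="ignore"):
        fail_maf = ~no_data & (stats.maf < min_maf)
        fail_het = ~no_data & (stats.obs_het > max_het)
    fail_n = ~no_data & (stats.n_genotyped < min_genotyped)
    keep = ~(no_data | fail_maf | fail_het | fail_n)
    report = FilterReport(
        n_input=matrix.n_sites,
        n_kept=int(keep.sum()),
        n_excluded=int((~keep).sum()),
        by_rule={
            "maf": int(fail_maf.sum()),
            "het": int(fail_het.sum()),
            "n_genotyped": int(fail_n.sum()),
            "no_data": int(no_data.sum()),
        },
    )
    return matrix.take_sites(keep), report
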