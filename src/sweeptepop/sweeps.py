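"""Sweep calling from window/gene statistics and XP-CLR scores, plus the
three-approach consensus.

Three independent routes flag candidate domestication sweeps per gene
pool: (1) imported XP-CLR window scores thresholded at a normalized
value >= 5; (2) sliding windows jointly in the top decile of the
diversity-reduction ratio and of FST; (3) genes jointly in the bottom
decile of (domesticated) diversity and top decile of FST. Windows map to
genes by >=1 bp overlap; the consensus intersects the per-approach gene
lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import XPCLRTable
from .types import GeneModel


@dataclass
class SweepCallSet:
    approach: str  # xpclr | window | gene
    pool: str  # AI | MI
    windows: pd.DataFrame  # called windows/genes with triggering statistics
    regions: list[tuple[str, int, int]]  # merged called regions
    gene_ids: set[str] = field(default_factory=set)
    thresholds: dict = field(default_factory=dict)


def merge_regions(intervals) -> list[tuple[str, int, int]]:
    """Union of half-open intervals; overlapping or bookended intervals
    merge into one region."""
    out: list[list] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1][2] = max(out[-1][2], end)
        else:
            out.append([chrom, start, end])
    return [tuple(x) for x in out]


def call_sweeps_xpclr(table: XPCLRTable, pool: str,
                      cutoff: float = 5.0) -> SweepCallSet:
    """Windows with normalized XP-CLR score >= cutoff (boundary inclusive),
    merged into regions."""
    df = table.df
    called = df[df.normalized_score >= cutoff].copy()
    regions = merge_regions(
        zip(called.chrom, called.window_start, called.window_end))
    return SweepCallSet(approach="xpclr", pool=pool, windows=called,
                        regions=regions, thresholds={"cutoff": cutoff})


def call_sweeps_window(stats: pd.DataFrame, pool: str,
                       q: float = 0.10) -> SweepCallSet:
    """Windows in the top q-fraction of BOTH the diversity-reduction
    ratio and FST (type-7 quantiles; ties at the cutoff included).

    Windows with undefined pi_reduction or FST are excluded from the
    ranking population and from the callable set.
    """
    usable = stats[np.isfinite(stats.pi_reduction)
                   & np.isfinite(stats.fst)].copy()
    if len(usable) < 10:
        raise ValueError(f"only {len(usable)} usable windows; need >= 10")
    pi_thr = float(np.quantile(usable.pi_reduction, 1 - q))
    fst_thr = float(np.quantile(usable.fst, 1 - q))
    called = usable[(usable.pi_reduction >= pi_thr)
                    & (usable.fst >= fst_thr)].copy()
    regions = merge_regions(zip(called.chrom, called.start, called.end))
    return SweepCallSet(
        approach="window", pool=pool, windows=called, regions=regions,
        thresholds={"q": q, "pi_reduction": pi_thr, "fst": fst_thr})


def call_sweeps_gene(stats: pd.DataFrame, pool: str, q: float = 0.10,
                     diversity_column: str = "diff_per_kbp_dom") -> SweepCallSet:
    """Genes in the bottom q-fraction of diversity (domesticated subset by
    default — the founder-effect signal) AND the top q-fraction of FST."""
    usable = stats[np.isfinite(stats[diversity_column])
                   & np.isfinite(stats.fst)].copy()
    if len(usable) < 10:
        raise ValueError(f"only {len(usable)} usable genes; need >= 10")
    div_thr = float(np.quantile(usable[diversity_column], q))
    fst_thr = float(np.quantile(usable.fst, 1 - q))
    called = usable[(usable[diversity_column] <= div_thr)
                    & (usable.fst >= fst_thr)].copy()
    regions = merge_regions(zip(called.chrom, called.start, called.end))
    return SweepCallSet(
        approach="gene", pool=pool, windows=called, regions=regions,
        gene_ids=set(called.gene), thresholds={
            "q": q, "diversity": div_thr, "fst": fst_thr,
            "diversity_column": diversity_column})


def map_windows_to_genes(regions, genes: list[GeneModel]) -> set[str]:
    """Gene ids overlapping any called region by >= 1 bp (half-open)."""
    out = set()
    for g in genes:
        for chrom, start, end in regions:
            if g.chrom == chrom and g.start < end and start < g.end:
                out.add(g.id)
                break
    return out


@dataclass
class ConsensusReport:
    pool: str
    mode: str
    genes: set[str]
    per_approach: dict[str, int]
    pairwise: dict[tuple[str, str], int]
    triple: int | None


def consensus(callsets: list[SweepCallSet], mode: str = "all",
              allow_mixed_pools: bool = False) -> ConsensusReport:
    """Set algebra over the per-approach gene lists.

    mode='all' intersects every call set, 'any' takes the union,
    'pairwise' keeps genes in at least two sets.
    """
    if len(callsets) < 2:
        raise ValueError("consensus needs >= 2 call sets")
    pools = {cs.pool for cs in callsets}
    if len(pools) > 1 and not allow_mixed_pools:
        raise ValueError(f"call sets mix gene pools {sorted(pools)}; "
                         "pass allow_mixed_pools=True to override")
    sets = {cs.approach: set(cs.gene_ids) for cs in callsets}
    names = list(sets)
    if mode == "all":
        genes = set.intersection(*sets.values())
    elif mode == "any":
        genes = set.union(*sets.values())
    elif mode == "pairwise":
        genes = {g for g in set.union(*sets.values())
                 if sum(g in s for s in sets.values()) >= 2}
    else:
        raise ValueError(f"unknown consensus mode {mode!r}")
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise[(names[i], names[j])] = len(
                sets[names[i]] & sets[names[j]])
    triple = (len(set.intersection(*sets.values()))
              if len(sets) >= 3 else None)
    return ConsensusReport(
        pool=sorted(pools)[0] if len(pools) == 1 else "mixed",
        mode=mode, genes=genes,
        per_approach={k: len(v) for k, v in sets.items()},
        pairwise=pairwise, triple=triple)
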