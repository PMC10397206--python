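#!/usr/bin/env python
"""Scan for selective sweeps with the three approaches and intersect.

Per gene pool: (1) XP-CLR score thresholding (normalized >= 5),
(2) 50/5 kbp sliding windows jointly in the top decile of the
diversity-reduction ratio (pi_wild - pi_dom)/pi_wild and of Hudson FST,
(3) genes jointly in the bottom decile of domesticated diversity and
top decile of FST. Called regions map to genes by >= 1 bp overlap; the
consensus intersects the three gene lists.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common  # noqa: E402

from sweeptepop import io as stio, sweeps  # noqa: E402
from sweeptepop.filtering import filter_variants  # noqa: E402
from sweeptepop.popgen import (  # noqa: E402
    gene_scan, sliding_windows, window_scan)
from sweeptepop.types import POOLS  # noqa: E402


def main() -> None:
    cohort_dir = common.ensure_cohort_files()
    cfg = common.cohort_config()
    matrix, _ = stio.read_vcf(cohort_dir / "cohort.vcf",
                              cohort_dir / "popmap.tsv")
    curated, _ = filter_variants(matrix, 0.05, 0.1, 40)
    genes = stio.read_genes_gff3(cohort_dir / "genes.gff3")
    wins = list(sliding_windows({cfg.chrom: cfg.chrom_length}))
    truth = {r for r in cfg.sweep_regions()}

    summary = []
    for pool in POOLS:
        wstats = window_scan(curated, pool, wins)
        wstats.to_csv(common.RESULTS / f"windows_{pool}.tsv", sep="\t",
                      index=False)
        gstats = gene_scan(curated, pool, genes)
        gstats.to_csv(common.RESULTS / f"genes_{pool}.tsv", sep="\t",
                      index=False)
        calls = {
            "window": sweeps.call_sweeps_window(wstats, pool, q=0.10),
            "gene": sweeps.call_sweeps_gene(gstats, pool, q=0.10),
            "xpclr": sweeps.call_sweeps_xpclr(
                stio.import_xpclr(cohort_dir / f"xpclr_raw_{pool}.tsv"),
                pool, cutoff=5.0),
        }
        for cs in calls.values():
            if cs.approach in ("window", "xpclr"):
                cs.gene_ids = sweeps.map_windows_to_genes(cs.regions, genes)
        rep = sweeps.consensus(list(calls.values()), mode="all")
        pool_truth = [r for r in truth if r.applies_to(pool)]
        recovered = sum(
            any(ws < r.end and r.start < we
                for _, ws, we in calls["window"].regions)
            for r in pool_truth)
        summary.append({
            "pool": pool,
            "genes_per_approach": rep.per_approach,
            "consensus_genes": sorted(rep.genes),
            "planted_sweeps": len(pool_truth),
            "recovered_by_window_approach": recovered,
        })
        print(f"[{pool}] genes per approach {rep.per_approach}; "
              f"3-way consensus {len(rep.genes)} genes; window approach "
              f"recovered {recovered}/{len(pool_truth)} planted sweeps")
    with open(common.RESULTS / "sweep_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    main()
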