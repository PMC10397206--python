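#!/usr/bin/env python
"""Relate variable TEs to genes and to sweep regions.

Links variable TEs to genes within a 10 kbp window, enumerates
PAV-defined gene alleles (reference all-present pattern first), and
intersects variable TEs with the per-pool sweep regions from the
window approach.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common  # noqa: E402

import pandas as pd  # noqa: E402

from sweeptepop import genete, io as stio, pav as pavmod, sweeps  # noqa: E402
from sweeptepop.filtering import filter_variants  # noqa: E402
from sweeptepop.popgen import sliding_windows, window_scan  # noqa: E402
from sweeptepop.types import POOLS  # noqa: E402


def main() -> None:
    common.ensure_cohort_files()
    c = common.get_cohort()
    cfg = c.config
    out = common.RESULTS

    pav_path = out / "pav_filtered.tsv"
    if not pav_path.exists():
        sys.exit("run analysis/04_te_pav.py first (needs pav_filtered.tsv)")
    main_m = stio.read_pav_tsv(pav_path)
    te_by_id = {t.id: t for t in c.te_annotations}
    variable_tes = [te_by_id[tid] for tid in main_m.te_ids]

    links = genete.associate_tes(c.genes, variable_tes, window=10_000)
    links.to_csv(out / "gene_te_links.tsv", sep="\t", index=False)
    genes_with_te = links.gene.nunique()
    print(f"{len(links)} gene-TE links; {genes_with_te}/{len(c.genes)} "
          f"genes have a variable TE within 10 kbp "
          f"({100 * genes_with_te / len(c.genes):.0f}%)")
    print("link relations: "
          + ", ".join(f"{k}:{v}"
                      for k, v in links.relation.value_counts().items()))

    gene_by_id = {g.id: g for g in c.genes}
    rows = []
    for gid, sub in links.groupby("gene"):
        alleles = genete.enumerate_alleles(gene_by_id[gid], list(sub.te),
                                           main_m)
        if alleles.n_alleles > 1:
            for pat, cnt, carriers in alleles.alleles:
                rows.append((gid, len(alleles.te_ids), pat, cnt))
    allele_df = pd.DataFrame(rows, columns=["gene", "n_tes", "pattern",
                                            "carriers"])
    allele_df.to_csv(out / "gene_alleles.tsv", sep="\t", index=False)
    multi = allele_df.groupby("gene").size()
    if len(multi):
        top = multi.idxmax()
        print(f"{multi.size} genes with >1 PAV allele; most diverse: "
              f"{top} with {multi.max()} alleles")

    # sweep regions per pool from the window approach
    matrix, _ = stio.read_vcf(common.COHORT_DIR / "cohort.vcf",
                              common.COHORT_DIR / "popmap.tsv")
    curated, _ = filter_variants(matrix, 0.05, 0.1, 40)
    wins = list(sliding_windows({cfg.chrom: cfg.chrom_length}))
    regions = {}
    for pool in POOLS:
        stats = window_scan(curated, pool, wins)
        regions[pool] = sweeps.call_sweeps_window(stats, pool, 0.10).regions
    in_sweeps = genete.tes_in_sweeps(variable_tes, regions)
    with open(out / "tes_in_sweeps.json", "w") as fh:
        json.dump({k: sorted(v) for k, v in in_sweeps.items()}, fh,
                  indent=2, sort_keys=True)
    print(f"variable TEs inside sweeps: AI-exclusive "
          f"{len(in_sweeps['AI_exclusive'])}, MI-exclusive "
          f"{len(in_sweeps['MI_exclusive'])}, shared "
          f"{len(in_sweeps['shared'])}")


if __name__ == "__main__":
    main()
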