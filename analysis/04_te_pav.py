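#!/usr/bin/env python
"""Genotype TE presence/absence from read-pair evidence and run the PAV
statistics.

Calls large deletions per accession from discordant read pairs,
genotypes every annotated TE at overlap thresholds 100/95/90/85%,
filters the 85% matrix (length >= 500 bp, variable TEs only), and runs
the downstream statistics: per-TE MAF, per-accession deletion counts,
singletons, Fisher differentiation (MI vs AI at 1e-10; wild vs
domesticated MI at 1e-5), pairwise Wilcoxon tests on deletion counts,
superfamily overrepresentation, and hierarchical/NJ clustering.
"""

import json
import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common  # noqa: E402

import numpy as np  # noqa: E402

from sweeptepop import io as stio, pav as pavmod  # noqa: E402
from sweeptepop.popgen import is_clade  # noqa: E402
from sweeptepop.types import POOLS  # noqa: E402


def main() -> None:
    common.ensure_cohort_files()
    c = common.get_cohort()
    cfg = c.config
    out = common.RESULTS

    dels = pavmod.call_deletions(c.read_pairs, cfg.insert_mean,
                                 cfg.insert_sd, z_cutoff=4, min_support=3)
    stio.write_deletions_bed(dels, out / "deletions_called.bed")
    print(f"called {dels.n_calls()} deletions from read pairs "
          f"(truth: {c.deletions_per_sample.n_calls()})")

    accs = c.genotypes.accessions
    counts_by_thr = {}
    for thr in (1.0, 0.95, 0.90, 0.85):
        m = pavmod.genotype_pav(c.te_annotations, dels, accs, thr)
        filt = pavmod.filter_pav(m, c.te_annotations, 500, True)
        counts_by_thr[thr] = filt.n_tes
        stio.write_pav_tsv(m, out / f"pav_{int(round(thr * 100)):03d}.tsv")
    print("variable TEs (length>=500) by threshold: "
          + ", ".join(f"{int(t * 100)}%:{n}"
                      for t, n in counts_by_thr.items()))

    main_m = pavmod.filter_pav(
        pavmod.genotype_pav(c.te_annotations, dels, accs, 0.85),
        c.te_annotations, 500, True)
    stio.write_pav_tsv(main_m, out / "pav_filtered.tsv")
    stio.write_pav_vcf(main_m, c.te_annotations, out / "pav.vcf")

    counts = pavmod.pav_counts(main_m)
    counts.to_csv(out / "pav_counts.tsv", sep="\t")
    pavmod.pav_maf(main_m).to_csv(out / "pav_maf.tsv", sep="\t")
    singles = pavmod.singletons(main_m)
    print(f"85% matrix: {main_m.n_tes} variable TEs, "
          f"{len(singles)} singletons, "
          f"{int(counts.sum())} deletion genotypes")

    pops = c.population_map
    fisher_pools = pavmod.fisher_differentiation(
        main_m, pops, POOLS["MI"], POOLS["AI"], alpha=1e-10)
    n_diag = sum(r.significant for r in fisher_pools)
    fisher_wd = pavmod.fisher_differentiation(
        main_m, pops, "WILD_MI", "DOM_MI", alpha=1e-5)
    n_wd = sum(r.significant for r in fisher_wd)
    print(f"pool-differentiated TEs (MI vs AI, p<1e-10): {n_diag}; "
          f"wild-vs-dom MI (p<1e-5): {n_wd}")

    wilcox = pavmod.pav_group_tests(counts, pops)
    wilcox.to_csv(out / "pav_wilcoxon.tsv", sep="\t", index=False)
    sig = wilcox[wilcox.wilcoxon_p < 0.05]
    print("Wilcoxon on deletion counts, significant pairs: "
          + (", ".join(f"{r.pop_a}-{r.pop_b}" for r in sig.itertuples())
             or "none"))

    te_by_id = {t.id: t for t in c.te_annotations}
    diag_sf = Counter(te_by_id[r.te_id].superfamily
                      for r in fisher_pools if r.significant)
    background = Counter(t.superfamily for t in c.te_annotations)
    if diag_sf:
        enr = pavmod.superfamily_enrichment(dict(diag_sf), dict(background))
        print(f"superfamily composition of pool-differentiated TEs "
              f"{dict(diag_sf)}; chi-square vs background: "
              f"chi2={enr.chi2:.1f}, p={enr.p_value:.2e}")

    _, tree = pavmod.pav_clustering(main_m)
    (out / "nj_pav.nwk").write_text(tree.newick() + "\n")
    ai = [a for a in main_m.accessions if pops[a] in POOLS["AI"]]
    print(f"NJ on the PAV matrix separates the gene pools: "
          f"{is_clade(tree, ai)}")

    with open(out / "pav_summary.json", "w") as fh:
        json.dump({
            "n_called_deletions": dels.n_calls(),
            "variable_tes_by_threshold": {str(k): v for k, v
                                          in counts_by_thr.items()},
            "n_singletons": len(singles),
            "n_pool_differentiated": n_diag,
            "n_wild_dom_mi_differentiated": n_wd,
        }, fh, indent=2)


if __name__ == "__main__":
    main()
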