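"""End-to-end orchestration: simulate/load -> curate -> sweep scans ->
PAV genotyping and statistics -> gene-TE associations, with a
checksummed run manifest for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genete, io, pav as pavmod, sweeps
from .filtering import filter_variants
from .popgen import (gene_scan, neighbor_joining, pav_distance_matrix,
                     sliding_windows, snp_distance_matrix, window_scan)
from .simulate import SimConfig, TEDeletionFreqModel, simulate_cohort
from .types import POOLS

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds of the analysis plus either a simulate block or
    paths to real inputs."""

    out_dir: str = "results/run"
    seed: int = 0
    simulate: SimConfig | None = None
    # input paths, used when simulate is None
    vcf: str | None = None
    population_map: str | None = None
    te_gff3: str | None = None
    genes_gff3: str | None = None
    deletions: str | None = None
    fragments: str | None = None
    xpclr: dict[str, str] = field(default_factory=dict)  # pool -> path
    # thresholds (defaults mirror the analysis constants)
    min_maf: float = 0.05
    max_het: float = 0.1
    min_genotyped: int = 40
    window: int = 50_000
    step: int = 5_000
    q: float = 0.10
    xpclr_cutoff: float = 5.0
    xpclr_normalization: str = "mean"
    pav_thresholds: tuple = (1.0, 0.95, 0.90, 0.85)
    pav_threshold_main: float = 0.85
    min_te_length: int = 500
    fisher_alpha_pools: float = 1e-10
    fisher_alpha_mi_wd: float = 1e-5
    proximity_window: int = 10_000
    z_cutoff: float = 4.0
    min_support: int = 3

    def validate(self) -> None:
        if self.simulate is None and (self.vcf is None
                                      or self.population_map is None):
            raise ValueError("config needs either a simulate block or "
                             "vcf + population_map paths")
        if not (0 < self.q <= 1):
            raise ValueError("q must be in (0, 1]")
        for t in self.pav_thresholds:
            if not (0 < t <= 1):
                raise ValueError("pav thresholds must be in (0, 1]")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            model = sim.pop("te_del_freq_model", None)
            sc = SimConfig(**sim)
            if model is not None:
                sc.te_del_freq_model = TEDeletionFreqModel(**model)
            cfg.simulate = sc
        if isinstance(cfg.pav_thresholds, list):
            cfg.pav_thresholds = tuple(cfg.pav_thresholds)
        return cfg

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["pav_thresholds"] = list(self.pav_thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.stages.append({
            "stage": stage,
            "params": params,
            "outputs": {str(p): _sha256(p) for p in sorted(outputs)},
        })

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages},
                      fh, indent=2, sort_keys=True, default=str)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage in dependency order, writing outputs and a
    checksummed manifest under config.out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))

    # --- stage: inputs -----------------------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        sim.seed = config.seed
        cohort = simulate_cohort(sim)
        matrix = cohort.genotypes
        tes = cohort.te_annotations
        genes = cohort.genes
        dels_input = None
        fragments = cohort.read_pairs
        xpclr_raw = cohort.xpclr_scores
        files = []
        io.write_vcf(matrix, out / "cohort.vcf")
        io.write_population_map(cohort.population_map, out / "popmap.tsv")
        io.write_te_gff3(tes, out / "tes.gff3")
        io.write_genes_gff3(genes, out / "genes.gff3")
        io.write_deletions_bed(cohort.deletions_per_sample,
                               out / "deletions_truth.bed")
        io.write_pav_tsv(cohort.deletion_truth, out / "pav_truth.tsv")
        with open(out / "sweep_truth.bed", "w") as fh:
            for r in cohort.sweep_truth:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.pool}\n")
        for pool, df in xpclr_raw.items():
            df.to_csv(out / f"xpclr_raw_{pool}.tsv", sep="\t", index=False)
            files.append(out / f"xpclr_raw_{pool}.tsv")
        files += [out / f for f in ["cohort.vcf", "popmap.tsv", "tes.gff3",
                                    "genes.gff3", "deletions_truth.bed",
                                    "pav_truth.tsv", "sweep_truth.bed"]]
        manifest.record("simulate", {"seed": config.seed}, files)
        chrom_lengths = {sim.chrom: sim.chrom_length}
    else:
        matrix, _ = io.read_vcf(config.vcf, config.population_map)
        tes = io.read_te_gff3(config.te_gff3) if config.te_gff3 else []
        genes = (io.read_genes_gff3(config.genes_gff3)
                 if config.genes_gff3 else [])
        dels_input = (io.read_deletions(config.deletions)
                      if config.deletions else None)
        fragments = (io.read_fragments_tsv(config.fragments)
                     if config.fragments else None)
        xpclr_raw = {pool: path for pool, path in config.xpclr.items()}
        chrom_lengths = {
            str(c): int(matrix.positions[matrix.chroms == c].max())
            for c in np.unique(matrix.chroms.astype(str))}

    # --- stage: SNP curation ----------------------------------------------
    curated, report = filter_variants(
        matrix, config.min_maf, config.max_het, config.min_genotyped)
    io.write_vcf(curated, out / "curated.vcf")
    with open(out / "filter_report.json", "w") as fh:
        json.dump(asdict(report), fh, indent=2)
    manifest.record("filter", {"min_maf": config.min_maf,
                               "max_het": config.max_het,
                               "min_genotyped": config.min_genotyped},
                    [out / "curated.vcf", out / "filter_report.json"])

    # --- stage: population structure ---------------------------------------
    snp_tree = neighbor_joining(snp_distance_matrix(curated))
    (out / "nj_snp.nwk").write_text(snp_tree.newick() + "\n")
    manifest.record("nj_snp", {}, [out / "nj_snp.nwk"])

    # --- stage: sweep scans -------------------------------------------------
    callsets: dict[str, dict[str, sweeps.SweepCallSet]] = {}
    for pool in POOLS:
        wins = list(sliding_windows(chrom_lengths, config.window, config.step))
        wstats = window_scan(curated, pool, wins)
        wstats.to_csv(out / f"windows_{pool}.tsv", sep="\t", index=False)
        gstats = gene_scan(curated, pool, genes) if genes else None
        pool_calls = {}
        pool_calls["window"] = sweeps.call_sweeps_window(wstats, pool, config.q)
        if gstats is not None:
            gstats.to_csv(out / f"genes_{pool}.tsv", sep="\t", index=False)
            pool_calls["gene"] = sweeps.call_sweeps_gene(gstats, pool, config.q)
        if pool in xpclr_raw:
            table = io.import_xpclr(xpclr_raw[pool],
                                    config.xpclr_normalization)
            pool_calls["xpclr"] = sweeps.call_sweeps_xpclr(
                table, pool, config.xpclr_cutoff)
        # map window/xpclr regions to genes
        for cs in pool_calls.values():
            if cs.approach in ("window", "xpclr") and genes:
                cs.gene_ids = sweeps.map_windows_to_genes(cs.regions, genes)
        with open(out / f"sweep_regions_{pool}.bed", "w") as fh:
            for cs in pool_calls.values():
                for chrom, s, e in cs.regions:
                    fh.write(f"{chrom}\t{s}\t{e}\t{cs.approach}\n")
        callsets[pool] = pool_calls
        outs = [out / f"windows_{pool}.tsv", out / f"sweep_regions_{pool}.bed"]
        if gstats is not None:
            outs.append(out / f"genes_{pool}.tsv")
        manifest.record(f"sweeps_{pool}",
                        {"q": config.q, "xpclr_cutoff": config.xpclr_cutoff},
                        outs)

    consensus_rows = []
    for pool, pool_calls in callsets.items():
        if len(pool_calls) >= 2:
            rep = sweeps.consensus(list(pool_calls.values()), mode="all")
            consensus_rows.append({
                "pool": pool, "per_approach": rep.per_approach,
                "triple": rep.triple,
                "consensus_genes": sorted(rep.genes)})
    with open(out / "consensus.json", "w") as fh:
        json.dump(consensus_rows, fh, indent=2, sort_keys=True)
    manifest.record("consensus", {"mode": "all"}, [out / "consensus.json"])

    # --- stage: deletions and PAV -------------------------------------------
    if fragments is not None:
        im = (config.simulate.insert_mean if config.simulate
              else float(np.median(np.concatenate(
                  [f.predicted_length for f in fragments.values()]))))
        isd = (config.simulate.insert_sd if config.simulate
               else float(np.std(np.concatenate(
                   [f.predicted_length for f in fragments.values()]))))
        dels = pavmod.call_deletions(fragments, im, isd,
                                     config.z_cutoff, config.min_support)
    elif dels_input is not None:
        dels = dels_input
    else:
        dels = None

    if dels is not None and tes:
        io.write_deletions_bed(dels, out / "deletions_called.bed")
        matrices = {}
        for t in sorted(set(config.pav_thresholds)
                        | {config.pav_threshold_main}):
            matrices[t] = pavmod.genotype_pav(tes, dels, matrix.accessions, t)
            io.write_pav_tsv(matrices[t],
                             out / f"pav_{int(round(t * 100)):03d}.tsv")
        main = pavmod.filter_pav(matrices[config.pav_threshold_main], tes,
                                 config.min_te_length, require_variable=True)
        io.write_pav_tsv(main, out / "pav_filtered.tsv")
        io.write_pav_vcf(main, tes, out / "pav.vcf")
        pav_outs = [out / "deletions_called.bed", out / "pav_filtered.tsv",
                    out / "pav.vcf"]
        pav_outs += [out / f"pav_{int(round(t * 100)):03d}.tsv"
                     for t in sorted(set(config.pav_thresholds)
                                     | {config.pav_threshold_main})]
        manifest.record("pav", {"thresholds": list(config.pav_thresholds),
                                "min_te_length": config.min_te_length},
                        pav_outs)

        # --- stage: PAV statistics ------------------------------------------
        pop_map = matrix.population_map
        maf = pavmod.pav_maf(main)
        maf.to_csv(out / "pav_maf.tsv", sep="\t")
        counts = pavmod.pav_counts(main)
        counts.to_csv(out / "pav_counts.tsv", sep="\t")
        (out / "pav_singletons.txt").write_text(
            "\n".join(pavmod.singletons(main)) + "\n")
        fisher_pools = pavmod.fisher_differentiation(
            main, pop_map, POOLS["MI"], POOLS["AI"],
            alpha=config.fisher_alpha_pools)
        fisher_wd = pavmod.fisher_differentiation(
            main, pop_map, "WILD_MI", "DOM_MI",
            alpha=config.fisher_alpha_mi_wd)
        for name, res in [("fisher_MI_vs_AI", fisher_pools),
                          ("fisher_wildMI_vs_domMI", fisher_wd)]:
            rows = [{"te": r.te_id, "p": r.fisher_p,
                     "freq_a": r.freq_a, "freq_b": r.freq_b,
                     "significant": r.significant} for r in res]
            with open(out / f"{name}.json", "w") as fh:
                json.dump(rows, fh, indent=2)
        wilcox = pavmod.pav_group_tests(counts, pop_map)
        wilcox.to_csv(out / "pav_wilcoxon.tsv", sep="\t", index=False)
        te_by_id = {t.id: t for t in tes}
        diag_ids = [r.te_id for r in fisher_pools if r.significant]
        background = {}
        for t in tes:
            background[t.superfamily] = background.get(t.superfamily, 0) + 1
        if diag_ids:
            subset = {}
            for tid in diag_ids:
                sf = te_by_id[tid].superfamily
                subset[sf] = subset.get(sf, 0) + 1
            enr = pavmod.superfamily_enrichment(subset, background)
            with open(out / "superfamily_enrichment.json", "w") as fh:
                json.dump(asdict(enr), fh, indent=2)
        _, pav_tree = pavmod.pav_clustering(main)
        (out / "nj_pav.nwk").write_text(pav_tree.newick() + "\n")
        manifest.record("pav_stats",
                        {"alpha_pools": config.fisher_alpha_pools,
                         "alpha_mi_wd": config.fisher_alpha_mi_wd},
                        [out / "pav_maf.tsv", out / "pav_counts.tsv",
                         out / "pav_singletons.txt",
                         out / "fisher_MI_vs_AI.json",
                         out / "fisher_wildMI_vs_domMI.json",
                         out / "pav_wilcoxon.tsv", out / "nj_pav.nwk"])

        # --- stage: gene-TE associations ------------------------------------
        if genes:
            variable_tes = [te_by_id[tid] for tid in main.te_ids]
            links = genete.associate_tes(genes, variable_tes,
                                         config.proximity_window)
            links.to_csv(out / "gene_te_links.tsv", sep="\t", index=False)
            sweep_regions = {
                pool: callsets[pool]["window"].regions
                for pool in callsets if "window" in callsets[pool]}
            in_sweeps = genete.tes_in_sweeps(variable_tes, sweep_regions)
            with open(out / "tes_in_sweeps.json", "w") as fh:
                json.dump({k: sorted(v) for k, v in in_sweeps.items()},
                          fh, indent=2, sort_keys=True)
            allele_rows = []
            gene_by_id = {g.id: g for g in genes}
            for gid, sub in links.groupby("gene"):
                cfg_alleles = genete.enumerate_alleles(
                    gene_by_id[gid], list(sub.te), main)
                if cfg_alleles.n_alleles > 1:
                    for pat, cnt, _carriers in cfg_alleles.alleles:
                        allele_rows.append((gid, pat, cnt,
                                            len(cfg_alleles.te_ids)))
            pd.DataFrame(allele_rows,
                         columns=["gene", "pattern", "carriers", "n_tes"]
                         ).to_csv(out / "gene_alleles.tsv", sep="\t",
                                  index=False)
            manifest.record("gene_te", {"window": config.proximity_window},
                            [out / "gene_te_links.tsv",
                             out / "tes_in_sweeps.json",
                             out / "gene_alleles.tsv"])

    manifest.write(out / "manifest.json")
    return manifest
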