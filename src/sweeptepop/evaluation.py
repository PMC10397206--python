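"""Benchmark experiments on synthetic cohorts.

Each function sets up a fully specified synthetic study, runs the
corresponding pipeline stage, and measures recovery of the simulated
ground truth. They back both the validation test suite and the
reproduction script, so the numbers they return are always recomputed
from scratch.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

from .filtering import filter_variants, site_stats
from .pav import (
    call_deletions,
    fisher_differentiation,
    filter_pav,
    genotype_pav,
)
from .popgen import (
    is_clade,
    neighbor_joining,
    pav_distance_matrix,
    sliding_windows,
    snp_distance_matrix,
    window_scan,
)
from .simulate import (
    SimConfig,
    TEDeletionFreqModel,
    simulate_read_pairs,
    simulate_snp_genotypes,
    simulate_te_deletions,
)
from .sweeps import call_sweeps_window
from .types import POOLS


# ---------------------------------------------------------------------------
# PAV identity and threshold monotonicity


def pav_cohort_config(seed: int) -> SimConfig:
    """A 60-accession, 2,000-TE cohort on a 20 Mbp chromosome."""
    return SimConfig(n_per_pop=15, chrom_length=20_000_000, n_snps=300,
                     n_sweeps=0, n_tes=2_000, seed=seed)


def pav_identity_and_monotonicity(seed: int) -> dict:
    """Genotype PAV from the truth deletions and compare with the truth
    matrix; count variable TEs per overlap threshold."""
    cfg = pav_cohort_config(seed)
    m = simulate_snp_genotypes(cfg)
    tes, truth, dels, _ = simulate_te_deletions(cfg, m)
    pav = genotype_pav(tes, dels, m.accessions, truth.overlap_threshold)
    concordance = float(np.mean(pav.codes == truth.codes))
    variable_counts = {}
    for t in (1.0, 0.95, 0.90, 0.85):
        mt = genotype_pav(tes, dels, m.accessions, t)
        variable_counts[t] = int(
            filter_pav(mt, tes, min_te_length=500,
                       require_variable=True).n_tes)
    return {"concordance": concordance,
            "n_cells": int(truth.codes.size),
            "variable_counts": variable_counts}


# ---------------------------------------------------------------------------
# deletion-caller recovery


def deletion_caller_config(seed: int) -> SimConfig:
    """8 accessions, 300 TEs of 600-3,000 bp on 4 Mbp, 10x coverage."""
    return SimConfig(n_per_pop=2, chrom_length=4_000_000, n_snps=200,
                     n_sweeps=0, n_tes=300, te_length_range=(600, 3_000),
                     coverage=10.0, seed=seed)


def deletion_caller_recovery(seed: int, z_cutoff: float = 4.0,
                             min_support: int = 3) -> dict:
    """Recall/precision of the read-pair caller against truth deletions
    >= 500 bp, plus breakpoint-midpoint accuracy."""
    cfg = deletion_caller_config(seed)
    m = simulate_snp_genotypes(cfg)
    _, _, truth_dels, _ = simulate_te_deletions(cfg, m)
    rp = simulate_read_pairs(cfg, truth_dels, m.accessions)
    called = call_deletions(rp, cfg.insert_mean, cfg.insert_sd,
                            z_cutoff, min_support)

    n_truth = n_recalled = n_called = n_matched_calls = 0
    midpoint_errors = []
    for acc in m.accessions:
        truths = [d for d in truth_dels.get(acc) if d.end - d.start >= 500]
        calls = called.get(acc)
        n_truth += len(truths)
        n_called += len(calls)
        for t in truths:
            tm = (t.start + t.end) / 2
            hits = [c for c in calls
                    if c.start < t.end and t.start < c.end
                    and abs((c.start + c.end) / 2 - tm) <= cfg.insert_sd]
            if hits:
                n_recalled += 1
                midpoint_errors.append(min(
                    abs((c.start + c.end) / 2 - tm) for c in hits))
        for c in calls:
            if any(c.start < t.end and t.start < c.end
                   for t in truth_dels.get(acc)):
                n_matched_calls += 1
    return {
        "n_truth": n_truth,
        "n_called": n_called,
        "recall": n_recalled / n_truth if n_truth else float("nan"),
        "precision": n_matched_calls / n_called if n_called else float("nan"),
        "median_midpoint_error": float(np.median(midpoint_errors))
        if midpoint_errors else float("nan"),
    }


# ---------------------------------------------------------------------------
# statistic oracles


def oracle_pi_per_bp(codes: np.ndarray, length: int) -> float:
    """Pair-counting nucleotide diversity: per site, k alt alleles among n
    give k(n-k)/C(n,2) mean pairwise differences."""
    total = 0.0
    for j in range(codes.shape[1]):
        geno = codes[:, j][codes[:, j] >= 0]
        n = 2 * len(geno)
        if n < 2:
            continue
        k = int(geno.sum())
        total += k * (n - k) / (n * (n - 1) / 2)
    return total / length


def oracle_hudson_fst(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Hudson ratio-of-sums from explicit within/between pair counting."""
    num = den = 0.0
    for j in range(codes_a.shape[1]):
        ga = codes_a[:, j][codes_a[:, j] >= 0]
        gb = codes_b[:, j][codes_b[:, j] >= 0]
        na, nb = 2 * len(ga), 2 * len(gb)
        if na < 2 or nb < 2:
            continue
        ka, kb = int(ga.sum()), int(gb.sum())
        num += 0.5 * (ka * (na - ka) / (na * (na - 1) / 2)
                      + kb * (nb - kb) / (nb * (nb - 1) / 2))
        den += (ka * (nb - kb) + kb * (na - ka)) / (na * nb)
    return 1.0 - num / den if den > 0 else float("nan")


def statistic_oracle_deviations(seed: int, n_matrices: int = 200) -> dict:
    """Max |pi - oracle| and |FST - oracle| over random small matrices,
    and max |Fisher p - enumeration| over a grid of 2x2 tables."""
    from scipy.stats import fisher_exact

    from .popgen import fst, nucleotide_diversity
    from .types import GenotypeMatrix, POPULATIONS

    rng = np.random.default_rng(seed)
    max_pi_dev = max_fst_dev = 0.0
    for _ in range(n_matrices):
        n_acc = int(rng.integers(4, 11))
        n_sites = int(rng.integers(5, 51))
        codes = rng.integers(0, 3, size=(n_acc, n_sites)).astype(np.int8)
        codes[rng.random(codes.shape) < 0.1] = -1
        accs = [f"a{i}" for i in range(n_acc)]
        m = GenotypeMatrix(
            accessions=accs,
            chroms=np.array(["c"] * n_sites, dtype=object),
            positions=np.arange(1, n_sites + 1),
            genotypes=codes,
            population_map={a: POPULATIONS[i % 4]
                            for i, a in enumerate(accs)})
        iv = ("c", 0, 1_000)
        pi = nucleotide_diversity(m, accs, iv)
        max_pi_dev = max(max_pi_dev,
                         abs(pi - oracle_pi_per_bp(codes, 1_000)))
        half = n_acc // 2
        want = oracle_hudson_fst(codes[:half], codes[half:])
        if np.isfinite(want):
            got = fst(m, accs[:half], accs[half:])
            max_fst_dev = max(max_fst_dev, abs(got - want))

    max_fisher_dev = 0.0
    for a in range(16):
        for b in range(16 - a):
            for c in range(16):
                for d in range(16 - c):
                    if a + b == 0 or c + d == 0:
                        continue
                    p = fisher_exact([[a, b], [c, d]])[1]
                    n1, n2, k = a + b, c + d, a + c
                    lo, hi = max(0, k - n2), min(k, n1)
                    pmf = hypergeom.pmf(np.arange(lo, hi + 1),
                                        n1 + n2, k, n1)
                    p_obs = hypergeom.pmf(a, n1 + n2, k, n1)
                    want = min(1.0, float(pmf[pmf <= p_obs * (1 + 1e-9)].sum()))
                    max_fisher_dev = max(max_fisher_dev, abs(p - want))
    return {"max_pi_deviation": max_pi_dev,
            "max_fst_deviation": max_fst_dev,
            "max_fisher_deviation": max_fisher_dev}


# ---------------------------------------------------------------------------
# sweep recovery


def sweep_cohort_config(seed: int) -> SimConfig:
    """60 accessions, 10 sweeps planted in both pools among ~780 windows.

    Sweeps are 50 kbp wide — at least the scan-window size, so that some
    windows lie fully inside a sweep; narrower sweeps are diluted by
    flanking neutral sequence in every overlapping window.
    """
    return SimConfig(n_per_pop=15, chrom_length=4_000_000, n_snps=12_000,
                     n_sweeps=10, sweep_halfwidth=25_000,
                     sweep_pi_reduction=0.8, sweep_pool_assignment="both",
                     seed=seed)


def sweep_recovery(seed: int, q: float = 0.10) -> dict:
    """Region-level sensitivity and neutral-window false-positive rate of
    the window approach, per gene pool, plus monotonicity in q."""
    cfg = sweep_cohort_config(seed)
    m = simulate_snp_genotypes(cfg)
    curated, _ = filter_variants(m, 0.05, 0.1, 40)
    wins = list(sliding_windows({cfg.chrom: cfg.chrom_length}))
    regions = [(r.start, r.end) for r in cfg.sweep_regions()]
    out = {"per_pool": {}, "q": q}
    for pool in POOLS:
        stats = window_scan(curated, pool, wins)
        cs = call_sweeps_window(stats, pool, q)
        called = list(zip(cs.windows.start, cs.windows.end))
        hit = sum(any(ws < re_ and rs < we for ws, we in called)
                  for rs, re_ in regions)
        usable = stats[np.isfinite(stats.pi_reduction)
                       & np.isfinite(stats.fst)]
        neutral = [(s, e) for s, e in zip(usable.start, usable.end)
                   if not any(s < re_ and rs < e for rs, re_ in regions)]
        fp = sum(any(s == cs_ and e == ce for cs_, ce in called)
                 for s, e in neutral)
        counts = {qq: len(call_sweeps_window(stats, pool, qq).windows)
                  for qq in (0.10, 0.05, 0.02)}
        out["per_pool"][pool] = {
            "sensitivity": hit / len(regions),
            "neutral_fpr": fp / len(neutral) if neutral else 0.0,
            "calls_by_q": counts,
        }
    return out


# ---------------------------------------------------------------------------
# structure recovery


def structure_cohort_config(seed: int) -> SimConfig:
    return SimConfig(n_per_pop=5, chrom_length=1_000_000, n_snps=600,
                     n_sweeps=2, sweep_halfwidth=10_000, n_tes=150,
                     te_length_range=(200, 2_000), seed=seed)


def structure_recovery(seed: int, n_replicates: int = 20) -> dict:
    """Fraction of replicates in which NJ trees from SNP and PAV
    distances both place each gene pool (AI, MI) as a clade."""
    n_ok_snp = n_ok_pav = n_ok_both = 0
    for r in range(n_replicates):
        cfg = structure_cohort_config(seed + r)
        m = simulate_snp_genotypes(cfg)
        _, truth, _, _ = simulate_te_deletions(cfg, m)
        ai = [a for a in m.accessions
              if m.population_map[a] in POOLS["AI"]]
        snp_ok = is_clade(neighbor_joining(snp_distance_matrix(m)), ai)
        pav_ok = is_clade(neighbor_joining(pav_distance_matrix(truth)), ai)
        n_ok_snp += snp_ok
        n_ok_pav += pav_ok
        n_ok_both += snp_ok and pav_ok
    return {"n_replicates": n_replicates, "snp_ok": n_ok_snp,
            "pav_ok": n_ok_pav, "both_ok": n_ok_both}


# ---------------------------------------------------------------------------
# filter determinism


def filter_oracle(matrix, min_maf, max_het, min_genotyped) -> np.ndarray:
    """Independently coded single-pass per-site filter."""
    keep = np.zeros(matrix.n_sites, dtype=bool)
    for j in range(matrix.n_sites):
        geno = matrix.genotypes[:, j]
        geno = geno[geno >= 0]
        if len(geno) == 0:
            continue
        alt = int(geno.sum())
        tot = 2 * len(geno)
        maf = min(alt, tot - alt) / tot
        het = float(np.mean(geno == 1))
        keep[j] = (maf >= min_maf and het <= max_het
                   and len(geno) >= min_genotyped)
    return keep


def filter_determinism(seed: int, n_snps: int = 50_000) -> dict:
    """Compare filter_variants with the independent oracle on a large
    synthetic site set, and check idempotence."""
    cfg = SimConfig(n_per_pop=15, chrom_length=10_000_000, n_snps=n_snps,
                    n_sweeps=0, missing_rate=0.2, seed=seed)
    m = simulate_snp_genotypes(cfg)
    kept, report = filter_variants(m, 0.05, 0.1, 40)
    want = filter_oracle(m, 0.05, 0.1, 40)
    agree = bool(np.array_equal(kept.positions, m.positions[want]))
    twice, rep2 = filter_variants(kept, 0.05, 0.1, 40)
    return {"n_input": report.n_input, "n_kept": report.n_kept,
            "oracle_agrees": agree,
            "idempotent": rep2.n_excluded == 0
            and bool(np.array_equal(twice.genotypes, kept.genotypes))}


# ---------------------------------------------------------------------------
# pool-diagnostic detection


def diagnostic_cohort_config(seed: int) -> SimConfig:
    model = TEDeletionFreqModel(class_proportions={
        "invariant": 0.0, "shared": 0.5, "pool_diagnostic": 0.5,
        "domestication": 0.0, "singleton": 0.0},
        shared_freq_range=(0.3, 0.3))
    return SimConfig(n_per_pop=15, chrom_length=4_000_000, n_snps=200,
                     n_sweeps=0, n_tes=400, te_length_range=(600, 3_000),
                     te_del_freq_model=model, seed=seed)


def pool_diagnostic_detection(seed: int, alpha: float = 1e-10) -> dict:
    """Fisher flag rates for pool-diagnostic vs shared-polymorphic TEs
    (MI vs AI comparison at a stringent alpha)."""
    cfg = diagnostic_cohort_config(seed)
    m = simulate_snp_genotypes(cfg)
    tes, truth, _, classes = simulate_te_deletions(cfg, m)
    res = fisher_differentiation(truth, m.population_map,
                                 POOLS["MI"], POOLS["AI"], alpha=alpha)
    by_te = {r.te_id: r for r in res}
    diag = [t.id for t, c in zip(tes, classes) if c == "pool_diagnostic"]
    shared = [t.id for t, c in zip(tes, classes) if c == "shared"]
    diag_rate = np.mean([by_te[t].significant for t in diag])
    shared_rate = np.mean([by_te[t].significant for t in shared])
    return {"n_diagnostic": len(diag), "n_shared": len(shared),
            "diagnostic_flag_rate": float(diag_rate),
            "shared_flag_rate": float(shared_rate)}


# ---------------------------------------------------------------------------
# cohort-level summaries (for the reproduction script)


def snp_summary(seed: int) -> dict:
    """Curated-SNP count and genome-wide pool FST on the default cohort."""
    from .popgen import fst

    cfg = SimConfig(seed=seed)
    m = simulate_snp_genotypes(cfg)
    curated, report = filter_variants(m, 0.05, 0.1, 40)
    return {
        "n_raw_snps": report.n_input,
        "n_curated_snps": report.n_kept,
        "fst_AI_vs_MI": float(fst(curated, POOLS["AI"], POOLS["MI"])),
        "mean_maf": float(np.nanmean(site_stats(curated).maf)),
    }
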