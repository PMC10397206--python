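"""Shared study configuration for the numbered analysis scripts.

One default 60-accession cohort (seed 42) drives the whole analysis;
every script regenerates or reloads it deterministically, so the
scripts can be run in order or individually.
"""

from pathlib import Path

from sweeptepop import io as stio
from sweeptepop.simulate import SimConfig, simulate_cohort

SEED = 42
RESULTS = Path("results/analysis")
COHORT_DIR = RESULTS / "cohort"


def cohort_config() -> SimConfig:
    return SimConfig(seed=SEED)


_cached = None


def get_cohort():
    """The in-memory cohort (cached per process; deterministic by seed)."""
    global _cached
    if _cached is None:
        _cached = simulate_cohort(cohort_config())
    return _cached


def ensure_cohort_files():
    """Write the cohort's file representation if not already present."""
    if (COHORT_DIR / "cohort.vcf").exists():
        return COHORT_DIR
    COHORT_DIR.mkdir(parents=True, exist_ok=True)
    c = get_cohort()
    stio.write_vcf(c.genotypes, COHORT_DIR / "cohort.vcf")
    stio.write_population_map(c.population_map, COHORT_DIR / "popmap.tsv")
    stio.write_te_gff3(c.te_annotations, COHORT_DIR / "tes.gff3")
    stio.write_genes_gff3(c.genes, COHORT_DIR / "genes.gff3")
    stio.write_deletions_bed(c.deletions_per_sample,
                             COHORT_DIR / "deletions_truth.bed")
    stio.write_pav_tsv(c.deletion_truth, COHORT_DIR / "pav_truth.tsv")
    with open(COHORT_DIR / "sweep_truth.bed", "w") as fh:
        for r in c.sweep_truth:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.pool}\n")
    for pool, df in c.xpclr_scores.items():
        df.to_csv(COHORT_DIR / f"xpclr_raw_{pool}.tsv", sep="\t",
                  index=False)
    return COHORT_DIR
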