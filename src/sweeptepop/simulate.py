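"""Synthetic two-gene-pool cohort generator.

Emulates the statistical structure of a wild/domesticated resequencing
panel from two divergent gene pools (Andean AI, Mesoamerican MI):

* hierarchical allele frequencies — an ancestral frequency per SNP, pool
  frequencies drawn through a Balding-Nichols drift kernel
  (``Beta(p(1-F)/F, (1-p)(1-F)/F)``, expected FST ~ F), and domesticated
  frequencies drawn from the wild ones with an extra bottleneck drift;
* planted selective sweeps — intervals where domesticated allele
  frequencies are pushed toward fixation of the wild major allele, with
  the push calibrated by bisection so the expected diversity-reduction
  ratio (pi_wild - pi_dom)/pi_wild matches a target;
* TE deletion polymorphisms in frequency classes (shared-polymorphic,
  pool-diagnostic, domestication-differentiated, singleton);
* read-pair fragment evidence in which pairs spanning a deletion show an
  abnormally large reference-projected fragment length.

All randomness flows from a single root seed through named child streams,
so a fixed seed fixes every output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    POOLS,
    POPULATIONS,
    Deletion,
    DeletionCallSet,
    GeneModel,
    GenotypeMatrix,
    PAVMatrix,
    TEAnnotation,
)

# deletion-frequency classes for TE presence/absence polymorphism
TE_CLASSES = ("invariant", "shared", "pool_diagnostic", "domestication", "singleton")

_DEFAULT_CLASS_PROPS = {
    "invariant": 0.35,
    "shared": 0.25,
    "pool_diagnostic": 0.15,
    "domestication": 0.05,
    "singleton": 0.20,
}

_DEFAULT_SUPERFAMILIES = {
    "LTR/Gypsy": 0.50,
    "LTR/Copia": 0.25,
    "DNA/CACTA": 0.10,
    "DNA/hAT": 0.05,
    "LINE/L1": 0.05,
    "MITE/Tourist": 0.05,
}


@dataclass(frozen=True)
class SweepRegion:
    chrom: str
    start: int
    end: int
    pool: str  # "AI", "MI" or "both"

    def applies_to(self, pool: str) -> bool:
        return self.pool in ("both", pool)


@dataclass
class TEDeletionFreqModel:
    """Per-class deletion-frequency specification.

    Frequencies are probabilities that an accession of the given group
    carries the (homozygous) deletion of a TE in that class.
    """

    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_PROPS))
    shared_freq_range: tuple[float, float] = (0.10, 0.50)
    diagnostic_absent_freq: float = 1.0
    diagnostic_present_freq: float = 0.0
    domestication_dom_freq: float = 0.70
    domestication_wild_freq: float = 0.05
    domestication_other_pool_freq: float = 0.02

    def validate(self) -> None:
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        unknown = set(self.class_proportions) - set(TE_CLASSES)
        if unknown:
            raise ValueError(f"unknown TE classes: {sorted(unknown)}")


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort.

    Defaults give a 60-accession cohort (15 per population, matching the
    design of a 13/19/15/14 four-population panel) on a single 2 Mbp
    chromosome.
    """

    n_per_pop: int = 15
    chrom: str = "Pl01"
    chrom_length: int = 2_000_000
    n_snps: int = 5_000
    pool_divergence_F: float = 0.30
    bottleneck_F: float = 0.10
    #: within-individual inbreeding (F_IS); high because the emulated
    #: species is predominantly selfing, so observed heterozygosity is low
    inbreeding_F: float = 0.95
    n_sweeps: int = 4
    sweep_halfwidth: int = 25_000
    sweep_pi_reduction: float = 0.8
    sweep_pool_assignment: str = "alternate"  # alternate | both | AI | MI
    n_tes: int = 500
    te_length_range: tuple[int, int] = (200, 4_000)  # ~50% genome TE load
    te_del_freq_model: TEDeletionFreqModel = field(default_factory=TEDeletionFreqModel)
    superfamily_proportions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SUPERFAMILIES))
    n_genes: int = 200
    gene_length: int = 3_000
    insert_mean: float = 600.0
    insert_sd: float = 60.0
    read_len: int = 150
    coverage: float = 10.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_per_pop", "chrom_length", "n_snps", "n_tes", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("pool_divergence_F", "bottleneck_F"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if not (0.0 <= self.inbreeding_F <= 1.0):
            raise ValueError("inbreeding_F must be in [0, 1]")
        if not (0.0 < self.sweep_pi_reduction <= 1.0):
            raise ValueError("sweep_pi_reduction must be in (0, 1]")
        if self.te_length_range[0] < 1:
            raise ValueError("te_length_range min must be >= 1")
        if self.te_length_range[0] > self.te_length_range[1]:
            raise ValueError("te_length_range min > max")
        if self.insert_sd <= 0:
            raise ValueError("insert_sd must be > 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.n_sweeps < 0:
            raise ValueError("n_sweeps must be >= 0")
        regs = self.sweep_regions()
        for a, b in zip(regs, regs[1:]):
            if b.start < a.end:
                raise ValueError(f"sweep regions overlap: {a} / {b}")
        for r in regs:
            if r.start < 0 or r.end > self.chrom_length:
                raise ValueError(f"sweep region outside chromosome: {r}")
        self.te_del_freq_model.validate()

    # --- derived layout -------------------------------------------------
    def accession_names(self) -> list[str]:
        return [f"{pop}_{i:02d}" for pop in POPULATIONS
                for i in range(self.n_per_pop)]

    def population_map(self) -> dict[str, str]:
        return {a: a.rsplit("_", 1)[0] for a in self.accession_names()}

    def sweep_regions(self) -> list[SweepRegion]:
        """Evenly spaced sweep intervals; pool assignment per config."""
        regions = []
        for i in range(self.n_sweeps):
            center = int((i + 0.5) * self.chrom_length / self.n_sweeps)
            if self.sweep_pool_assignment == "alternate":
                pool = "AI" if i % 2 == 0 else "MI"
            else:
                pool = self.sweep_pool_assignment
            regions.append(SweepRegion(
                self.chrom,
                max(0, center - self.sweep_halfwidth),
                min(self.chrom_length, center + self.sweep_halfwidth),
                pool,
            ))
        return regions

    def gene_models(self) -> list[GeneModel]:
        """A regular grid of gene intervals along the chromosome."""
        spacing = self.chrom_length / self.n_genes
        if self.gene_length >= spacing:
            raise ValueError("gene_length must be smaller than gene spacing")
        genes = []
        for i in range(self.n_genes):
            start = int(i * spacing + (spacing - self.gene_length) / 2)
            genes.append(GeneModel(
                id=f"Pl01G{i:07d}", chrom=self.chrom,
                start=start, end=start + self.gene_length,
                strand="+" if i % 2 == 0 else "-",
            ))
        return genes


@dataclass
class FragmentTable:
    """Bulk read-pair fragment evidence for one accession."""

    chrom: str
    left_inner: np.ndarray
    right_inner: np.ndarray
    predicted_length: np.ndarray

    def __len__(self) -> int:
        return len(self.predicted_length)


@dataclass
class SimulatedCohort:
    config: SimConfig
    genotypes: GenotypeMatrix
    te_annotations: list[TEAnnotation]
    te_classes: list[str]
    deletion_truth: PAVMatrix
    deletions_per_sample: DeletionCallSet
    read_pairs: dict[str, FragmentTable]
    genes: list[GeneModel]
    sweep_truth: list[SweepRegion]
    xpclr_scores: "object"  # pandas.DataFrame (chrom, start, end, raw_score) per pool
    population_map: dict[str, str]


# ---------------------------------------------------------------------------
# allele-frequency machinery


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Drift kernel: resample frequencies around p with inbreeding F."""
    if F == 0.0:
        return p.copy()
    p = np.clip(p, 1e-9, 1 - 1e-9)
    scale = (1.0 - F) / F
    out = rng.beta(p * scale, (1.0 - p) * scale)
    return np.clip(out, 0.0, 1.0)


def _calibrate_sweep_push(p_wild: np.ndarray, p_dom: np.ndarray,
                          target_reduction: float, n_steps: int = 20) -> float:
    """Bisection on the push factor lambda so that the expected
    heterozygosity ratio inside the sweep hits 1 - target_reduction.

    Pushed frequency: (1-lambda)*p_dom + lambda*m, with m the indicator
    that the wild major allele is the alternative allele.
    """
    if len(p_wild) == 0:
        return 0.0
    if target_reduction >= 1.0:
        return 1.0
    m = (p_wild >= 0.5).astype(float)
    hw = np.sum(2 * p_wild * (1 - p_wild))
    if hw == 0:
        return 0.0

    def reduction(lam: float) -> float:
        pd = (1 - lam) * p_dom + lam * m
        hd = np.sum(2 * pd * (1 - pd))
        return 1.0 - hd / hw

    if reduction(0.0) >= target_reduction:
        return 0.0
    lo, hi = 0.0, 1.0
    for _ in range(n_steps):
        mid = 0.5 * (lo + hi)
        if reduction(mid) < target_reduction:
            lo = mid
        else:
            hi = mid
    return hi


def _sample_distinct_positions(rng: np.random.Generator, length: int,
                               n: int) -> np.ndarray:
    """n distinct 1-based positions, without materializing arange(length)."""
    if n > length:
        raise ValueError("more SNPs than base pairs")
    positions: np.ndarray = np.empty(0, dtype=np.int64)
    while len(positions) < n:
        draw = rng.integers(1, length + 1, size=int(1.2 * (n - len(positions))
                                                    + 16))
        positions = np.unique(np.concatenate([positions, draw]))
    # thin deterministically to exactly n while keeping sorted order
    idx = np.linspace(0, len(positions) - 1, n).round().astype(int)
    return positions[idx]


def simulate_snp_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw the cohort's diploid SNP genotypes.

    Sites are uniform along the chromosome; frequencies follow the
    hierarchical pool/bottleneck model; inside planted sweeps the
    domesticated frequencies of the sweep's pool are pushed toward the
    wild major allele so the expected diversity-reduction ratio matches
    ``sweep_pi_reduction``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[0])

    positions = _sample_distinct_positions(rng, config.chrom_length,
                                           config.n_snps)
    p_anc = rng.uniform(0.05, 0.95, size=config.n_snps)

    pool_freq = {pool: _balding_nichols(rng, p_anc, config.pool_divergence_F)
                 for pool in ("AI", "MI")}
    pop_freq = {}
    for pool in ("AI", "MI"):
        p_wild = pool_freq[pool]
        p_dom = _balding_nichols(rng, p_wild, config.bottleneck_F)
        pop_freq[f"WILD_{pool}"] = p_wild
        pop_freq[f"DOM_{pool}"] = p_dom

    # sweep planting: push domesticated frequencies toward wild major allele
    for region in config.sweep_regions():
        in_sweep = (positions - 1 >= region.start) & (positions - 1 < region.end)
        if not in_sweep.any():
            continue
        for pool in ("AI", "MI"):
            if not region.applies_to(pool):
                continue
            pw = pop_freq[f"WILD_{pool}"][in_sweep]
            pd = pop_freq[f"DOM_{pool}"][in_sweep]
            lam = _calibrate_sweep_push(pw, pd, config.sweep_pi_reduction)
            m = (pw >= 0.5).astype(float)
            pop_freq[f"DOM_{pool}"][in_sweep] = (1 - lam) * pd + lam * m

    accessions = config.accession_names()
    pop_map = config.population_map()
    # genotypes: with probability inbreeding_F the two alleles are
    # identical by descent (selfing), otherwise a random HWE union
    geno = np.empty((len(accessions), config.n_snps), dtype=np.int8)
    for i, acc in enumerate(accessions):
        p = pop_freq[pop_map[acc]]
        ibd = rng.random(config.n_snps) < config.inbreeding_F
        hom = 2 * (rng.random(config.n_snps) < p)
        outbred = rng.binomial(2, p)
        geno[i] = np.where(ibd, hom, outbred).astype(np.int8)
    if config.missing_rate > 0:
        geno[rng.random(geno.shape) < config.missing_rate] = -1

    return GenotypeMatrix(
        accessions=accessions,
        chroms=np.array([config.chrom] * config.n_snps, dtype=object),
        positions=positions,
        genotypes=geno,
        population_map=pop_map,
    )


# ---------------------------------------------------------------------------
# TE deletion polymorphism


def _te_deletion_prob(model: TEDeletionFreqModel, te_class: str,
                      rng: np.random.Generator,
                      pop_of: np.ndarray) -> np.ndarray:
    """Per-accession probability of carrying the deletion, for one TE."""
    n = len(pop_of)
    q = np.zeros(n)
    if te_class == "invariant":
        return q
    if te_class == "shared":
        q[:] = rng.uniform(*model.shared_freq_range)
        return q
    if te_class == "pool_diagnostic":
        absent_pool = "AI" if rng.random() < 0.5 else "MI"
        for i, pop in enumerate(pop_of):
            pool = pop.rsplit("_", 1)[1]
            q[i] = (model.diagnostic_absent_freq if pool == absent_pool
                    else model.diagnostic_present_freq)
        return q
    if te_class == "domestication":
        # differentiated between wild and domesticated within the MI pool
        for i, pop in enumerate(pop_of):
            if pop == "DOM_MI":
                q[i] = model.domestication_dom_freq
            elif pop == "WILD_MI":
                q[i] = model.domestication_wild_freq
            else:
                q[i] = model.domestication_other_pool_freq
        return q
    if te_class == "singleton":
        q[rng.integers(n)] = 1.0
        return q
    raise ValueError(f"unknown TE class {te_class!r}")


def simulate_te_deletions(
    config: SimConfig, genotypes: GenotypeMatrix,
) -> tuple[list[TEAnnotation], PAVMatrix, DeletionCallSet, list[str]]:
    """Place non-overlapping TE intervals and draw deletion genotypes.

    Returns the annotation, the ground-truth PAV matrix (at the 0.85
    generating threshold), the per-accession truth deletions, and the
    per-TE frequency-class labels.

    Each truth deletion covers a fraction f in [0.85, 1] of its TE (with
    most mass at full coverage), so genotyping at 0.85 recovers the truth
    exactly while stricter thresholds genuinely call fewer absences.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[1])
    model = config.te_del_freq_model

    lengths = rng.integers(config.te_length_range[0],
                           config.te_length_range[1] + 1, size=config.n_tes)
    total = int(lengths.sum())
    slack = config.chrom_length - total
    if slack <= config.n_tes:
        raise ValueError("TEs do not fit in the chromosome without overlap")
    gaps = rng.dirichlet(np.ones(config.n_tes + 1)) * slack
    starts = (np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lengths[:-1])]))
    starts = starts.astype(np.int64)

    sf_names = list(config.superfamily_proportions)
    sf_probs = np.array([config.superfamily_proportions[s] for s in sf_names])
    sf_probs = sf_probs / sf_probs.sum()
    superfams = rng.choice(sf_names, size=config.n_tes, p=sf_probs)

    tes = [
        TEAnnotation(id=f"TE{i:06d}", chrom=config.chrom,
                     start=int(starts[i]), end=int(starts[i] + lengths[i]),
                     superfamily=str(superfams[i]),
                     family=str(superfams[i]).split("/")[-1])
        for i in range(config.n_tes)
    ]

    class_names = [c for c in TE_CLASSES if model.class_proportions.get(c, 0) > 0]
    class_probs = np.array([model.class_proportions[c] for c in class_names])
    te_classes = [str(c) for c in
                  rng.choice(class_names, size=config.n_tes, p=class_probs)]

    accessions = genotypes.accessions
    pop_of = np.array([genotypes.population_map[a] for a in accessions])
    codes = np.ones((len(accessions), config.n_tes), dtype=np.int8)
    dels = DeletionCallSet()

    for j, te in enumerate(tes):
        q = _te_deletion_prob(model, te_classes[j], rng, pop_of)
        if te_classes[j] == "singleton":
            deleted = q >= 1.0
        else:
            deleted = rng.random(len(accessions)) < q
        codes[deleted, j] = 0
        for i in np.flatnonzero(deleted):
            if rng.random() < 0.6:
                frac = 1.0
            else:
                frac = rng.uniform(0.85, 1.0)
            trim = int((1.0 - frac) * te.length)
            if rng.random() < 0.5:
                start, end = te.start + trim, te.end
            else:
                start, end = te.start, te.end - trim
            dels.add(accessions[i],
                     Deletion(te.chrom, start, end,
                              support=int(rng.integers(5, 30)), quality=60.0))

    truth = PAVMatrix(accessions=list(accessions),
                      te_ids=[t.id for t in tes],
                      codes=codes, overlap_threshold=0.85)
    return tes, truth, dels, te_classes


# ---------------------------------------------------------------------------
# read-pair fragment evidence


def simulate_read_pairs(
    config: SimConfig, deletions: DeletionCallSet,
    accessions: list[str] | None = None,
) -> dict[str, FragmentTable]:
    """Generate reference-projected fragment records for every accession.

    Fragments are placed on the accession's (deletion-carrying) genome
    with physical length ~ Normal(insert_mean, insert_sd); endpoints are
    projected back to reference coordinates, so pairs spanning a deletion
    of length L show predicted length ~ Normal(insert_mean + L, insert_sd).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[2])
    if accessions is None:
        accessions = config.accession_names()

    out: dict[str, FragmentTable] = {}
    for acc in accessions:
        acc_dels = sorted(deletions.get(acc), key=lambda d: d.start)
        del_starts = np.array([d.start for d in acc_dels], dtype=np.int64)
        del_lens = np.array([d.end - d.start for d in acc_dels], dtype=np.int64)
        cum_before = np.concatenate([[0], np.cumsum(del_lens)])
        # deletion start positions in sample (deletion-removed) coordinates
        del_starts_sample = del_starts - cum_before[:-1]
        sample_len = config.chrom_length - int(del_lens.sum())

        n_pairs = int(round(config.coverage * sample_len / (2 * config.read_len)))
        frag = np.rint(rng.normal(config.insert_mean, config.insert_sd,
                                  size=n_pairs)).astype(np.int64)
        frag = np.maximum(frag, 2 * config.read_len + 1)
        start = rng.integers(0, np.maximum(sample_len - frag, 1))

        def offset_idx(g: np.ndarray) -> np.ndarray:
            return np.searchsorted(del_starts_sample, g, side="right")

        def to_ref(g: np.ndarray) -> np.ndarray:
            return g + cum_before[offset_idx(g)]

        # reads straddling a deletion breakpoint would be clipped by the
        # aligner and lost as pair evidence; drop them
        mappable = (offset_idx(start) == offset_idx(start + config.read_len)) \
            & (offset_idx(start + frag - config.read_len)
               == offset_idx(start + frag))
        start, frag = start[mappable], frag[mappable]
        left_inner = to_ref(start + config.read_len)
        right_inner = to_ref(start + frag - config.read_len)
        predicted = to_ref(start + frag) - to_ref(start)
        out[acc] = FragmentTable(config.chrom, left_inner, right_inner, predicted)
    return out


# ---------------------------------------------------------------------------
# XP-CLR-style score tables


def simulate_xpclr_scores(config: SimConfig, window: int = 50_000,
                          step: int = 5_000):
    """Synthesize per-pool raw score tables shaped like an XP-CLR scan.

    Neutral windows draw Exp(1) raw scores; windows overlapping a planted
    sweep of the pool draw Uniform(40, 80), so mean-normalized scores
    clear the conventional >=5 cutoff inside sweeps.
    """
    import pandas as pd

    from .popgen import sliding_windows

    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    wins = list(sliding_windows({config.chrom: config.chrom_length},
                                window=window, step=step))
    tables = {}
    for pool in ("AI", "MI"):
        regs = [r for r in config.sweep_regions() if r.applies_to(pool)]
        rows = []
        for chrom, ws, we in wins:
            swept = any(ws < r.end and r.start < we for r in regs)
            raw = rng.uniform(40.0, 80.0) if swept else rng.exponential(1.0)
            rows.append((chrom, ws, we, raw))
        tables[pool] = pd.DataFrame(
            rows, columns=["chrom", "window_start", "window_end", "raw_score"])
    return tables


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Run the full generator and bundle every layer of the cohort."""
    config.validate()
    genotypes = simulate_snp_genotypes(config)
    tes, truth, dels, te_classes = simulate_te_deletions(config, genotypes)
    read_pairs = simulate_read_pairs(config, dels, genotypes.accessions)
    return SimulatedCohort(
        config=config,
        genotypes=genotypes,
        te_annotations=tes,
        te_classes=te_classes,
        deletion_truth=truth,
        deletions_per_sample=dels,
        read_pairs=read_pairs,
        genes=config.gene_models(),
        sweep_truth=config.sweep_regions(),
        xpclr_scores=simulate_xpclr_scores(config),
        population_map=config.population_map(),
    )
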