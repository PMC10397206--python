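"""Core in-memory containers shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; 1-based
conventions apply only at VCF/GFF3 emission and parsing boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical population labels: domesticated/wild of the Andean (AI) and
#: Mesoamerican (MI) gene pools.
POPULATIONS = ("DOM_AI", "WILD_AI", "DOM_MI", "WILD_MI")

#: Gene pool -> member populations.
POOLS = {
    "AI": ("DOM_AI", "WILD_AI"),
    "MI": ("DOM_MI", "WILD_MI"),
}

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid genotypes at biallelic SNPs for a labelled cohort.

    genotypes codes: 0=hom-ref, 1=het, 2=hom-alt, -1=missing.
    Shape is (n_accessions, n_sites); positions are 1-based and strictly
    increasing within each chromosome.
    """

    accessions: list[str]
    chroms: np.ndarray  # per-site chromosome name (str array)
    positions: np.ndarray  # per-site 1-based position (int array)
    genotypes: np.ndarray  # int8 (n_acc, n_sites)
    population_map: dict[str, str]

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.accessions), len(self.positions)):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} inconsistent with "
                f"{len(self.accessions)} accessions x {len(self.positions)} sites"
            )
        bad = set(np.unique(self.genotypes)) - {-1, 0, 1, 2}
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        missing_pop = [a for a in self.accessions if a not in self.population_map]
        if missing_pop:
            raise ValueError(f"accessions without population label: {missing_pop}")
        for c in np.unique(self.chroms.astype(str)):
            pos = self.positions[self.chroms == c]
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def accession_indices(self, populations) -> np.ndarray:
        """Row indices of accessions belonging to any of `populations`."""
        wanted = set(populations)
        idx = [i for i, a in enumerate(self.accessions)
               if self.population_map[a] in wanted]
        return np.asarray(idx, dtype=np.intp)

    def pool_indices(self, pool: str) -> np.ndarray:
        return self.accession_indices(POOLS[pool])

    def take_sites(self, mask_or_idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            accessions=list(self.accessions),
            chroms=self.chroms[mask_or_idx],
            positions=self.positions[mask_or_idx],
            genotypes=self.genotypes[:, mask_or_idx],
            population_map=dict(self.population_map),
        )


@dataclass(frozen=True)
class TEAnnotation:
    """A transposable-element interval with its superfamily label."""

    id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    superfamily: str
    family: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"TE {self.id}: end {self.end} <= start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Deletion:
    chrom: str
    start: int
    end: int
    support: int = 0
    quality: float = 0.0
    est_length: float = 0.0  # read-pair estimate; 0 when unknown

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"deletion end {self.end} <= start {self.start}")


@dataclass
class DeletionCallSet:
    """Per-accession large-deletion intervals (truth or called)."""

    calls: dict[str, list[Deletion]] = field(default_factory=dict)

    def add(self, accession: str, deletion: Deletion) -> None:
        self.calls.setdefault(accession, []).append(deletion)

    def get(self, accession: str) -> list[Deletion]:
        return self.calls.get(accession, [])

    @property
    def accessions(self) -> list[str]:
        return sorted(self.calls)

    def n_calls(self) -> int:
        return sum(len(v) for v in self.calls.values())


@dataclass
class PAVMatrix:
    """Accessions x TEs presence(1)/absence(0) matrix; -1 = missing."""

    accessions: list[str]
    te_ids: list[str]
    codes: np.ndarray  # int8 (n_acc, n_te)
    overlap_threshold: float = 0.85

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.accessions), len(self.te_ids)):
            raise ValueError("PAV codes shape inconsistent with labels")
        bad = set(np.unique(self.codes)) - {-1, 0, 1}
        if bad:
            raise ValueError(f"invalid PAV codes: {sorted(bad)}")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_tes(self) -> int:
        return len(self.te_ids)


@dataclass(frozen=True)
class GeneModel:
    """A gene interval; exons are optional (needed only for intron calls)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.id}: end <= start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FragmentRecord:
    """A read-pair's reference-projected evidence.

    left_inner/right_inner bound the unsequenced gap between the two reads
    (0-based half-open); predicted_length is the reference-projected
    fragment length inferred from the mapped endpoints.
    """

    chrom: str
    left_inner: int
    right_inner: int
    predicted_length: int
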