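"""Diversity and differentiation statistics, distances and neighbor-joining.

Nucleotide diversity is computed from unphased diploid genotypes via the
unbiased per-site estimator sum_k k(n-k) / C(n,2) (equivalently
[n/(n-1)] 2p(1-p)), summed over sites and divided by the interval length.
FST uses Hudson's ratio-of-sums estimator, which is robust to unequal
sample sizes: FST = 1 - sum(mean within-population diversity) /
sum(between-population diversity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import POOLS, POPULATIONS, GeneModel, GenotypeMatrix, PAVMatrix

logger = logging.getLogger(__name__)


def _subset_indices(matrix: GenotypeMatrix, subset) -> np.ndarray:
    """Resolve a subset given as population labels, a pool name, or
    accession labels, into row indices."""
    if isinstance(subset, str):
        subset = POOLS[subset] if subset in POOLS else [subset]
    subset = list(subset)
    if all(s in POPULATIONS for s in subset):
        idx = matrix.accession_indices(subset)
    else:
        pos = {a: i for i, a in enumerate(matrix.accessions)}
        try:
            idx = np.array([pos[s] for s in subset], dtype=np.intp)
        except KeyError as e:
            raise ValueError(f"unknown accession or population: {e}") from e
    if len(idx) == 0:
        raise ValueError(f"empty accession subset: {subset}")
    return idx


def _site_mask(matrix: GenotypeMatrix, interval) -> np.ndarray:
    chrom, start, end = interval
    return ((matrix.chroms.astype(str) == chrom)
            & (matrix.positions - 1 >= start)
            & (matrix.positions - 1 < end))


def _het_terms(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site unbiased heterozygosity 2p(1-p)n/(n-1) and allele counts n.

    Sites with n < 2 get term 0 (they carry no pair information).
    """
    genotyped = g >= 0
    n = 2 * genotyped.sum(axis=0)
    k = np.where(genotyped, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        term = 2.0 * k * (n - k) / (n * (n - 1.0))
    return np.where(n >= 2, term, 0.0), n


def nucleotide_diversity(matrix: GenotypeMatrix, subset, interval) -> float:
    """Per-bp nucleotide diversity pi of `subset` over `interval`
    (0-based half-open)."""
    chrom, start, end = interval
    if end <= start:
        raise ValueError("interval length must be > 0")
    idx = _subset_indices(matrix, subset)
    mask = _site_mask(matrix, interval)
    terms, _ = _het_terms(matrix.genotypes[np.ix_(idx, np.flatnonzero(mask))])
    return float(terms.sum() / (end - start))


def _between_terms(ga: np.ndarray, gb: np.ndarray):
    """Per-site mean within (0.5(hw_a+hw_b)) and between
    (pa(1-pb)+pb(1-pa)) diversities, plus usability mask."""
    ha, na = _het_terms(ga)
    hb_, nb = _het_terms(gb)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(ga >= 0, ga, 0).sum(axis=0) / na
        pb = np.where(gb >= 0, gb, 0).sum(axis=0) / nb
    usable = (na >= 2) & (nb >= 2)
    between = np.where(usable, pa * (1 - pb) + pb * (1 - pa), 0.0)
    within = np.where(usable, 0.5 * (ha + hb_), 0.0)
    return within, between, usable


def fst(matrix: GenotypeMatrix, pop_a, pop_b, interval=None) -> float:
    """Hudson ratio-of-sums FST between two accession subsets.

    Sites lacking >=2 genotyped alleles in either subset are skipped.
    Returns NaN (logged) when no usable site has between-population
    diversity.
    """
    ia = _subset_indices(matrix, pop_a)
    ib = _subset_indices(matrix, pop_b)
    if interval is None:
        cols = np.arange(matrix.n_sites)
    else:
        cols = np.flatnonzero(_site_mask(matrix, interval))
    within, between, usable = _between_terms(
        matrix.genotypes[np.ix_(ia, cols)], matrix.genotypes[np.ix_(ib, cols)])
    denom = between.sum()
    if not usable.any() or denom == 0:
        logger.warning("fst: no usable between-population diversity; NaN")
        return float("nan")
    return float(1.0 - within.sum() / denom)


def sliding_windows(chrom_lengths: dict[str, int], window: int = 50_000,
                    step: int = 5_000, include_trailing: bool = False):
    """Yield (chrom, start, end) windows anchored at coordinate 0.

    Full windows [k*step, k*step+window); one trailing partial window is
    appended only when `include_trailing` is set. Chromosomes shorter
    than `window` yield nothing (logged).
    """
    if not (window >= step > 0):
        raise ValueError("require window >= step > 0")
    for chrom, length in chrom_lengths.items():
        if length < window:
            logger.info("sliding_windows: %s shorter than window", chrom)
            n_full = 0
        else:
            n_full = (length - window) // step + 1
        for k in range(n_full):
            yield chrom, k * step, k * step + window
        if include_trailing and n_full * step < length:
            yield chrom, n_full * step, length


def window_scan(matrix: GenotypeMatrix, pool: str, windows) -> pd.DataFrame:
    """Per-window pi (wild and domesticated subsets of `pool`),
    diversity-reduction ratio and Hudson FST.

    pi_reduction is NaN where pi_wild is 0 (undefined ratio; such
    windows are excluded from downstream decile ranking).
    """
    iw = matrix.accession_indices([f"WILD_{pool}"])
    idm = matrix.accession_indices([f"DOM_{pool}"])
    if len(iw) == 0 or len(idm) == 0:
        raise ValueError(f"pool {pool}: empty wild or domesticated subset")
    hw, _ = _het_terms(matrix.genotypes[iw])
    hd, _ = _het_terms(matrix.genotypes[idm])
    within, between, usable = _between_terms(
        matrix.genotypes[iw], matrix.genotypes[idm])

    chroms = matrix.chroms.astype(str)
    rows = []
    for chrom, start, end in windows:
        onchrom = chroms == chrom
        pos = matrix.positions[onchrom] - 1
        lo, hi = np.searchsorted(pos, [start, end])
        sel = np.flatnonzero(onchrom)[lo:hi]
        length = end - start
        pi_w = hw[sel].sum() / length
        pi_d = hd[sel].sum() / length
        pi_red = (pi_w - pi_d) / pi_w if pi_w > 0 else np.nan
        denom = between[sel].sum()
        f = 1.0 - within[sel].sum() / denom if denom > 0 else np.nan
        rows.append((chrom, start, end, pi_w, pi_d, pi_red, f,
                     int(usable[sel].sum())))
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "pi_wild", "pi_dom", "pi_reduction",
        "fst", "n_sites"])


def gene_scan(matrix: GenotypeMatrix, pool: str,
              genes: list[GeneModel]) -> pd.DataFrame:
    """Per-gene diversity (as average pairwise differences per kbp, i.e.
    1000*pi) for the wild and domesticated subsets and wild-vs-dom FST."""
    df = window_scan(matrix, pool,
                     [(g.chrom, g.start, g.end) for g in genes])
    df.insert(0, "gene", [g.id for g in genes])
    df["diff_per_kbp_wild"] = 1000.0 * df.pi_wild
    df["diff_per_kbp_dom"] = 1000.0 * df.pi_dom
    return df


# ---------------------------------------------------------------------------
# distances and neighbor-joining


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if (self.values < 0).any() or not np.allclose(np.diag(self.values), 0):
            raise ValueError("distances must be nonnegative with zero diagonal")


def snp_distance_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """1 - identity-by-state share over co-genotyped sites.

    IBS share per pair = mean of (2 - |g_i - g_j|)/2.
    """
    g = matrix.genotypes.astype(np.int16)
    ok = g >= 0
    n = matrix.n_accessions
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            if not both.any():
                raise ValueError(
                    f"no co-genotyped sites for {matrix.accessions[i]} / "
                    f"{matrix.accessions[j]}")
            ibs = np.mean((2 - np.abs(g[i, both] - g[j, both])) / 2.0)
            d[i, j] = d[j, i] = 1.0 - ibs
    return DistanceMatrix(list(matrix.accessions), d)


def pav_distance_matrix(pav: PAVMatrix) -> DistanceMatrix:
    """Simple mismatch fraction over co-called TEs."""
    c = pav.codes
    ok = c >= 0
    n = pav.n_accessions
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            if not both.any():
                raise ValueError(
                    f"no co-called TEs for {pav.accessions[i]} / "
                    f"{pav.accessions[j]}")
            d[i, j] = d[j, i] = np.mean(c[i, both] != c[j, both])
    return DistanceMatrix(list(pav.accessions), d)


def distance_matrix(data) -> DistanceMatrix:
    if isinstance(data, GenotypeMatrix):
        return snp_distance_matrix(data)
    if isinstance(data, PAVMatrix):
        return pav_distance_matrix(data)
    raise TypeError(f"unsupported input type {type(data)!r}")


@dataclass
class TreeNode:
    """Node of an unrooted NJ tree (represented rooted at the final join)."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> frozenset:
        if not self.children:
            return frozenset([self.label])
        out = frozenset()
        for child, _ in self.children:
            out |= child.leaves()
        return out

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c._newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def tree_splits(root: TreeNode) -> set[frozenset]:
    """Leaf sets of every edge of the (unrooted) tree."""
    out: set[frozenset] = set()

    def walk(node: TreeNode) -> None:
        for child, _ in node.children:
            out.add(child.leaves())
            walk(child)

    walk(root)
    return out


def is_clade(root: TreeNode, labels) -> bool:
    """True if `labels` forms one side of some bipartition of the tree."""
    want = frozenset(labels)
    all_leaves = root.leaves()
    if not want <= all_leaves:
        raise ValueError("labels not all in tree")
    comp = all_leaves - want
    splits = tree_splits(root)
    return want in splits or comp in splits


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of node labels (internal nodes carry synthetic labels ordered
    after creation). Negative branch lengths are clamped to zero with a
    warning. The returned node joins the final three (or two) lineages.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes = [TreeNode(label=lab) for lab in dm.labels]
    names = list(dm.labels)
    D = dm.values.copy()
    next_internal = 0

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning("neighbor_joining: clamping negative branch %g", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if Q[i, j] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    key = tuple(sorted((names[i], names[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        li = clamp(0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(D[i, j] - (0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))))
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [f"\x00internal{next_internal}"]
        next_internal += 1

    # join the final three lineages at a central node
    (d01, d02, d12) = (D[0, 1], D[0, 2], D[1, 2])
    l0 = clamp(0.5 * (d01 + d02 - d12))
    l1 = clamp(0.5 * (d01 + d12 - d02))
    l2 = clamp(0.5 * (d02 + d12 - d01))
    return TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])
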