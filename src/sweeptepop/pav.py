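"""TE presence-absence genotyping and its statistics.

A simplified read-pair deletion caller flags fragments with abnormally
large reference-projected lengths, clusters mutually overlapping
discordant pairs and emits a deletion per sufficiently supported
cluster. TE presence/absence is then genotyped per accession from the
fractional overlap between the TE and the union of that accession's
deletions: the TE is coded absent (0) when at least a fixed fraction of
its base pairs is covered, present (1, the reference allele) otherwise.

Downstream statistics mirror standard PAV analyses: per-TE minor allele
frequency, per-accession deletion counts, singleton detection, exact
Fisher differentiation between population groups at fixed stringent
alphas (no multiple-testing correction — error control is via the
thresholds themselves), Wilcoxon rank-sum comparisons of deletion
counts, chi-square superfamily overrepresentation, and hierarchical /
neighbor-joining clustering of the binary matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .popgen import neighbor_joining, pav_distance_matrix
from .simulate import FragmentTable
from .types import Deletion, DeletionCallSet, PAVMatrix, TEAnnotation

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# deletion calling


def call_deletions(
    read_pairs: dict[str, FragmentTable],
    insert_mean: float,
    insert_sd: float,
    z_cutoff: float = 4.0,
    min_support: int = 3,
) -> DeletionCallSet:
    """Call large deletions per accession from fragment evidence.

    Discordant pairs (predicted length > insert_mean + z_cutoff*insert_sd)
    are clustered so that every pair in a cluster overlaps the running
    intersection of inner intervals; each cluster with >= min_support
    pairs emits a deletion spanning that intersection, with estimated
    length median(predicted) - insert_mean.
    """
    if insert_sd <= 0:
        raise ValueError("insert_sd must be > 0")
    cutoff = insert_mean + z_cutoff * insert_sd
    out = DeletionCallSet()
    for acc, ft in read_pairs.items():
        disc = ft.predicted_length > cutoff
        if not disc.any():
            continue
        order = np.argsort(ft.left_inner[disc], kind="stable")
        lefts = ft.left_inner[disc][order]
        rights = ft.right_inner[disc][order]
        preds = ft.predicted_length[disc][order]

        def emit(members: list[int], lo: int, hi: int) -> None:
            if len(members) >= min_support and hi > lo:
                est = float(np.median(preds[members]) - insert_mean)
                out.add(acc, Deletion(ft.chrom, int(lo), int(hi),
                                      support=len(members),
                                      quality=float(len(members)),
                                      est_length=est))

        members: list[int] = []
        lo = hi = 0
        for k in range(len(lefts)):
            if members and lefts[k] < hi:
                members.append(k)
                lo = max(lo, int(lefts[k]))
                hi = min(hi, int(rights[k]))
            else:
                emit(members, lo, hi)
                members = [k]
                lo, hi = int(lefts[k]), int(rights[k])
        emit(members, lo, hi)
    return out


# ---------------------------------------------------------------------------
# PAV genotyping


def _merged_intervals(dels: list[Deletion]) -> dict[str, np.ndarray]:
    """Per-chromosome union of deletion intervals as (k,2) arrays."""
    by_chrom: dict[str, list] = {}
    for d in dels:
        by_chrom.setdefault(d.chrom, []).append((d.start, d.end))
    out = {}
    for chrom, ivals in by_chrom.items():
        merged = []
        for s, e in sorted(ivals):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged, dtype=np.int64)
    return out


def _covered_bp(merged: np.ndarray, start: int, end: int) -> int:
    starts, ends = merged[:, 0], merged[:, 1]
    i0 = np.searchsorted(ends, start, side="right")
    i1 = np.searchsorted(starts, end, side="left")
    if i1 <= i0:
        return 0
    s = np.maximum(starts[i0:i1], start)
    e = np.minimum(ends[i0:i1], end)
    return int(np.maximum(e - s, 0).sum())


def genotype_pav(tes: list[TEAnnotation], dels: DeletionCallSet,
                 accessions: list[str], threshold: float = 0.85) -> PAVMatrix:
    """Binary presence/absence per accession x TE at an overlap threshold.

    Code 0 (absent) iff the union of the accession's deletions covers at
    least `threshold` of the TE's length ("at least" = inclusive).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    codes = np.ones((len(accessions), len(tes)), dtype=np.int8)
    for i, acc in enumerate(accessions):
        merged = _merged_intervals(dels.get(acc))
        for j, te in enumerate(tes):
            m = merged.get(te.chrom)
            if m is None:
                continue
            cov = _covered_bp(m, te.start, te.end)
            if cov / te.length >= threshold:
                codes[i, j] = 0
    return PAVMatrix(accessions=list(accessions), te_ids=[t.id for t in tes],
                     codes=codes, overlap_threshold=threshold)


def filter_pav(pav: PAVMatrix, tes: list[TEAnnotation],
               min_te_length: int = 500,
               require_variable: bool = True) -> PAVMatrix:
    """Drop short TEs (< min_te_length) and, optionally, TEs with no
    deletion evidence in any accession."""
    length = {t.id: t.length for t in tes}
    keep = np.array([length[tid] >= min_te_length for tid in pav.te_ids])
    if require_variable:
        keep &= (pav.codes == 0).any(axis=0)
    return PAVMatrix(
        accessions=list(pav.accessions),
        te_ids=[tid for tid, k in zip(pav.te_ids, keep) if k],
        codes=pav.codes[:, keep],
        overlap_threshold=pav.overlap_threshold)


# ---------------------------------------------------------------------------
# PAV statistics


def pav_maf(pav: PAVMatrix) -> pd.Series:
    """Minor allele frequency per TE over non-missing haploid-style codes."""
    ok = pav.codes >= 0
    n = ok.sum(axis=0)
    absent = (pav.codes == 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = absent / n
        maf = np.minimum(f, 1 - f)
    return pd.Series(np.where(n > 0, maf, np.nan), index=pav.te_ids,
                     name="maf")


def pav_counts(pav: PAVMatrix) -> pd.Series:
    """Number of TE deletions (0 codes) per accession."""
    return pd.Series((pav.codes == 0).sum(axis=1), index=pav.accessions,
                     name="n_deletions")


def singletons(pav: PAVMatrix) -> list[str]:
    """TEs absent in exactly one accession (among non-missing codes)."""
    absent = (pav.codes == 0).sum(axis=0)
    return [tid for tid, a in zip(pav.te_ids, absent) if a == 1]


@dataclass
class TEDifferentiationResult:
    te_id: str
    table: tuple  # ((absent_a, present_a), (absent_b, present_b))
    fisher_p: float
    freq_a: float
    freq_b: float
    significant: bool


def fisher_differentiation(
    pav: PAVMatrix, population_map: dict[str, str],
    group_a, group_b, alpha: float = 1e-10,
) -> list[TEDifferentiationResult]:
    """Exact two-sided Fisher test of absence frequency between two
    population groups, per TE.

    Two-sided p is the minimum-likelihood convention: the sum of
    hypergeometric probabilities of tables no more likely than the
    observed one. TEs with an all-missing group are skipped (logged).
    """
    group_a = set([group_a] if isinstance(group_a, str) else group_a)
    group_b = set([group_b] if isinstance(group_b, str) else group_b)
    ia = [i for i, a in enumerate(pav.accessions)
          if population_map[a] in group_a]
    ib = [i for i, a in enumerate(pav.accessions)
          if population_map[a] in group_b]
    if not ia or not ib:
        raise ValueError("both population groups must be non-empty")
    results = []
    n_skipped = 0
    for j, tid in enumerate(pav.te_ids):
        col_a = pav.codes[ia, j]
        col_b = pav.codes[ib, j]
        ok_a, ok_b = col_a >= 0, col_b >= 0
        if not ok_a.any() or not ok_b.any():
            n_skipped += 1
            continue
        abs_a = int((col_a == 0).sum())
        pres_a = int(ok_a.sum()) - abs_a
        abs_b = int((col_b == 0).sum())
        pres_b = int(ok_b.sum()) - abs_b
        _, p = sps.fisher_exact([[abs_a, pres_a], [abs_b, pres_b]],
                                alternative="two-sided")
        results.append(TEDifferentiationResult(
            te_id=tid,
            table=((abs_a, pres_a), (abs_b, pres_b)),
            fisher_p=float(p),
            freq_a=abs_a / (abs_a + pres_a),
            freq_b=abs_b / (abs_b + pres_b),
            significant=bool(p < alpha)))
    if n_skipped:
        logger.info("fisher_differentiation: skipped %d all-missing TEs",
                    n_skipped)
    return results


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided rank-sum p: exact for small untied samples (<= 12 per
    group), normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 12 and not has_ties) \
        else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method=method).pvalue)


def pav_group_tests(counts: pd.Series,
                    population_map: dict[str, str]) -> pd.DataFrame:
    """Pairwise Wilcoxon comparisons of per-accession deletion counts
    between all population pairs."""
    groups: dict[str, list[float]] = {}
    for acc, c in counts.items():
        groups.setdefault(population_map[acc], []).append(float(c))
    pops = sorted(groups)
    rows = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            p = wilcoxon_rank_sum(groups[pops[i]], groups[pops[j]])
            rows.append((pops[i], pops[j], len(groups[pops[i]]),
                         len(groups[pops[j]]), p))
    return pd.DataFrame(rows, columns=["pop_a", "pop_b", "n_a", "n_b",
                                       "wilcoxon_p"])


@dataclass
class EnrichmentResult:
    chi2: float
    p_value: float
    df: int
    observed: dict[str, int]
    expected: dict[str, float]


def superfamily_enrichment(subset_counts: dict[str, int],
                           background_counts: dict[str, int]) -> EnrichmentResult:
    """Chi-square goodness-of-fit of subset superfamily counts against the
    background superfamily proportions (df = k - 1)."""
    cats = sorted(background_counts)
    bg = np.array([background_counts[c] for c in cats], dtype=float)
    if (bg <= 0).any():
        raise ValueError("background counts must be positive")
    obs = np.array([subset_counts.get(c, 0) for c in cats], dtype=float)
    total = obs.sum()
    if total == 0:
        raise ValueError("empty subset")
    expected = bg / bg.sum() * total
    chi2, p = sps.chisquare(obs, f_exp=expected)
    return EnrichmentResult(
        chi2=float(chi2), p_value=float(p), df=len(cats) - 1,
        observed=dict(zip(cats, obs.astype(int))),
        expected=dict(zip(cats, expected)))


def pav_clustering(pav: PAVMatrix):
    """Average-linkage hierarchical clustering and an NJ tree of the PAV
    mismatch-distance matrix.

    Returns (scipy linkage matrix, TreeNode). Raises if any accession
    pair shares no co-called TE.
    """
    if pav.n_accessions < 3:
        raise ValueError("clustering needs >= 3 accessions")
    dm = pav_distance_matrix(pav)
    linkage = average(squareform(dm.values, checks=False))
    tree = neighbor_joining(dm)
    return linkage, tree
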