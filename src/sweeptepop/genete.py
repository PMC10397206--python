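"""Relating variable TEs to genes: proximity links, PAV-defined gene
alleles, and intersection of variable TEs with sweep regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .types import GeneModel, PAVMatrix, TEAnnotation

logger = logging.getLogger(__name__)


def associate_tes(genes: list[GeneModel], tes: list[TEAnnotation],
                  window: int = 10_000) -> pd.DataFrame:
    """Link each TE to genes it overlaps or flanks within `window` bp
    (boundary inclusive).

    Relations: 'exonic' / 'intronic' when the gene has exon structure and
    the TE does / does not touch an exon; 'gene_body' for overlap without
    exon structure; 'upstream' / 'downstream' by gene strand for flanking
    TEs (distance = gap between closest interval ends, 0 for overlap).
    """
    rows = []
    for g in genes:
        for te in tes:
            if te.chrom != g.chrom:
                continue
            if te.start < g.end and g.start < te.end:  # body overlap
                if g.exons:
                    on_exon = any(te.start < ee and es < te.end
                                  for es, ee in g.exons)
                    relation = "exonic" if on_exon else "intronic"
                else:
                    relation = "gene_body"
                rows.append((g.id, te.id, relation, 0))
                continue
            if te.end <= g.start:
                gap = g.start - te.end
                side = "upstream" if g.strand == "+" else "downstream"
            else:
                gap = te.start - g.end
                side = "downstream" if g.strand == "+" else "upstream"
            if gap <= window:
                rows.append((g.id, te.id, side, gap))
    return pd.DataFrame(rows, columns=["gene", "te", "relation", "distance"])


@dataclass
class AlleleConfiguration:
    """Distinct PAV patterns over a gene's variable TEs.

    alleles: list of (pattern string over ordered TEs, carrier count,
    carrier accession tuple); the reference (all-present) pattern is
    listed first when observed, the rest by descending carrier count.
    """

    gene: str
    te_ids: list[str]
    alleles: list[tuple[str, int, tuple]]
    n_excluded_missing: int = 0

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


def enumerate_alleles(gene: GeneModel, linked_te_ids: list[str],
                      pav: PAVMatrix) -> AlleleConfiguration:
    """Enumerate a gene's PAV alleles from its linked variable TEs.

    TEs are restricted to those variable in the matrix, ordered by their
    column order (coordinate order for matrices built from a coordinate-
    sorted annotation). Accessions with any missing code among those TEs
    are excluded (logged).
    """
    col = {tid: j for j, tid in enumerate(pav.te_ids)}
    cols = [col[t] for t in linked_te_ids if t in col]
    cols = [j for j in sorted(cols) if (pav.codes[:, j] == 0).any()]
    if not cols:
        return AlleleConfiguration(gene=gene.id, te_ids=[], alleles=[])
    sub = pav.codes[:, cols]
    complete = (sub >= 0).all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info("enumerate_alleles(%s): excluded %d accessions with "
                    "missing codes", gene.id, n_excluded)
    patterns: dict[str, list[str]] = {}
    for i, acc in enumerate(pav.accessions):
        if not complete[i]:
            continue
        pat = "".join(str(int(c)) for c in sub[i])
        patterns.setdefault(pat, []).append(acc)
    ref = "1" * len(cols)
    ordered = sorted(patterns,
                     key=lambda p: (p != ref, -len(patterns[p]), p))
    alleles = [(p, len(patterns[p]), tuple(patterns[p])) for p in ordered]
    return AlleleConfiguration(
        gene=gene.id,
        te_ids=[pav.te_ids[j] for j in cols],
        alleles=alleles,
        n_excluded_missing=n_excluded)


def tes_in_sweeps(tes_variable: list[TEAnnotation],
                  sweep_regions: dict[str, list]) -> dict[str, set[str]]:
    """Assign variable TEs to gene pools by >=1 bp overlap with that
    pool's sweep regions.

    Returns sets keyed by pool plus '<pool>_exclusive' and 'shared'
    (TEs overlapping sweeps of every pool).
    """
    per_pool: dict[str, set[str]] = {}
    for pool, regions in sweep_regions.items():
        hits = set()
        for te in tes_variable:
            for chrom, start, end in regions:
                if te.chrom == chrom and te.start < end and start < te.end:
                    hits.add(te.id)
                    break
        per_pool[pool] = hits
    out = dict(per_pool)
    pools = list(per_pool)
    if len(pools) >= 2:
        shared = set.intersection(*per_pool.values())
        out["shared"] = shared
        for pool in pools:
            others = set.union(*(per_pool[p] for p in pools if p != pool))
            out[f"{pool}_exclusive"] = per_pool[pool] - others
    return out
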