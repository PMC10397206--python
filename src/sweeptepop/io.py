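"""Readers and writers for the standard formats the pipeline touches.

File conventions are 1-based inclusive (VCF, GFF3) or 0-based half-open
(BED); everything is converted to the package's internal 0-based
half-open intervals on read and back on write. No reader drops records
silently: every skipped record increments a logged counter that the
reader also returns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simulate import FragmentTable
from .types import (
    Deletion,
    DeletionCallSet,
    GeneModel,
    GenotypeMatrix,
    PAVMatrix,
    TEAnnotation,
)

logger = logging.getLogger(__name__)

# cyvcf2 gt_types -> internal codes (0 hom-ref, 1 het, 2 hom-alt, -1 missing)
_CYVCF2_CODE = {0: 0, 1: 1, 2: -1, 3: 2}
_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


# ---------------------------------------------------------------------------
# population map


def read_population_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["accession", "population"],
                     dtype=str, comment="#")
    return dict(zip(df.accession, df.population))


def write_population_map(pop_map: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for acc, pop in pop_map.items():
            fh.write(f"{acc}\t{pop}\n")


# ---------------------------------------------------------------------------
# SNP VCF


def read_vcf(path, population_map_path) -> tuple[GenotypeMatrix, int]:
    """Load a diploid SNP VCF into a GenotypeMatrix.

    Multi-allelic records are skipped (logged and returned as a count);
    missing genotypes become -1. Accession order follows the VCF header.
    Every sample must appear in the population map.
    """
    pop_map = read_population_map(population_map_path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in pop_map]
    if unknown:
        raise ValueError(f"samples absent from population map: {unknown}")

    chroms, positions, rows = [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        chroms.append(var.CHROM)
        positions.append(var.POS)
        rows.append([_CYVCF2_CODE[t] for t in var.gt_types])
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic records", n_skipped)
    geno = (np.array(rows, dtype=np.int8).T if rows
            else np.zeros((len(samples), 0), dtype=np.int8))
    matrix = GenotypeMatrix(
        accessions=samples,
        chroms=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        genotypes=geno,
        population_map={s: pop_map[s] for s in samples},
    )
    return matrix, n_skipped


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Emit a deterministic, byte-stable VCFv4.2 with GT-only genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweeptepop\n")
        for chrom in sorted(set(matrix.chroms.astype(str))):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.accessions) + "\n")
        for j in range(matrix.n_sites):
            gts = "\t".join(_GT_STRING[int(g)] for g in matrix.genotypes[:, j])
            fh.write(f"{matrix.chroms[j]}\t{matrix.positions[j]}\t"
                     f"snp{j}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# GFF3 / BED intervals


def _gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _iter_gff3(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            start, end = int(fields[3]), int(fields[4])
            if end < start:
                raise ValueError(f"{path}:{lineno}: end {end} < start {start}")
            yield lineno, fields, start - 1, end  # 0-based half-open


def read_te_gff3(path) -> list[TEAnnotation]:
    tes = []
    for lineno, fields, start, end in _iter_gff3(path):
        attrs = _gff3_attributes(fields[8])
        tes.append(TEAnnotation(
            id=attrs.get("ID", f"TE_line{lineno}"),
            chrom=fields[0], start=start, end=end,
            superfamily=attrs.get("Superfamily", fields[2]),
            family=attrs.get("Family", ""),
        ))
    return tes


def write_te_gff3(tes: list[TEAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for te in tes:
            fh.write(f"{te.chrom}\tsweeptepop\ttransposable_element\t"
                     f"{te.start + 1}\t{te.end}\t.\t+\t.\t"
                     f"ID={te.id};Superfamily={te.superfamily};Family={te.family}\n")


def read_genes_gff3(path) -> list[GeneModel]:
    """Parse gene features; exon features are attached via their Parent."""
    genes, exons = {}, {}
    for lineno, fields, start, end in _iter_gff3(path):
        ftype = fields[2].lower()
        attrs = _gff3_attributes(fields[8])
        if ftype == "gene":
            gid = attrs.get("ID", f"gene_line{lineno}")
            genes[gid] = (fields[0], start, end, fields[6])
        elif ftype == "exon":
            parent = attrs.get("Parent")
            if parent:
                exons.setdefault(parent, []).append((start, end))
    out = []
    for gid, (chrom, start, end, strand) in genes.items():
        out.append(GeneModel(id=gid, chrom=chrom, start=start, end=end,
                             strand=strand if strand in "+-" else "+",
                             exons=tuple(sorted(exons.get(gid, [])))))
    return out


def write_genes_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tsweeptepop\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.id}\n")
            for k, (es, ee) in enumerate(g.exons):
                fh.write(f"{g.chrom}\tsweeptepop\texon\t{es + 1}\t{ee}\t.\t"
                         f"{g.strand}\t.\tID={g.id}.exon{k};Parent={g.id}\n")


# ---------------------------------------------------------------------------
# deletions


def write_deletions_bed(dels: DeletionCallSet, path) -> None:
    """BED-style table: chrom, start, end, accession, support, quality,
    estimated length."""
    with open(path, "w") as fh:
        for acc in dels.accessions:
            for d in sorted(dels.get(acc), key=lambda d: (d.chrom, d.start)):
                fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{acc}\t"
                         f"{d.support}\t{d.quality:g}\t{d.est_length:g}\n")


def read_deletions(path) -> DeletionCallSet:
    """Read per-accession deletions from the BED-style table or a DEL VCF."""
    path = str(path)
    if path.endswith(".vcf"):
        return _read_deletions_vcf(path)
    dels = DeletionCallSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: need >=4 columns")
            start, end = int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end {end} <= start {start}")
            support = int(fields[4]) if len(fields) > 4 else 0
            quality = float(fields[5]) if len(fields) > 5 else 0.0
            est = float(fields[6]) if len(fields) > 6 else 0.0
            dels.add(fields[3],
                     Deletion(fields[0], start, end, support, quality, est))
    return dels


def _read_deletions_vcf(path) -> DeletionCallSet:
    dels = DeletionCallSet()
    vcf = VCF(path)
    samples = list(vcf.samples)
    for var in vcf:
        if var.INFO.get("SVTYPE") != "DEL":
            continue
        end = int(var.INFO.get("END"))
        for i, t in enumerate(var.gt_types):
            if t == 3:  # hom-alt = deletion carrier
                dels.add(samples[i], Deletion(var.CHROM, var.POS - 1, end))
    vcf.close()
    return dels


def write_deletions_vcf(dels: DeletionCallSet, accessions: list[str], path) -> None:
    """Merged symbolic-DEL VCF: one record per distinct deletion interval."""
    carriers: dict[tuple[str, int, int], set[str]] = {}
    for acc in dels.accessions:
        for d in dels.get(acc):
            carriers.setdefault((d.chrom, d.start, d.end), set()).add(acc)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(accessions) + "\n")
        for k, (chrom, start, end) in enumerate(sorted(carriers)):
            gts = "\t".join("1/1" if a in carriers[(chrom, start, end)] else "0/0"
                            for a in accessions)
            fh.write(f"{chrom}\t{start + 1}\tdel{k}\tN\t<DEL>\t.\tPASS\t"
                     f"SVTYPE=DEL;END={end}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# PAV matrix


def write_pav_tsv(pav: PAVMatrix, path) -> None:
    df = pd.DataFrame(pav.codes, index=pav.accessions, columns=pav.te_ids)
    df.to_csv(path, sep="\t", index_label="accession")


def read_pav_tsv(path, overlap_threshold: float = 0.85) -> PAVMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PAVMatrix(accessions=list(df.index), te_ids=list(df.columns),
                     codes=df.to_numpy(dtype=np.int8),
                     overlap_threshold=overlap_threshold)


def write_pav_vcf(pav: PAVMatrix, tes: list[TEAnnotation], path) -> None:
    """PAV as a symbolic-deletion VCF: presence is the reference allele,
    absence (TE deleted) is the ALT allele."""
    te_by_id = {t.id: t for t in tes}
    missing = [tid for tid in pav.te_ids if tid not in te_by_id]
    if missing:
        raise ValueError(f"TE ids without annotation: {missing[:5]}")
    gt = {1: "0/0", 0: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=TEID,Number=1,Type=String,Description="TE id">\n')
        fh.write('##ALT=<ID=DEL,Description="TE deletion">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(pav.accessions) + "\n")
        for j, tid in enumerate(pav.te_ids):
            te = te_by_id[tid]
            gts = "\t".join(gt[int(c)] for c in pav.codes[:, j])
            fh.write(f"{te.chrom}\t{te.start + 1}\t{tid}\tN\t<DEL>\t.\tPASS\t"
                     f"SVTYPE=DEL;END={te.end};TEID={tid}\tGT\t{gts}\n")


def read_pav_vcf(path, overlap_threshold: float = 0.85) -> PAVMatrix:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    te_ids, cols = [], []
    code = {0: 1, 1: -1, 2: -1, 3: 0}  # hom-ref=present, hom-alt=absent
    for var in vcf:
        te_ids.append(var.INFO.get("TEID") or var.ID)
        cols.append([code[t] for t in var.gt_types])
    vcf.close()
    codes = (np.array(cols, dtype=np.int8).T if cols
             else np.zeros((len(samples), 0), dtype=np.int8))
    return PAVMatrix(accessions=samples, te_ids=te_ids, codes=codes,
                     overlap_threshold=overlap_threshold)


# ---------------------------------------------------------------------------
# fragment evidence


def write_fragments_tsv(read_pairs: dict[str, FragmentTable], path) -> None:
    frames = []
    for acc in sorted(read_pairs):
        ft = read_pairs[acc]
        frames.append(pd.DataFrame({
            "accession": acc, "chrom": ft.chrom,
            "left_inner": ft.left_inner, "right_inner": ft.right_inner,
            "predicted_length": ft.predicted_length}))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path) -> dict[str, FragmentTable]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for (acc, chrom), sub in df.groupby(["accession", "chrom"]):
        out[acc] = FragmentTable(
            chrom=chrom,
            left_inner=sub.left_inner.to_numpy(np.int64),
            right_inner=sub.right_inner.to_numpy(np.int64),
            predicted_length=sub.predicted_length.to_numpy(np.int64),
        )
    return out


# ---------------------------------------------------------------------------
# XP-CLR score tables


@dataclass
class XPCLRTable:
    """Window scores from a cross-population composite-likelihood scan."""

    df: pd.DataFrame  # chrom, window_start, window_end, raw_score, normalized_score
    normalization: str
    n_dropped: int = 0


def import_xpclr(path_or_df, normalization: str = "mean") -> XPCLRTable:
    """Load a raw XP-CLR window table and attach normalized scores.

    ``normalization='mean'`` divides raw scores by their genome-wide mean
    (the conventional reading of a "normalized" XP-CLR scan);
    ``'zscore'`` standardizes instead. NaN or negative raw scores are
    dropped with a logged count.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t")
    required = ["chrom", "window_start", "window_end", "raw_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"XP-CLR table missing columns: {missing}")
    n0 = len(df)
    df = df[np.isfinite(df.raw_score) & (df.raw_score >= 0)].copy()
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("import_xpclr: dropped %d NaN/negative rows", n_dropped)
    if df.empty:
        raise ValueError("XP-CLR table is empty after dropping invalid rows")
    df = df.sort_values(["chrom", "window_start"]).reset_index(drop=True)
    if normalization == "mean":
        df["normalized_score"] = df.raw_score / df.raw_score.mean()
    elif normalization == "zscore":
        sd = df.raw_score.std(ddof=0)
        df["normalized_score"] = ((df.raw_score - df.raw_score.mean()) / sd
                                  if sd > 0 else 0.0)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return XPCLRTable(df=df, normalization=normalization, n_dropped=n_dropped)
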