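"""Candidate-gene lookup, allele-effect summaries and plot-ready exports.

Given QTL blocks, gene models from a GFF3 file are screened for overlap;
non-overlapping genes are reported with their signed distance from the
block's top marker.  Allele-class summaries reproduce the customary
"x% higher phenotypic value in class A/B vs the reference class"
statement with a rank-sum test.  Manhattan and QQ exports provide the
cumulative genome coordinate tables and the genomic inflation factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import QTLBlock
from .assoc import AssociationScan

logger = logging.getLogger(__name__)


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "."
    annotation: str = ""


def read_gff3(path: str, feature_type: str = "gene") -> list[GeneRecord]:
    """Parse gene models from a GFF3 file (in-memory gffutils database)."""
    import gffutils

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for f in db.features_of_type(feature_type):
        note = ";".join(f.attributes.get("Note", [])
                        or f.attributes.get("description", []))
        genes.append(GeneRecord(f.id, f.seqid, f.start, f.end, f.strand, note))
    return genes


def genes_in_qtl(qtl: QTLBlock, genes: list[GeneRecord],
                 top_marker_pos: int | None = None) -> pd.DataFrame:
    """Genes overlapping the QTL window, or nearby genes with their signed
    distance from the block's top marker.

    Overlapping genes get distance 0 and location "within".  Otherwise the
    distance runs from the top marker position to the nearest gene edge,
    labelled upstream (gene before the marker) or downstream (gene after).
    """
    same = [g for g in genes if str(g.chrom) == str(qtl.chrom)]
    if genes and not same:
        logger.warning("genes_in_qtl: no genes on chromosome %s", qtl.chrom)
        return pd.DataFrame(columns=["gene_id", "chrom", "start", "end",
                                     "strand", "distance_bp", "location",
                                     "annotation"])
    rows = []
    pos = top_marker_pos
    for g in same:
        if g.start <= qtl.end and qtl.start <= g.end:
            rows.append((g.gene_id, g.chrom, g.start, g.end, g.strand, 0,
                         "within", g.annotation))
        elif pos is not None:
            if g.start > pos:
                rows.append((g.gene_id, g.chrom, g.start, g.end, g.strand,
                             g.start - pos, "downstream", g.annotation))
            else:
                rows.append((g.gene_id, g.chrom, g.start, g.end, g.strand,
                             pos - g.end, "upstream", g.annotation))
    out = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                      "strand", "distance_bp", "location",
                                      "annotation"])
    return out.sort_values("distance_bp").reset_index(drop=True)


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "ns"


def allele_effect_summary(dosages: np.ndarray, blues: pd.Series,
                          alleles: tuple[str, str] = ("A", "T"),
                          min_class_n: int = 3) -> pd.DataFrame:
    """Per-genotype-class phenotype summary at one marker.

    Classes are labelled from REF/ALT alleles (dosage 0 = ref/ref,
    1 = ref/alt, 2 = alt/alt).  The reference class is the most frequent
    one; each other class is reported as its percent difference
    ``100 * (mean_class - mean_ref) / mean_ref`` with a two-sided
    Wilcoxon rank-sum p-value (classes below ``min_class_n`` members are
    counted but not tested).
    """
    d = np.asarray(dosages)
    y = blues.to_numpy(dtype=float) if isinstance(blues, pd.Series) else \
        np.asarray(blues, dtype=float)
    if len(d) != len(y):
        raise ValueError("dosages and phenotype lengths differ")
    ref, alt = alleles
    labels = {0: f"{ref}/{ref}", 1: f"{ref}/{alt}", 2: f"{alt}/{alt}"}
    classes = [c for c in (0, 1, 2) if (d == c).any()]
    counts = {c: int((d == c).sum()) for c in classes}
    ref_class = max(classes, key=lambda c: counts[c])
    y_ref = y[d == ref_class]
    rows = []
    for c in classes:
        yc = y[d == c]
        if c == ref_class:
            rows.append((labels[c], counts[c], float(yc.mean()), 0.0, np.nan,
                         "ref"))
            continue
        pct = 100.0 * (yc.mean() - y_ref.mean()) / y_ref.mean()
        if counts[c] >= min_class_n and counts[ref_class] >= min_class_n:
            p = float(stats.mannwhitneyu(yc, y_ref,
                                         alternative="two-sided").pvalue)
            rows.append((labels[c], counts[c], float(yc.mean()), float(pct),
                         p, _stars(p)))
        else:
            rows.append((labels[c], counts[c], float(yc.mean()), float(pct),
                         np.nan, "untested"))
    return pd.DataFrame(rows, columns=["class", "n", "mean", "pct_vs_ref",
                                       "p", "significance"])


def join_expression(candidates: pd.DataFrame, expression: pd.DataFrame,
                    gene_col: str = "gene_id") -> pd.DataFrame:
    """Left-join per-tissue expression onto a candidate table by gene id.

    Duplicate expression rows keep the first occurrence (logged); genes
    absent from the expression table are flagged ``no data``.
    """
    expr = expression.copy()
    key = expr.columns[0] if gene_col not in expr.columns else gene_col
    if expr[key].duplicated().any():
        logger.info("join_expression: %d duplicate gene ids, keeping first",
                    int(expr[key].duplicated().sum()))
        expr = expr.drop_duplicates(subset=key, keep="first")
    out = candidates.merge(expr, how="left", left_on=gene_col, right_on=key,
                           suffixes=("", "_expr"))
    tissue_cols = [c for c in expr.columns if c != key]
    out["expression_status"] = np.where(
        out[tissue_cols].notna().any(axis=1), "measured", "no data")
    return out


def genomic_inflation(p_values) -> float:
    """Median chi-square inflation factor lambda_GC of a p-value vector."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def export_manhattan_qq(scan: AssociationScan, threshold: float | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Plot-ready Manhattan and QQ tables plus the genomic inflation factor.

    The Manhattan table carries a strictly increasing cumulative genome
    coordinate and a chromosome alternation index; the QQ table pairs
    sorted observed -log10 p with their uniform expectations.
    """
    t = scan.table[scan.table["tested"]].copy()
    chroms = list(pd.unique(t["chrom"].astype(str)))
    offset, off = {}, 0
    for c in chroms:
        offset[c] = off
        off += int(t.loc[t["chrom"].astype(str) == c, "pos"].max()) + 1
    t["cum_pos"] = [offset[str(c)] + int(p) for c, p in zip(t["chrom"], t["pos"])]
    t["chrom_index"] = [chroms.index(str(c)) % 2 for c in t["chrom"]]
    t["neglog10p"] = -np.log10(np.clip(t["p"], 1e-300, None))
    t["threshold"] = threshold if threshold is not None else np.nan
    man = t[["chrom", "pos", "id", "cum_pos", "chrom_index", "neglog10p",
             "threshold"]].sort_values("cum_pos").reset_index(drop=True)
    p_sorted = np.sort(t["p"].to_numpy())
    m = len(p_sorted)
    qq = pd.DataFrame({
        "expected": -np.log10((np.arange(1, m + 1) - 0.5) / m),
        "observed": -np.log10(np.clip(p_sorted, 1e-300, None)),
    })
    return man, qq, genomic_inflation(p_sorted)
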