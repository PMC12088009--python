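"""Cross-year, multi-method aggregation of association scans into QTLs.

Per-method p-values from the two field seasons are combined with
Fisher's method (chi-square with 4 df).  Significance thresholds come
from Benjamini-Hochberg FDR control computed on an LD-pruned independent
marker set (window 50 SNPs, step 5, r-squared > 0.5) and are then applied
to all markers.  A marker becomes a consensus marker-trait association
(MTA) when at least two scan engines flag it within a single year and
Fisher's combined p-value supports it across years.  Consensus markers
are clustered into QTL blocks: markers with pairwise dosage r-squared
above 0.75 form connected components, and each component's span is padded
by 25 kb on each side.  A flowering-time residual analysis reruns the
same machinery on phenology-corrected phenotypes so shared and
phenology-specific signals can be separated.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AssociationScan
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- Fisher

def fisher_combine(p_year1, p_year2):
    """Fisher combination of two p-values: X2 = -2(ln p1 + ln p2) ~ chi2(4).

    Accepts scalars or arrays; zeros are clamped to the smallest positive
    float with a warning.
    """
    p1 = np.asarray(p_year1, dtype=float)
    p2 = np.asarray(p_year2, dtype=float)
    if (p1 == 0).any() or (p2 == 0).any():
        logger.warning("fisher_combine: zero p-values clamped")
    tiny = np.finfo(float).tiny
    x2 = -2.0 * (np.log(np.clip(p1, tiny, 1.0)) + np.log(np.clip(p2, tiny, 1.0)))
    out = stats.chi2.sf(x2, df=4)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------- pruning

def prune_independent(g: GenotypeMatrix, window: int = 50, step: int = 5,
                      r2: float = 0.5) -> np.ndarray:
    """Sliding-window LD pruning; returns retained marker column indices.

    Within each 50-marker window (advanced by ``step``, per chromosome)
    any marker whose squared dosage correlation with an earlier surviving
    marker exceeds ``r2`` is removed; removals persist across windows.
    """
    removed = np.zeros(g.n_markers, dtype=bool)
    D = g.dosages.astype(float)
    chrom = np.asarray(g.markers["chrom"])
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        for start in range(0, len(idx), step):
            win = idx[start:start + window]
            alive = win[~removed[win]]
            if len(alive) < 2:
                if start + window >= len(idx):
                    break
                continue
            sub = D[:, alive]
            sd = sub.std(axis=0)
            ok = sd > 0
            corr = np.zeros((len(alive), len(alive)))
            if ok.sum() >= 2:
                cc = np.corrcoef(sub[:, ok], rowvar=False)
                corr[np.ix_(ok, ok)] = cc
            r2m = corr ** 2
            dead_local = np.zeros(len(alive), dtype=bool)
            for j in range(1, len(alive)):
                if (r2m[:j, j][~dead_local[:j]] > r2).any():
                    dead_local[j] = True
            removed[alive[dead_local]] = True
            if start + window >= len(idx):
                break
    return np.flatnonzero(~removed)


def fdr_threshold(p_values, q: float = 0.05) -> float:
    """Benjamini-Hochberg genome-wide p threshold from an independent set.

    The threshold is the largest order statistic p_(k) with
    p_(k) <= k*q/M; with zero discoveries it falls back to q/M.  Apply the
    returned threshold to the full marker set.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("empty p-value set")
    m = p.size
    crit = (np.arange(1, m + 1) * q) / m
    passing = np.flatnonzero(p <= crit)
    if passing.size == 0:
        return q / m
    return float(p[passing[-1]])


# ---------------------------------------------------------------- consensus

@dataclass
class ConsensusMTA:
    """A marker retained by the two-method + Fisher consensus rule."""

    marker_id: str
    chrom: str
    pos: int
    trait: str
    methods_by_year: dict            # year -> set of significant methods
    fisher_p: dict                   # method -> combined p
    supported_methods: set
    tag: str                         # "2021" | "2022" | "all"
    min_p: float
    best_method: str


def consensus(scans: dict, thresholds: dict, combined_thresholds: dict,
              trait: str = "", require_same_method: bool = True
              ) -> list[ConsensusMTA]:
    """Apply the multi-method, cross-year retention rule.

    Parameters
    ----------
    scans : dict mapping (method, year) -> AssociationScan; the grid of
        methods x years must be complete.
    thresholds : dict mapping (method, year) -> per-year p threshold.
    combined_thresholds : dict mapping method -> threshold for the
        Fisher-combined p-values.
    require_same_method : if True (default) the Fisher support must come
        from one of the methods that flagged the marker; otherwise any
        method's combined p suffices.
    """
    methods = sorted({m for m, _ in scans})
    years = sorted({y for _, y in scans})
    for m in methods:
        for y in years:
            if (m, y) not in scans:
                raise ValueError(f"missing scan for method {m!r}, year {y!r}")
    if len(years) != 2:
        raise ValueError("consensus expects exactly two years")
    ref = scans[(methods[0], years[0])].table
    n_markers = len(ref)
    pmat = {key: sc.table["p"].to_numpy() for key, sc in scans.items()}
    fisher = {m: fisher_combine(pmat[(m, years[0])], pmat[(m, years[1])])
              for m in methods}

    out: list[ConsensusMTA] = []
    for j in range(n_markers):
        # BH rejects p <= p_(k), so the threshold comparison is inclusive
        by_year = {y: {m for m in methods
                       if pmat[(m, y)][j] <= thresholds[(m, y)]}
                   for y in years}
        sig_years = [y for y in years if len(by_year[y]) >= 2]
        if not sig_years:
            continue
        flaggers = set().union(*(by_year[y] for y in sig_years))
        support = {m for m in methods
                   if np.isfinite(fisher[m][j])
                   and fisher[m][j] <= combined_thresholds[m]}
        if require_same_method:
            support &= flaggers
        if not support:
            continue
        tag = "all" if len(sig_years) == 2 else sig_years[0]
        cand = [(pmat[(m, y)][j], m) for y in sig_years for m in by_year[y]]
        min_p, best = min(cand)
        out.append(ConsensusMTA(
            marker_id=str(ref["id"].iloc[j]), chrom=str(ref["chrom"].iloc[j]),
            pos=int(ref["pos"].iloc[j]), trait=trait,
            methods_by_year={y: by_year[y] for y in years},
            fisher_p={m: float(fisher[m][j]) for m in methods},
            supported_methods=support, tag=tag, min_p=float(min_p),
            best_method=best))
    return out


# ---------------------------------------------------------------- QTL blocks

@dataclass
class QTLBlock:
    """LD-linked cluster of consensus markers padded to a genomic interval."""

    name: str
    trait: str
    chrom: str
    start: int
    end: int
    members: list = field(default_factory=list)  # marker ids
    top_marker: str = ""
    min_p: float = np.nan
    tag: str = "content"                         # content | residual | both


def _chrom_label(chrom: str) -> str:
    m = re.search(r"(\d+|Un)$", str(chrom))
    return m.group(1) if m else str(chrom)


def build_qtl_blocks(mtas: list[ConsensusMTA], g: GenotypeMatrix,
                     link_r2: float = 0.75, pad_bp: int = 25_000,
                     analysis: str = "content") -> list[QTLBlock]:
    """Cluster consensus markers into padded QTL intervals.

    Per trait and chromosome, markers with pairwise dosage r-squared
    above ``link_r2`` are joined; each connected component spans
    [min pos - pad, max pos + pad] (floored at 1) and is named
    ``<Ion>_<Cont|Res><chrom>-<ordinal>`` with ordinals by ascending
    start position within the chromosome.
    """
    id_to_col = {str(i): j for j, i in enumerate(g.markers["id"])}
    D = g.dosages.astype(float)
    prefix = "Cont" if analysis == "content" else "Res"
    blocks: list[QTLBlock] = []
    key = lambda m: (m.trait, str(m.chrom))
    groups: dict = {}
    for m in mtas:
        if m.marker_id not in id_to_col:
            raise ValueError(f"marker {m.marker_id} absent from genotype matrix")
        groups.setdefault(key(m), []).append(m)
    for (trait, chrom), ms in groups.items():
        cols = [id_to_col[m.marker_id] for m in ms]
        k = len(ms)
        parent = list(range(k))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        sub = D[:, cols]
        sd = sub.std(axis=0)
        for a in range(k):
            for b in range(a + 1, k):
                if sd[a] == 0 or sd[b] == 0:
                    continue
                r = np.corrcoef(sub[:, a], sub[:, b])[0, 1]
                if r * r > link_r2:
                    parent[find(a)] = find(b)
        comp: dict = {}
        for i in range(k):
            comp.setdefault(find(i), []).append(ms[i])
        chrom_blocks = []
        for members in comp.values():
            start = max(1, min(m.pos for m in members) - pad_bp)
            end = max(m.pos for m in members) + pad_bp
            top = min(members, key=lambda m: m.min_p)
            chrom_blocks.append(QTLBlock(
                name="", trait=trait, chrom=chrom, start=start, end=end,
                members=[m.marker_id for m in members],
                top_marker=top.marker_id, min_p=top.min_p, tag=analysis))
        chrom_blocks.sort(key=lambda b: b.start)
        for i, b in enumerate(chrom_blocks, start=1):
            b.name = f"{trait}_{prefix}{_chrom_label(chrom)}-{i}"
        blocks += chrom_blocks
    return blocks


def tag_block_overlaps(content: list[QTLBlock], residual: list[QTLBlock]
                       ) -> None:
    """Mark blocks found by both the content and residual analyses as 'both'."""
    for cb in content:
        for rb in residual:
            if (cb.trait == rb.trait and str(cb.chrom) == str(rb.chrom)
                    and cb.start <= rb.end and rb.start <= cb.end):
                cb.tag = rb.tag = "both"


# ---------------------------------------------------------------- residuals

def residualize_on_flowering(blues: pd.Series, flowering: pd.Series) -> pd.Series:
    """Residuals of BLUE ~ flowering time, aligned to the BLUE index.

    Requires flowering time for at least 90% of genotypes; genotypes
    without it are dropped.  Constant flowering returns centered values
    with a warning (nothing to correct)."""
    common = blues.index.intersection(flowering.dropna().index)
    if len(common) < 0.9 * len(blues):
        raise ValueError("flowering time available for < 90% of genotypes")
    y = blues.loc[common].to_numpy(dtype=float)
    x = flowering.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        logger.warning("residualize_on_flowering: zero-variance flowering time")
        return pd.Series(y - y.mean(), index=common, name=blues.name)
    xc = x - x.mean()
    beta = float(xc @ (y - y.mean()) / (xc @ xc))
    resid = y - y.mean() - beta * xc
    return pd.Series(resid, index=common, name=blues.name)


def overlap_report(content: list[ConsensusMTA], residual: list[ConsensusMTA]
                   ) -> pd.DataFrame:
    """Shared vs analysis-specific markers between the content and residual
    analyses (long table: trait, marker, chrom, pos, type)."""
    key = lambda m: (m.trait, m.marker_id)
    c_ids = {key(m): m for m in content}
    r_ids = {key(m): m for m in residual}
    rows = []
    for k, m in c_ids.items():
        rows.append((m.trait, m.marker_id, m.chrom, m.pos,
                     "both" if k in r_ids else "content"))
    for k, m in r_ids.items():
        if k not in c_ids:
            rows.append((m.trait, m.marker_id, m.chrom, m.pos, "residual"))
    return pd.DataFrame(rows, columns=["trait", "marker", "chrom", "pos", "type"])


# ---------------------------------------------------------------- tables

def mta_table(mtas: list[ConsensusMTA]) -> pd.DataFrame:
    """Consensus MTA export: Ion, SNP, Chrom, POS, pvalue_max,
    significant_method, methods, Year."""
    rows = []
    for m in mtas:
        all_methods = sorted(set().union(*m.methods_by_year.values()))
        rows.append((m.trait, m.marker_id, m.chrom, m.pos, m.min_p,
                     m.best_method, ",".join(all_methods), m.tag))
    return pd.DataFrame(rows, columns=["Ion", "SNP", "Chrom", "POS",
                                       "pvalue_max", "significant_method",
                                       "methods", "Year"])


def qtl_table(blocks: list[QTLBlock]) -> pd.DataFrame:
    """QTL export: QTL_name, chrom, nbr_sig_snp, QTL_Pos, Type, Ion."""
    rows = [(b.name, b.chrom, len(b.members), f"{b.start}-{b.end}", b.tag,
             b.trait) for b in blocks]
    return pd.DataFrame(rows, columns=["QTL_name", "chrom", "nbr_sig_snp",
                                       "QTL_Pos", "Type", "Ion"])
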