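"""End-to-end drivers: genotype QC cascade and the multi-scan GWAS study.

`qc_pipeline` applies the marker/sample filters, fits the ancestry
factorization, imputes missing calls and applies the heterozygosity cap
(computed on pre-imputation calls), in that order.  `run_gwas_study`
takes a clean panel plus per-genotype BLUEs for two years, runs the four
scan engines per year, derives pruning-based FDR thresholds, combines
years with Fisher's method, applies the two-method consensus rule and
delineates QTL blocks; optionally the whole analysis is repeated on
flowering-time residuals and the two passes cross-tagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aggregate, assoc, phenotypes
from .ancestry import AncestryModel, estimate_ancestry, impute_missing
from .genotypes import (GenotypeMatrix, filter_heterozygosity, filter_markers,
                        filter_samples)

logger = logging.getLogger(__name__)

METHODS = ("EMMA", "LFMM", "CMLM", "BLINK")


def qc_pipeline(g: GenotypeMatrix, max_missing: float = 0.50,
                min_maf: float = 0.05, min_call_rate: float = 0.80,
                max_het: float = 0.12, K_range=range(1, 11),
                replicates: int = 10, seed: int = 0,
                ancestry_kwargs: dict | None = None
                ) -> tuple[GenotypeMatrix, AncestryModel]:
    """Marker filter -> sample filter -> ancestry -> imputation -> het cap."""
    g1 = filter_markers(g, max_missing, min_maf)
    g2 = filter_samples(g1, min_call_rate)
    het = g2.het_freq()
    model = estimate_ancestry(g2, K_range=K_range, replicates=replicates,
                              seed=seed, **(ancestry_kwargs or {}))
    g3 = impute_missing(g2, model)
    keep = np.flatnonzero(~(het > max_het))
    g4 = g3.take_markers(keep)
    model.F = model.F[:, keep]
    logger.info("qc_pipeline: %d samples x %d markers retained",
                g4.n_samples, g4.n_markers)
    return g4, model


def compute_blues(trial: pd.DataFrame, traits: list[str],
                  years: list[str] | None = None, min_reps: int = 2,
                  gate_n_traits: int | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-year BLUEs, heritabilities and the normality gate for each trait."""
    return phenotypes.analyze_all(trial, traits, years, min_reps, gate_n_traits)


@dataclass
class TraitResult:
    scans: dict = field(default_factory=dict)        # (method, year) -> scan
    thresholds: dict = field(default_factory=dict)   # (method, year) -> p thr
    combined_thresholds: dict = field(default_factory=dict)  # method -> thr
    mtas: list = field(default_factory=list)
    blocks: list = field(default_factory=list)


@dataclass
class StudyResult:
    genotypes: GenotypeMatrix
    kinship: np.ndarray
    independent_idx: np.ndarray
    content: dict = field(default_factory=dict)   # trait -> TraitResult
    residual: dict = field(default_factory=dict)  # trait -> TraitResult
    overlap: pd.DataFrame | None = None

    def all_blocks(self) -> list:
        out = []
        for res in self.content.values():
            out += res.blocks
        for res in self.residual.values():
            out += res.blocks
        return out


def _run_scans(y: pd.Series, g: GenotypeMatrix, K: np.ndarray,
               Q_cov: np.ndarray | None, n_factors: int, n_groups: int | None,
               trait: str, year: str, methods=METHODS) -> dict:
    scans = {}
    for m in methods:
        if m == "EMMA":
            scans[m] = assoc.scan_mlm(y, g, K, trait=trait, year=year)
        elif m == "LFMM":
            scans[m] = assoc.scan_lfmm(y, g, n_factors, trait=trait, year=year)
        elif m == "CMLM":
            scans[m] = assoc.scan_cmlm(y, g, K, n_groups, trait=trait, year=year)
        elif m == "BLINK":
            scans[m] = assoc.scan_blink(y, g, covariates=Q_cov, trait=trait,
                                        year=year)
        else:
            raise ValueError(f"unknown method {m!r}")
    return scans


def _trait_analysis(blues_by_year: dict, g: GenotypeMatrix, K: np.ndarray,
                    ind_idx: np.ndarray, Q_cov, n_factors, n_groups,
                    trait: str, fdr_q: float, methods) -> TraitResult:
    res = TraitResult()
    years = sorted(blues_by_year)
    for year in years:
        y = blues_by_year[year].reindex(g.sample_ids)
        scans = _run_scans(y, g, K, Q_cov, n_factors, n_groups, trait, year,
                           methods)
        for m, sc in scans.items():
            res.scans[(m, year)] = sc
            p_ind = sc.table["p"].to_numpy()[ind_idx]
            p_ind = p_ind[np.isfinite(p_ind)]
            res.thresholds[(m, year)] = aggregate.fdr_threshold(p_ind, fdr_q)
    for m in methods:
        comb = aggregate.fisher_combine(
            res.scans[(m, years[0])].table["p"].to_numpy(),
            res.scans[(m, years[1])].table["p"].to_numpy())
        c_ind = comb[ind_idx]
        res.combined_thresholds[m] = aggregate.fdr_threshold(
            c_ind[np.isfinite(c_ind)], fdr_q)
    res.mtas = aggregate.consensus(res.scans, res.thresholds,
                                   res.combined_thresholds, trait=trait)
    return res


def run_gwas_study(g: GenotypeMatrix, blue_table: pd.DataFrame,
                   traits: list[str] | None = None,
                   flowering: pd.Series | None = None,
                   ancestry_Q: np.ndarray | None = None,
                   n_factors: int = 3, n_groups: int | None = None,
                   fdr_q: float = 0.05, prune_window: int = 50,
                   prune_step: int = 5, prune_r2: float = 0.5,
                   link_r2: float = 0.75, pad_bp: int = 25_000,
                   methods=METHODS) -> StudyResult:
    """Four-method, two-year association study with consensus QTL blocks.

    ``blue_table`` is long format (trait, year, genotype, blue).  If
    ``flowering`` (a per-genotype Series) is given, the residual analysis
    is run as well and content/residual blocks cross-tagged.
    """
    traits = traits or sorted(blue_table["trait"].unique())
    K = assoc.kinship(g)
    ind_idx = aggregate.prune_independent(g, prune_window, prune_step, prune_r2)
    Q_cov = None
    if ancestry_Q is not None and ancestry_Q.shape[1] > 1:
        Q_cov = ancestry_Q[:, :-1]  # drop one column (rows sum to 1)
    result = StudyResult(genotypes=g, kinship=K, independent_idx=ind_idx)

    for trait in traits:
        sub = blue_table[blue_table["trait"] == trait]
        blues_by_year = {y: s.set_index("genotype")["blue"]
                         for y, s in sub.groupby("year")}
        res = _trait_analysis(blues_by_year, g, K, ind_idx, Q_cov, n_factors,
                              n_groups, trait, fdr_q, methods)
        res.blocks = aggregate.build_qtl_blocks(res.mtas, g, link_r2, pad_bp,
                                                analysis="content")
        result.content[trait] = res
        if flowering is not None:
            resid_by_year = {
                y: aggregate.residualize_on_flowering(b, flowering)
                for y, b in blues_by_year.items()}
            rres = _trait_analysis(resid_by_year, g, K, ind_idx, Q_cov,
                                   n_factors, n_groups, trait, fdr_q, methods)
            rres.blocks = aggregate.build_qtl_blocks(rres.mtas, g, link_r2,
                                                     pad_bp, analysis="residual")
            aggregate.tag_block_overlaps(res.blocks, rres.blocks)
            result.residual[trait] = rres

    if flowering is not None:
        all_c = [m for r in result.content.values() for m in r.mtas]
        all_r = [m for r in result.residual.values() for m in r.mtas]
        result.overlap = aggregate.overlap_report(all_c, all_r)
    return result


def scans_table(result: StudyResult) -> pd.DataFrame:
    """Long export of every scan: chrom, pos, id, trait, year, method,
    beta, se, p, neglog10p."""
    frames = []
    for group in (result.content, result.residual):
        for trait, res in group.items():
            for (m, year), sc in res.scans.items():
                t = sc.table.copy()
                t["trait"], t["year"], t["method"] = trait, year, m
                t["neglog10p"] = -np.log10(np.clip(t["p"], 1e-300, None))
                frames.append(t)
    return pd.concat(frames, ignore_index=True)
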