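import numpy as np
import pandas as pd
import pytest

import ionogwas as ig
from ionogwas.aggregate import (ConsensusMTA, build_qtl_blocks, consensus,
                                fdr_threshold, fisher_combine, mta_table,
                                overlap_report, prune_independent, qtl_table,
                                residualize_on_flowering, tag_block_overlaps)
from ionogwas.assoc import AssociationScan

from conftest import make_matrix


# ---------------------------------------------------------------- Fisher

def test_fisher_closed_form_oracle():
    """chi2(4) survival has the closed form (1 + x/2) exp(-x/2), so the
    combined p is (1 - ln(p1 p2)) * p1 * p2."""
    for p1, p2 in [(0.05, 0.05), (0.01, 0.3), (0.5, 0.5), (1e-6, 0.9)]:
        expected = (1.0 - np.log(p1 * p2)) * p1 * p2
        assert fisher_combine(p1, p2) == pytest.approx(expected, rel=1e-10)
    assert fisher_combine(0.05, 0.05) == pytest.approx(0.0174787, abs=5e-7)


def test_fisher_symmetry_monotone_and_zero_clamp():
    assert fisher_combine(0.01, 0.2) == fisher_combine(0.2, 0.01)
    ps = [fisher_combine(p, 0.1) for p in [0.5, 0.1, 0.01, 1e-5]]
    assert ps == sorted(ps, reverse=True)
    out = fisher_combine(0.0, 0.5)
    assert 0.0 <= out < 1e-200
    arr = fisher_combine(np.array([0.05, 0.5]), np.array([0.05, 0.5]))
    assert arr.shape == (2,)


# ---------------------------------------------------------------- pruning

def _ld_toy(seed, n=60, m=200, block=4):
    """Markers in LD blocks of `block` highly correlated columns."""
    rng = np.random.default_rng(seed)
    cols = []
    for _ in range(m // block):
        base = rng.integers(0, 3, size=n)
        for _ in range(block):
            c = base.copy()
            flip = rng.random(n) < 0.05
            c[flip] = rng.integers(0, 3, size=flip.sum())
            cols.append(c)
    return make_matrix(np.column_stack(cols))


def test_prune_independent_set_has_low_ld():
    g = _ld_toy(0)
    kept = prune_independent(g)
    D = g.dosages.astype(float)
    # any retained pair close enough to have shared a window must be below r2
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            i, j = kept[a], kept[b]
            if j - i > 45:
                continue
            r = np.corrcoef(D[:, i], D[:, j])[0, 1]
            assert r * r <= 0.5 + 1e-12
    # LD blocks of 4 near-copies collapse roughly 4x
    assert len(kept) < 0.5 * g.n_markers


def test_prune_keeps_independent_markers():
    rng = np.random.default_rng(1)
    g = make_matrix(rng.integers(0, 3, size=(80, 100)))
    kept = prune_independent(g)
    assert len(kept) == 100


def test_prune_removes_exact_duplicates():
    rng = np.random.default_rng(2)
    col = rng.integers(0, 3, size=50)
    g = make_matrix(np.column_stack([col, col, col]))
    kept = prune_independent(g)
    assert list(kept) == [0]


def test_prune_respects_chromosome_boundaries():
    rng = np.random.default_rng(3)
    col = rng.integers(0, 3, size=50)
    g = make_matrix(np.column_stack([col, col]), chrom=["chr1", "chr2"])
    kept = prune_independent(g)
    assert list(kept) == [0, 1]


# ---------------------------------------------------------------- FDR

def test_fdr_threshold_matches_statsmodels_bruteforce():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(4)
    for _ in range(100):
        m = rng.integers(20, 300)
        p = rng.random(m) ** rng.uniform(1, 4)  # enrich small p sometimes
        thr = fdr_threshold(p, q=0.05)
        reject_ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(p <= thr, reject_ref)


def test_fdr_fallback_and_empty():
    p = np.array([0.4, 0.6, 0.9])
    assert fdr_threshold(p, q=0.05) == pytest.approx(0.05 / 3)
    with pytest.raises(ValueError):
        fdr_threshold(np.array([np.nan]))


# ---------------------------------------------------------------- consensus

def _grid(pvals):
    """Build a (method, year) -> AssociationScan grid from a dict of
    method-year p-value arrays over 4 markers on chr1/chr2."""
    n = len(next(iter(pvals.values())))
    chrom = (["chr1", "chr1", "chr2", "chr2"] * 4)[:n]
    pos = ([100_000, 110_000, 5_000, 900_000] * 4)[:n]
    ids = [f"m{k}" for k in range(n)]
    scans = {}
    for (m, y), p in pvals.items():
        t = pd.DataFrame({"chrom": chrom, "pos": pos, "id": ids,
                          "beta": 0.0, "se": 1.0, "p": p, "tested": True})
        scans[(m, y)] = AssociationScan(t, trait="Zn", year=y, method=m)
    return scans


def test_consensus_rule_enumeration():
    big = 0.9
    # marker0: two methods in 2021 only; marker1: both years; marker2: one
    # method only (excluded); marker3: flagged but no Fisher support
    p = {("A", "2021"): np.array([1e-6, 1e-6, 1e-6, 1e-4]),
         ("A", "2022"): np.array([big, 1e-6, big, big]),
         ("B", "2021"): np.array([1e-6, 1e-6, big, 1e-4]),
         ("B", "2022"): np.array([big, 1e-6, big, big])}
    thr = {k: 1e-3 for k in p}
    comb = {"A": 1e-4, "B": 1e-4}
    mtas = consensus(_grid(p), thr, comb, trait="Zn")
    got = {m.marker_id: m.tag for m in mtas}
    assert got == {"m0": "2021", "m1": "all"}
    m0 = next(m for m in mtas if m.marker_id == "m0")
    assert m0.methods_by_year["2021"] == {"A", "B"}
    assert m0.min_p == pytest.approx(1e-6)
    # marker3 would be kept if the huge-combined-threshold grid allowed it
    mtas_loose = consensus(_grid(p), thr, {"A": 1.0, "B": 1.0}, trait="Zn")
    assert {m.marker_id for m in mtas_loose} == {"m0", "m1", "m3"}


def test_consensus_same_method_requirement():
    big = 0.9
    # flagged by A and B in 2021, but only method C has Fisher support
    p = {("A", "2021"): np.array([1e-6]), ("A", "2022"): np.array([big]),
         ("B", "2021"): np.array([1e-6]), ("B", "2022"): np.array([big]),
         ("C", "2021"): np.array([big]), ("C", "2022"): np.array([big])}
    thr = {k: 1e-3 for k in p}
    comb = {"A": 1e-12, "B": 1e-12, "C": 1.0}
    assert consensus(_grid(p), thr, comb) == []
    loose = consensus(_grid(p), thr, comb, require_same_method=False)
    assert len(loose) == 1
    assert loose[0].supported_methods == {"C"}


def test_consensus_threshold_boundary_inclusive():
    """A marker whose p-value equals the BH threshold (the case of a single
    genome-wide hit, where the threshold is that very order statistic) must
    be retained."""
    big = 0.9
    p = {("A", "2021"): np.array([1e-8, big]), ("A", "2022"): np.array([1e-8, big]),
         ("B", "2021"): np.array([1e-8, big]), ("B", "2022"): np.array([1e-8, big])}
    thr = {k: 1e-8 for k in p}
    comb = {m: fisher_combine(1e-8, 1e-8) for m in "AB"}
    mtas = consensus(_grid(p), thr, comb, trait="Zn")
    assert [m.marker_id for m in mtas] == ["m0"]


def test_consensus_grid_validation():
    p = {("A", "2021"): np.array([0.5]), ("A", "2022"): np.array([0.5]),
         ("B", "2021"): np.array([0.5])}
    with pytest.raises(ValueError):
        consensus(_grid(p), {k: 0.05 for k in p}, {"A": 0.05, "B": 0.05})
    p3 = {("A", y): np.array([0.5]) for y in ["2020", "2021", "2022"]}
    with pytest.raises(ValueError):
        consensus(_grid(p3), {k: 0.05 for k in p3}, {"A": 0.05})


# ---------------------------------------------------------------- QTL blocks

def _mta(mid, chrom, pos, trait="Fe", min_p=1e-7):
    return ConsensusMTA(marker_id=mid, chrom=chrom, pos=pos, trait=trait,
                        methods_by_year={"2021": {"A", "B"}, "2022": set()},
                        fisher_p={"A": 1e-8}, supported_methods={"A"},
                        tag="2021", min_p=min_p, best_method="A")


def test_single_mta_block_padding():
    rng = np.random.default_rng(5)
    g = make_matrix(rng.integers(0, 3, size=(40, 1)), pos=[100_000])
    blocks = build_qtl_blocks([_mta("s0", "chr1", 100_000)], g)
    assert len(blocks) == 1
    b = blocks[0]
    assert (b.start, b.end) == (75_000, 125_000)
    assert b.name == "Fe_Cont1-1"
    assert b.top_marker == "s0"


def test_block_padding_floored_at_one():
    rng = np.random.default_rng(6)
    g = make_matrix(rng.integers(0, 3, size=(40, 1)), pos=[10_000])
    b = build_qtl_blocks([_mta("s0", "chr1", 10_000)], g)[0]
    assert b.start == 1
    assert b.end == 35_000


def test_linked_markers_merge_unlinked_split():
    rng = np.random.default_rng(7)
    a = rng.integers(0, 3, size=60)
    b = a.copy()
    b[:3] = (b[:3] + 1) % 3          # r2 > 0.75 with a
    c = rng.integers(0, 3, size=60)  # independent
    g = make_matrix(np.column_stack([a, b, c]),
                    pos=[100_000, 140_000, 600_000])
    mtas = [_mta("s0", "chr1", 100_000), _mta("s1", "chr1", 140_000),
            _mta("s2", "chr1", 600_000)]
    blocks = build_qtl_blocks(mtas, g)
    assert len(blocks) == 2
    merged = next(bl for bl in blocks if len(bl.members) == 2)
    assert (merged.start, merged.end) == (75_000, 165_000)
    names = sorted(bl.name for bl in blocks)
    assert names == ["Fe_Cont1-1", "Fe_Cont1-2"]
    res = build_qtl_blocks(mtas, g, analysis="residual")
    assert res[0].name.startswith("Fe_Res1-")


def test_block_unknown_marker_raises(clean_panel):
    g, _ = clean_panel
    with pytest.raises(ValueError):
        build_qtl_blocks([_mta("nope", "chr1", 5)], g)


def test_tag_block_overlaps():
    c = [ig.QTLBlock("Fe_Cont1-1", "Fe", "chr1", 100, 200),
         ig.QTLBlock("Fe_Cont1-2", "Fe", "chr1", 900, 1000)]
    r = [ig.QTLBlock("Fe_Res1-1", "Fe", "chr1", 150, 400)]
    tag_block_overlaps(c, r)
    assert c[0].tag == "both" and r[0].tag == "both"
    assert c[1].tag == "content"


# ---------------------------------------------------------------- residuals

def test_residualize_orthogonality():
    rng = np.random.default_rng(8)
    idx = [f"G{i:03d}" for i in range(100)]
    ft = pd.Series(rng.normal(70, 5, size=100), index=idx)
    blues = pd.Series(0.4 * ft.to_numpy() + rng.normal(size=100), index=idx)
    resid = residualize_on_flowering(blues, ft)
    assert abs(resid.mean()) < 1e-10
    assert abs(np.corrcoef(resid, ft.loc[resid.index])[0, 1]) < 1e-10


def test_residualize_coverage_and_constant():
    idx = [f"G{i:03d}" for i in range(50)]
    blues = pd.Series(np.arange(50.0), index=idx)
    short = pd.Series(np.arange(30.0), index=idx[:30])
    with pytest.raises(ValueError):
        residualize_on_flowering(blues, short)
    const = pd.Series(70.0, index=idx)
    out = residualize_on_flowering(blues, const)
    np.testing.assert_allclose(out, np.arange(50.0) - 24.5)


# ---------------------------------------------------------------- tables

def test_overlap_report_types():
    c = [_mta("s0", "chr1", 10), _mta("s1", "chr1", 20)]
    r = [_mta("s1", "chr1", 20), _mta("s2", "chr1", 30)]
    rep = overlap_report(c, r)
    types = dict(zip(rep["marker"], rep["type"]))
    assert types == {"s0": "content", "s1": "both", "s2": "residual"}


def test_export_tables_shapes():
    mt = mta_table([_mta("s0", "chr1", 10)])
    assert list(mt.columns) == ["Ion", "SNP", "Chrom", "POS", "pvalue_max",
                                "significant_method", "methods", "Year"]
    qt = qtl_table([ig.QTLBlock("Fe_Cont1-1", "Fe", "chr1", 1, 2,
                                members=["s0"])])
    assert qt.loc[0, "nbr_sig_snp"] == 1
    assert qt.loc[0, "QTL_Pos"] == "1-2"
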