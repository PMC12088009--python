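import itertools

import numpy as np
import pytest
from scipy import stats

import ionogwas as ig
from ionogwas.assoc import (_bic, _ols_scan, compress_kinship,
                            forward_bic_select, pca_factors)

from conftest import make_matrix, structured_null_phenotype


@pytest.fixture(scope="module")
def panel_K(clean_panel):
    g, _ = clean_panel
    return g, ig.kinship(g)


def test_kinship_hand_oracle():
    d = np.array([[0, 2, 2], [2, 0, 0], [0, 2, 0], [2, 0, 2]], dtype=np.int8)
    g = make_matrix(d)
    p = d.mean(axis=0) / 2.0
    W = d - 2.0 * p
    expected = W @ W.T / (2.0 * np.sum(p * (1 - p)))
    np.testing.assert_allclose(ig.kinship(g), expected, atol=1e-12)


def test_kinship_rejects_missing_and_all_monomorphic():
    with pytest.raises(ValueError):
        ig.kinship(make_matrix(np.array([[0, -1], [2, 0]])))
    with pytest.raises(ValueError):
        ig.kinship(make_matrix(np.array([[0, 2], [0, 2]])))
    # monomorphic columns are dropped, not fatal
    with_mono = ig.kinship(make_matrix(np.array([[0, 0], [0, 2]])))
    without = ig.kinship(make_matrix(np.array([[0], [2]])))
    np.testing.assert_allclose(with_mono, without)


def test_mlm_identity_kinship_reduces_to_ols(panel_K):
    g, _ = panel_K
    y = structured_null_phenotype(np.eye(g.n_samples), 0)
    mlm = ig.scan_mlm(y, g, np.eye(g.n_samples))
    ols = ig.scan_lfmm(y, g, n_factors=0)
    np.testing.assert_allclose(mlm.p, ols.p, atol=1e-10)


def test_lfmm_zero_factors_matches_linregress(panel_K):
    g, _ = panel_K
    rng = np.random.default_rng(1)
    y = rng.normal(size=g.n_samples)
    scan = ig.scan_lfmm(y, g, n_factors=0)
    for j in [0, 57, 1999]:
        x = g.dosages[:, j].astype(float)
        if x.std() == 0:
            continue
        res = stats.linregress(x, y)
        assert scan.p[j] == pytest.approx(res.pvalue, rel=1e-9)
        assert scan.table["beta"].iloc[j] == pytest.approx(res.slope, rel=1e-9)


def test_mlm_matches_dense_gls_oracle(panel_K):
    """Independent oracle: at the null REML delta, the per-marker Wald test
    from a dense GLS solve must match the rotated-scan p-values."""
    g, K = panel_K
    y = structured_null_phenotype(K, 3)
    scan = ig.scan_mlm(y, g, K)
    delta = scan.extras["delta"]
    n = g.n_samples
    Vi = np.linalg.inv(K + delta * np.eye(n))
    for j in [5, 123, 877, 1500]:
        X = np.column_stack([np.ones(n), g.dosages[:, j].astype(float)])
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        resid = y - X @ beta
        s2 = float(resid @ Vi @ resid) / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(XtViX)[1, 1])
        t = beta[1] / se
        p_ref = 2.0 * stats.t.sf(abs(t), n - 2)
        assert abs(np.log10(scan.p[j]) - np.log10(p_ref)) < 1e-2


def test_mlm_exact_mode_close_to_p3d(panel_K):
    g, K = panel_K
    sub = g.take_markers(np.arange(100))
    y = structured_null_phenotype(K, 4)
    p3d = ig.scan_mlm(y, sub, K, mode="p3d")
    exact = ig.scan_mlm(y, sub, K, mode="exact")
    d = np.abs(np.log10(p3d.p) - np.log10(exact.p))
    assert np.nanmedian(d) < 0.1
    with pytest.raises(ValueError):
        ig.scan_mlm(y, sub, K, mode="bogus")


def test_mlm_sample_permutation_invariance(panel_K):
    g, K = panel_K
    y = structured_null_phenotype(K, 5)
    rng = np.random.default_rng(0)
    perm = rng.permutation(g.n_samples)
    gp = g.take_samples(perm)
    scan = ig.scan_mlm(y, g, K)
    scan_p = ig.scan_mlm(y[perm], gp, K[np.ix_(perm, perm)])
    # eigendecomposition order/sign differ across permutations, so agreement
    # is to numerical rather than bitwise precision
    np.testing.assert_allclose(scan.p, scan_p.p, rtol=1e-6)


def test_monomorphic_marker_untested(panel_K):
    g, K = panel_K
    d = g.dosages.copy()
    d[:, 0] = 2
    gm = ig.GenotypeMatrix(d, g.sample_ids, g.markers)
    y = structured_null_phenotype(K, 6)
    scan = ig.scan_mlm(y, gm, K)
    baseline = ig.scan_mlm(y, g, K)
    assert not scan.table["tested"].iloc[0]
    # only the forced-monomorphic marker changes tested status
    np.testing.assert_array_equal(scan.table["tested"].iloc[1:],
                                  baseline.table["tested"].iloc[1:])


def test_null_calibration_ks(panel_K):
    """Structured polygenic null: MLM p-values should be near-uniform."""
    g, K = panel_K
    pvals = []
    for seed in range(5):
        y = structured_null_phenotype(K, 100 + seed)
        scan = ig.scan_mlm(y, g, K)
        pvals.append(scan.p[scan.table["tested"]])
    p = np.concatenate(pvals)
    assert stats.kstest(p, "uniform").pvalue > 1e-3
    lam = ig.genomic_inflation(p)
    assert 0.9 < lam < 1.1


def test_pca_factors_match_svd(panel_K):
    g, _ = panel_K
    D = g.dosages.astype(float)
    Dc = D - D.mean(axis=0)
    u, s, _ = np.linalg.svd(Dc, full_matrices=False)
    F = pca_factors(g, 3)
    for k in range(3):
        # scores defined up to sign
        assert min(np.abs(F[:, k] - u[:, k] * s[k]).max(),
                   np.abs(F[:, k] + u[:, k] * s[k]).max()) < 1e-8


def test_cmlm_full_groups_recovers_mlm(panel_K):
    g, K = panel_K
    y = structured_null_phenotype(K, 7)
    full = ig.scan_cmlm(y, g, K, n_groups=g.n_samples)
    mlm = ig.scan_mlm(y, g, K)
    np.testing.assert_array_equal(full.p, mlm.p)


def test_cmlm_default_group_count(panel_K):
    g, K = panel_K
    y = structured_null_phenotype(K, 8)
    scan = ig.scan_cmlm(y, g, K)
    assert scan.extras["n_groups"] == int(np.ceil(np.sqrt(g.n_samples)))
    assert scan.method == "CMLM-style"


def test_compress_kinship_properties(panel_K):
    _, K = panel_K
    lab, K_eff = compress_kinship(K, 10)
    assert len(np.unique(lab)) <= 10
    np.testing.assert_allclose(K_eff, K_eff.T, atol=1e-12)
    # members of a group share identical rows of the compressed kinship
    for grp in np.unique(lab)[:3]:
        members = np.flatnonzero(lab == grp)
        if len(members) > 1:
            np.testing.assert_allclose(K_eff[members[0]], K_eff[members[1]],
                                       atol=1e-12)
    with pytest.raises(ValueError):
        compress_kinship(K, 1)


def test_forward_bic_never_worse_than_empty_and_matches_bruteforce():
    rng = np.random.default_rng(2)
    n, c = 120, 6
    cand = rng.normal(size=(n, c))
    y = 0.8 * cand[:, 1] - 0.6 * cand[:, 4] + rng.normal(size=n)
    base = np.ones((n, 1))
    sel = forward_bic_select(y, base, cand)
    bic_sel = _bic(y, np.column_stack([base, cand[:, sel]]))
    # brute force over all subsets of <= 6 candidates
    best = min(_bic(y, np.column_stack([base, cand[:, list(S)]])
                    if S else base)
               for r in range(c + 1)
               for S in itertools.combinations(range(c), r))
    assert bic_sel <= best + np.log(n) + 1e-9  # greedy within one penalty unit
    assert set(sel) >= {1, 4}


def test_blink_null_usually_empty(panel_K):
    g, _ = panel_K
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(300 + seed)
        y = rng.normal(size=g.n_samples)
        scan = ig.scan_blink(y, g)
        hits += len(scan.extras["pseudo_qtns"]) == 0
    assert hits >= 4


def test_blink_recovers_spiked_qtl(panel_K):
    g, K = panel_K
    rng = np.random.default_rng(9)
    j = 700
    x = g.dosages[:, j].astype(float)
    y = structured_null_phenotype(K, 9) + 2.0 * (x - x.mean()) / x.std()
    scan = ig.scan_blink(y, g)
    assert scan.extras["converged"]
    # the causal marker (or a proxy in its LD block) is selected and its
    # own final-scan p-value is genome-wide small
    assert scan.p[j] < 1e-6
    assert int(np.nanargmin(scan.p)) == j


def test_power_monotone_in_effect_size(panel_K):
    g, K = panel_K
    j = 42
    x = g.dosages[:, j].astype(float)
    base = structured_null_phenotype(K, 10)
    last = 1.0
    for eff in [0.5, 1.0, 2.0]:
        scan = ig.scan_mlm(base + eff * (x - x.mean()) / x.std(), g, K)
        assert scan.p[j] < last
        last = scan.p[j]
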