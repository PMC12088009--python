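"""Genome-scan engines for genotype-trait association.

Four complementary engines are provided, each a minimal faithful core of
a widely used GWAS family rather than a wrapper around an external tool:

* ``scan_mlm`` — exact single-kinship mixed model (EMMA-style): REML of
  the variance ratio through the spectral decomposition of the kinship,
  then per-marker Wald tests; ``p3d`` mode reuses the null-model ratio
  for every marker, ``exact`` mode re-estimates it.
* ``scan_lfmm`` — latent-factor regression (LFMM-style): top principal
  components of the dosage matrix enter as fixed covariates.
* ``scan_cmlm`` — compressed mixed model (CMLM-style): individuals are
  clustered on kinship distance and share group-level random effects.
* ``scan_blink`` — iterative pseudo-QTN conditioning (BLINK-inspired):
  LD-filtered candidates are selected by BIC forward search and absorbed
  as fixed covariates, excluding each tested marker's own LD block.

All engines emit per-marker effect, standard error and Wald p-value;
monomorphic markers are flagged untested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class AssociationScan:
    """Marker-wise scan result with (trait, year, method) metadata."""

    table: pd.DataFrame  # chrom, pos, id, beta, se, p, tested
    trait: str = ""
    year: str = ""
    method: str = ""
    covariates: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    def neglog10p(self) -> np.ndarray:
        return -np.log10(np.clip(self.p, 1e-300, None))


def kinship(g: GenotypeMatrix) -> np.ndarray:
    """VanRaden realized relationship: K = (G-2P)(G-2P)' / (2 sum p(1-p))."""
    if (g.dosages == -1).any():
        raise ValueError("kinship requires complete (imputed) dosages")
    D = g.dosages.astype(float)
    p = D.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers")
    W = D[:, poly] - 2.0 * p[poly]
    return W @ W.T / (2.0 * np.sum(p[poly] * (1.0 - p[poly])))


# ----------------------------------------------------------- shared core

def _align_y(y, g: GenotypeMatrix) -> np.ndarray:
    if isinstance(y, pd.Series):
        y = y.reindex(g.sample_ids)
        if y.isna().any():
            raise ValueError("phenotype missing for some samples")
        return y.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) != g.n_samples:
        raise ValueError("phenotype length does not match samples")
    return y


def _ols_scan(y: np.ndarray, G: np.ndarray, X: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-column OLS of y on [X, G[:, j]]; Wald t p-values.

    Returns (beta, se, p, tested).  Columns of G collinear with X (e.g.
    monomorphic) are flagged untested.
    """
    n = len(y)
    Q, _ = np.linalg.qr(X)
    y_t = y - Q @ (Q.T @ y)
    G_t = G - Q @ (Q.T @ G)
    gg = np.einsum("ij,ij->j", G_t, G_t)
    tested = gg > 1e-10 * n
    gg_safe = np.where(tested, gg, 1.0)
    beta = (G_t.T @ y_t) / gg_safe
    dof = n - X.shape[1] - 1
    if dof < 1:
        raise ValueError("not enough residual degrees of freedom")
    rss = np.maximum(y_t @ y_t - beta ** 2 * gg_safe, 0.0)
    se = np.sqrt(rss / dof / gg_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, 0.0)
    p = np.clip(2.0 * stats.t.sf(np.abs(tval), dof), np.finfo(float).tiny, 1.0)
    beta[~tested] = np.nan
    se[~tested] = np.nan
    p = np.where(tested, p, np.nan)
    return beta, se, p, tested


def _reml_delta(yt: np.ndarray, Xt: np.ndarray, s: np.ndarray,
                n_grid: int = 50) -> float:
    """REML estimate of delta = s2_e/s2_g for Var(y) = s2_g (K + delta I),
    in the eigenbasis of K (eigenvalues ``s``)."""
    n, p = Xt.shape

    def nll(log_delta: float) -> float:
        d = s + np.exp(log_delta)
        w = 1.0 / d
        sw = np.sqrt(w)
        Xs, ys = Xt * sw[:, None], yt * sw
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        rss = float(np.sum((ys - Xs @ beta) ** 2))
        sign, logdet_x = np.linalg.slogdet(Xs.T @ Xs)
        return 0.5 * ((n - p) * np.log(max(rss / (n - p), 1e-300))
                      + np.sum(np.log(d)) + logdet_x)

    grid = np.linspace(-10.0, 10.0, n_grid)
    vals = [nll(x) for x in grid]
    x0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(nll, bounds=(x0 - 1.0, x0 + 1.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(np.exp(res.x))


def _scan_frame(g: GenotypeMatrix, beta, se, p, tested) -> pd.DataFrame:
    t = g.markers[["chrom", "pos", "id"]].copy()
    t["beta"], t["se"], t["p"], t["tested"] = beta, se, p, tested
    return t


def scan_mlm(y, g: GenotypeMatrix, K: np.ndarray,
             covariates: np.ndarray | None = None, mode: str = "p3d",
             trait: str = "", year: str = "") -> AssociationScan:
    """Single-kinship mixed-model scan (EMMA-style).

    Model ``y = X b + s g_j + u + e`` with ``u ~ N(0, s2_g K)``.  The
    variance ratio is REML-estimated on the null model through the
    eigendecomposition of K; ``p3d`` reuses it for every marker, ``exact``
    re-estimates it per marker.  Wald t tests on the marker effect.
    """
    y = _align_y(y, g)
    n = len(y)
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    s, U = np.linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    yt, Xt = U.T @ y, U.T @ X
    G = g.dosages.astype(float)
    Gt = U.T @ G
    delta = _reml_delta(yt, Xt, s)
    if mode == "p3d":
        sw = 1.0 / np.sqrt(s + delta)
        beta, se, p, tested = _ols_scan(yt * sw, Gt * sw[:, None], Xt * sw[:, None])
    elif mode == "exact":
        beta = np.empty(g.n_markers)
        se = np.empty(g.n_markers)
        p = np.empty(g.n_markers)
        tested = np.empty(g.n_markers, dtype=bool)
        for j in range(g.n_markers):
            Xa = np.column_stack([Xt, Gt[:, j]])
            dj = _reml_delta(yt, Xa, s)
            sw = 1.0 / np.sqrt(s + dj)
            b, e_, pp, tt = _ols_scan(yt * sw, (Gt[:, [j]] * sw[:, None]),
                                      Xt * sw[:, None])
            beta[j], se[j], p[j], tested[j] = b[0], e_[0], pp[0], tt[0]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return AssociationScan(_scan_frame(g, beta, se, p, tested), trait, year,
                           "EMMA-style", extras={"delta": delta, "mode": mode})


def pca_factors(g: GenotypeMatrix, n_factors: int) -> np.ndarray:
    """Top principal components of the centered dosage matrix (scores)."""
    D = g.dosages.astype(float)
    Dc = D - D.mean(axis=0)
    u, s_, _ = np.linalg.svd(Dc, full_matrices=False)
    return u[:, :n_factors] * s_[:n_factors]


def scan_lfmm(y, g: GenotypeMatrix, n_factors: int = 3,
              trait: str = "", year: str = "") -> AssociationScan:
    """Latent-factor regression scan (LFMM-style).

    The top ``n_factors`` principal components of the dosage matrix model
    unobserved structure; each marker is tested by OLS with the factors
    as covariates.  ``n_factors=0`` reduces to simple regression.
    """
    y = _align_y(y, g)
    if n_factors >= g.n_samples - 2:
        raise ValueError("n_factors must be < n_samples - 2")
    n = len(y)
    X = np.ones((n, 1))
    if n_factors > 0:
        X = np.column_stack([X, pca_factors(g, n_factors)])
    beta, se, p, tested = _ols_scan(y, g.dosages.astype(float), X)
    return AssociationScan(_scan_frame(g, beta, se, p, tested), trait, year,
                           "LFMM-style", covariates=f"{n_factors} PCs")


def compress_kinship(K: np.ndarray, n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage clustering on kinship distance; returns the group
    assignment (0-based) and the n x n compressed kinship built from
    within/between group means."""
    n = K.shape[0]
    if not 1 < n_groups <= n:
        raise ValueError("need 1 < n_groups <= n")
    if n_groups == n:
        return np.arange(n), K
    d = np.diag(K)
    D = np.maximum(d[:, None] + d[None, :] - 2.0 * K, 0.0)
    np.fill_diagonal(D, 0.0)
    lab = fcluster(linkage(squareform(D, checks=False), method="average"),
                   t=n_groups, criterion="maxclust") - 1
    if len(np.unique(lab)) < 2:
        raise ValueError("degenerate clustering: all individuals in one group")
    B = np.zeros((n, lab.max() + 1))
    B[np.arange(n), lab] = 1.0
    counts = B.sum(axis=0)
    Kg = (B.T @ K @ B) / np.outer(counts, counts)
    return lab, B @ Kg @ B.T


def scan_cmlm(y, g: GenotypeMatrix, K: np.ndarray, n_groups: int | None = None,
              covariates: np.ndarray | None = None,
              trait: str = "", year: str = "") -> AssociationScan:
    """Compressed mixed-model scan (CMLM-style).

    Individuals are clustered by average linkage on kinship distance into
    ``n_groups`` (default ceil(sqrt(n))) groups sharing random effects;
    the scan then proceeds exactly as :func:`scan_mlm` on the compressed
    kinship.  ``n_groups = n`` recovers the uncompressed scan.
    """
    n = K.shape[0]
    if n_groups is None:
        n_groups = int(np.ceil(np.sqrt(n)))
    _, K_eff = compress_kinship(K, n_groups)
    out = scan_mlm(y, g, K_eff, covariates=covariates, trait=trait, year=year)
    out.method = "CMLM-style"
    out.extras["n_groups"] = n_groups
    return out


# ----------------------------------------------------------- BLINK-style

def _bic(y: np.ndarray, X: np.ndarray) -> float:
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    k = np.linalg.matrix_rank(X)
    return n * np.log(max(rss / n, 1e-300)) + k * np.log(n)


def forward_bic_select(y: np.ndarray, base: np.ndarray, cand: np.ndarray,
                       max_size: int = 10) -> list[int]:
    """Greedy forward search over candidate columns minimizing BIC of the
    model ``y ~ base + selected``.  Returns selected candidate indices."""
    selected: list[int] = []
    best = _bic(y, base)
    remaining = list(range(cand.shape[1]))
    while remaining and len(selected) < max_size:
        scores = [(_bic(y, np.column_stack([base, cand[:, selected + [j]]])), j)
                  for j in remaining]
        score, j = min(scores)
        if score >= best - 1e-9:
            break
        best = score
        selected.append(j)
        remaining.remove(j)
    return selected


def _ld_r2(G: np.ndarray, i: int, j: int) -> float:
    a, b = G[:, i], G[:, j]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def scan_blink(y, g: GenotypeMatrix, covariates: np.ndarray | None = None,
               max_iter: int = 10, ld_r2: float = 0.7, max_qtns: int = 10,
               cand_p: float | None = None, cand_pool: int = 20,
               trait: str = "", year: str = "") -> AssociationScan:
    """Iterative pseudo-QTN conditioning scan (BLINK-inspired).

    Each iteration runs a fixed-effect scan conditioning on the current
    pseudo-QTNs, filters top candidates (entry threshold ``cand_p``,
    defaulting to Bonferroni 0.05/m) so that retained candidates are
    mutually below ``ld_r2``, and re-selects the pseudo-QTN set by BIC
    forward search (max ``max_qtns``).  At the fixed point, the final scan
    conditions every marker on the selected set minus the marker's own LD
    block (r-squared >= ``ld_r2`` with the tested marker).
    """
    y = _align_y(y, g)
    n = len(y)
    G = g.dosages.astype(float)
    base = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    if cand_p is None:
        cand_p = 0.05 / g.n_markers  # Bonferroni-scaled entry threshold

    pseudo: list[int] = []
    converged = False
    for _ in range(max_iter):
        X = base if not pseudo else np.column_stack([base, G[:, pseudo]])
        _, _, p, tested = _ols_scan(y, G, X)
        p_eff = np.where(tested, p, 1.0)
        # current pseudo-QTNs are collinear with the conditioned scan, so they
        # stay in the pool by construction and compete again in the BIC search
        order = np.argsort(p_eff)
        candidates: list[int] = list(pseudo)
        for j in order:
            if p_eff[j] >= cand_p or len(candidates) >= cand_pool:
                break
            if all(_ld_r2(G, j, c) < ld_r2 for c in candidates):
                candidates.append(int(j))
        sel = forward_bic_select(y, base, G[:, candidates], max_qtns)
        new_pseudo = sorted(candidates[i] for i in sel)
        if new_pseudo == sorted(pseudo):
            pseudo = new_pseudo
            converged = True
            break
        pseudo = new_pseudo
    if not converged:
        logger.warning("scan_blink: pseudo-QTN set did not stabilize in %d "
                       "iterations; using last", max_iter)

    # final conditioned scan, excluding each marker's own block
    if not pseudo:
        beta, se, p, tested = _ols_scan(y, G, base)
    else:
        Gq = G[:, pseudo]
        sd_g = G.std(axis=0)
        sd_q = Gq.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = ((G - G.mean(0)).T @ (Gq - Gq.mean(0)) / n
                    / np.where(sd_g[:, None] * sd_q[None, :] > 0,
                               sd_g[:, None] * sd_q[None, :], np.inf))
        r2 = corr ** 2
        in_block = r2 >= ld_r2  # n_markers x n_pseudo
        free = ~in_block.any(axis=1)
        beta = np.full(g.n_markers, np.nan)
        se = np.full(g.n_markers, np.nan)
        p = np.full(g.n_markers, np.nan)
        tested = np.zeros(g.n_markers, dtype=bool)
        X_all = np.column_stack([base, Gq])
        if free.any():
            b, e_, pp, tt = _ols_scan(y, G[:, free], X_all)
            beta[free], se[free], p[free], tested[free] = b, e_, pp, tt
        for j in np.flatnonzero(~free):
            keep = [q for q, blocked in zip(pseudo, in_block[j]) if not blocked]
            Xj = base if not keep else np.column_stack([base, G[:, keep]])
            b, e_, pp, tt = _ols_scan(y, G[:, [j]], Xj)
            beta[j], se[j], p[j], tested[j] = b[0], e_[0], pp[0], tt[0]
    out = AssociationScan(_scan_frame(g, beta, se, p, tested), trait, year,
                          "BLINK-style")
    out.extras["pseudo_qtns"] = pseudo
    out.extras["converged"] = converged
    return out
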