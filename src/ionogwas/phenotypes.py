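"""Per-year trial modelling of plot-level ion data.

The plot model is ``Trait = repId + repId:subBlock + genotype + e``.
With genotype fixed it yields best linear unbiased estimators (BLUEs,
genotype-adjusted marginal means); with genotype random it yields REML
variance components and the generalized (Cullis) heritability

    H^2 = 1 - mean pairwise BLUP-difference variance / (2 sigma^2_g),

which is robust to unbalanced replication.  Iterative studentized-residual
outlier removal and a Shapiro–Wilk / Box-Cox normality gate complete the
trait preprocessing ahead of association scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------- design

@dataclass
class _Design:
    """Treatment-coded design for rep + rep:subblock, sum-to-zero genotype."""

    reps: list
    blocks: list            # "rep:subblock" labels, first block per rep dropped
    genotypes: list

    @classmethod
    def from_table(cls, t: pd.DataFrame) -> "_Design":
        reps = sorted(t["rep"].unique())
        rb = sorted((t["rep"] + ":" + t["subblock"]).unique())
        drop = {r: min(b for b in rb if b.startswith(r + ":")) for r in reps}
        blocks = [b for b in rb if b not in drop.values()]
        return cls(reps=reps, blocks=blocks, genotypes=sorted(t["genotype"].unique()))

    def matrix(self, t: pd.DataFrame) -> np.ndarray:
        n = len(t)
        rep = t["rep"].to_numpy()
        rb = (t["rep"] + ":" + t["subblock"]).to_numpy()
        geno = t["genotype"].to_numpy()
        cols = [np.ones(n)]
        cols += [(rep == r).astype(float) for r in self.reps[1:]]
        cols += [(rb == b).astype(float) for b in self.blocks]
        G = self.genotypes
        for g in G[:-1]:
            c = (geno == g).astype(float)
            c[geno == G[-1]] = -1.0
            cols.append(c)
        return np.column_stack(cols)

    def fixed_matrix(self, t: pd.DataFrame) -> np.ndarray:
        """Design without genotype columns (for the random-genotype model)."""
        n = len(t)
        rep = t["rep"].to_numpy()
        rb = (t["rep"] + ":" + t["subblock"]).to_numpy()
        cols = [np.ones(n)]
        cols += [(rep == r).astype(float) for r in self.reps[1:]]
        cols += [(rb == b).astype(float) for b in self.blocks]
        return np.column_stack(cols)

    def genotype_incidence(self, t: pd.DataFrame) -> np.ndarray:
        geno = t["genotype"].to_numpy()
        return np.column_stack([(geno == g).astype(float) for g in self.genotypes])

    def marginal_contrast(self, t: pd.DataFrame, genotype: str) -> np.ndarray:
        """Row vector predicting the genotype's mean averaged over all
        observed (rep, sub-block) cells — the estimable marginal mean."""
        cells = t[["rep", "subblock"]].drop_duplicates()
        pred = cells.copy()
        pred["genotype"] = genotype
        return self.matrix(pred).mean(axis=0)


def _subset(t: pd.DataFrame, trait: str, year: str) -> pd.DataFrame:
    if trait not in t.columns:
        raise ModelError(f"trait {trait!r} not in table")
    sub = t[(t["year"] == str(year)) & t[trait].notna()].copy()
    if sub.empty:
        raise ModelError(f"no observations for {trait} in {year}")
    return sub


# ---------------------------------------------------------------- BLUEs

def fit_blues(t: pd.DataFrame, trait: str, year: str) -> pd.DataFrame:
    """OLS genotype-adjusted means under the trial model.

    Solved through the Moore–Penrose generalized inverse of the normal
    equations; genotype marginal means are estimable under a connected
    design, so the result does not depend on the inverse chosen.  Returns
    a DataFrame indexed by genotype with columns ``blue`` and ``se``.
    """
    sub = _subset(t, trait, year)
    if sub["genotype"].nunique() < 2:
        raise ModelError("need at least two genotypes")
    design = _Design.from_table(sub)
    X = design.matrix(sub)
    y = sub[trait].to_numpy(dtype=float)
    XtX_pinv = np.linalg.pinv(X.T @ X)
    beta = XtX_pinv @ X.T @ y
    resid = y - X @ beta
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.info("fit_blues(%s, %s): rank-deficient design (%d < %d), "
                    "aliased columns resolved by generalized inverse",
                    trait, year, rank, X.shape[1])
    dof = max(len(y) - rank, 1)
    s2 = float(resid @ resid) / dof
    rows = []
    for gname in design.genotypes:
        c = design.marginal_contrast(sub, gname)
        rows.append((gname, float(c @ beta), float(np.sqrt(s2 * c @ XtX_pinv @ c))))
    return pd.DataFrame(rows, columns=["genotype", "blue", "se"]).set_index("genotype")


# ---------------------------------------------------------------- REML H2

def _reml_profile(lam: np.ndarray, y_rot: np.ndarray):
    """Profiled REML negative log-likelihood as a function of gamma = s2_g/s2_e."""
    m = len(y_rot)

    def nll(gamma: float) -> float:
        d = gamma * lam + 1.0
        s2e = float(np.mean(y_rot ** 2 / d))
        return 0.5 * (m * np.log(max(s2e, 1e-300)) + np.sum(np.log(d)))

    return nll


def fit_heritability(t: pd.DataFrame, trait: str, year: str
                     ) -> tuple[float, float, float]:
    """REML variance components and generalized heritability.

    Genotype enters as a random effect; replicate and sub-block stay
    fixed.  The single variance ratio is profiled out analytically after
    rotating the data onto the fixed-effect null space (eigendecomposition
    of the projected genotype covariance), leaving a one-dimensional
    REML maximization.  Returns ``(s2_g, s2_e, H2)`` with the Cullis form
    ``H2 = 1 - vbar_BLUP / (2 s2_g)``.
    """
    sub = _subset(t, trait, year)
    design = _Design.from_table(sub)
    X = design.fixed_matrix(sub)
    Z = design.genotype_incidence(sub)
    y = sub[trait].to_numpy(dtype=float)
    n = len(y)

    # orthonormal basis of the orthogonal complement of col(X)
    u, s, _ = np.linalg.svd(X, full_matrices=True)
    rank = int(np.sum(s > s[0] * 1e-10)) if len(s) else 0
    B = u[:, rank:]
    A = B.T @ Z @ Z.T @ B
    lam, V = np.linalg.eigh(A)
    lam = np.clip(lam, 0.0, None)
    y_rot = V.T @ (B.T @ y)

    nll = _reml_profile(lam, y_rot)
    res = minimize_scalar(lambda x: nll(np.exp(x)), bounds=(-12.0, 12.0),
                          method="bounded", options={"xatol": 1e-10})
    gamma = float(np.exp(res.x))
    if nll(0.0) <= res.fun:  # boundary: no genetic variance
        gamma = 0.0
    d = gamma * lam + 1.0
    s2e = float(np.mean(y_rot ** 2 / d))
    s2g = gamma * s2e
    if s2g <= 1e-12 * max(s2e, 1.0):
        logger.warning("fit_heritability(%s, %s): genetic variance at boundary",
                       trait, year)
        return 0.0, s2e, 0.0

    # Cullis H2 from the BLUP prediction-error covariance
    V_full = s2g * (Z @ Z.T) + s2e * np.eye(n)
    Vi = np.linalg.inv(V_full)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.pinv(XtViX) @ X.T @ Vi
    C = s2g * np.eye(Z.shape[1]) - s2g * (Z.T @ P @ Z) * s2g  # PEV of BLUPs
    cd = np.diag(C)
    pair = cd[:, None] + cd[None, :] - 2.0 * C
    g = Z.shape[1]
    vbar = float(pair.sum() / (g * (g - 1)))
    h2 = float(np.clip(1.0 - vbar / (2.0 * s2g), 0.0, 1.0))
    return s2g, s2e, h2


# ---------------------------------------------------------------- outliers

def remove_outliers_iterative(t: pd.DataFrame, trait: str, year: str,
                              alpha: float = 0.05, max_iter: int = 10
                              ) -> tuple[pd.DataFrame, int]:
    """Iteratively drop plots whose |standardized residual| exceeds the
    dataset-size-based limit ``Phi^{-1}(1 - alpha / (2n))``; refit until
    stable.  Returns the table with offending rows of this trait-year
    blanked out (set to NaN) and the number removed."""
    work = t.copy()
    removed = 0
    for _ in range(max_iter):
        sub = _subset(work, trait, year)
        design = _Design.from_table(sub)
        X = design.matrix(sub)
        y = sub[trait].to_numpy(dtype=float)
        beta = np.linalg.pinv(X) @ y
        resid = y - X @ beta
        dof = max(len(y) - np.linalg.matrix_rank(X), 1)
        sigma = np.sqrt(resid @ resid / dof)
        if sigma == 0:
            break
        limit = stats.norm.ppf(1.0 - alpha / (2.0 * len(y)))
        bad = np.abs(resid / sigma) > limit
        if not bad.any():
            break
        work.loc[sub.index[bad], trait] = np.nan
        removed += int(bad.sum())
    n0 = t[(t["year"] == str(year)) & t[trait].notna()].shape[0]
    if n0 and removed > 0.2 * n0:
        logger.warning("remove_outliers_iterative(%s, %s): removed %d of %d plots",
                       trait, year, removed, n0)
    return work, removed


def exclude_underreplicated(t: pd.DataFrame, trait: str, year: str,
                            min_reps: int = 2) -> pd.DataFrame:
    """Drop genotypes observed fewer than ``min_reps`` times for the trait-year."""
    sub = t[(t["year"] == str(year)) & t[trait].notna()]
    counts = sub.groupby("genotype").size()
    keep = set(counts.index[counts >= min_reps])
    mask = (t["year"] == str(year)) & ~t["genotype"].isin(keep)
    out = t.copy()
    out.loc[mask, trait] = np.nan
    return out


# ---------------------------------------------------------------- normality

def normality_gate_boxcox(values: np.ndarray, n_traits: int = 17,
                          alpha: float = 0.05
                          ) -> tuple[np.ndarray, float | None, float]:
    """Shapiro–Wilk gate with Bonferroni threshold ``alpha / n_traits``;
    non-normal vectors get a profile-ML Box-Cox transform (lambda grid
    [-2, 2], step 0.01).  Returns (values, lambda or None, shapiro p)."""
    v = np.asarray(values, dtype=float)
    if np.ptp(v) == 0:
        logger.warning("normality gate skipped: constant vector")
        return v, None, 1.0
    p = float(stats.shapiro(v).pvalue)
    if p >= alpha / n_traits:
        return v, None, p
    shift = 0.0
    if v.min() <= 0:
        shift = -v.min() + 1e-6 * max(np.ptp(v), 1.0)
    vs = v + shift
    grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
    llf = np.array([stats.boxcox_llf(lmb, vs) for lmb in grid])
    lam = float(grid[int(np.argmax(llf))])
    return stats.boxcox(vs, lmbda=lam), lam, p


# ---------------------------------------------------------------- driver

def analyze_trait_year(t: pd.DataFrame, trait: str, year: str,
                       min_reps: int = 2, outlier_alpha: float = 0.05
                       ) -> tuple[pd.DataFrame, dict]:
    """Full per-trait-year workflow: replication filter, iterative outlier
    removal, BLUEs, REML heritability.  Returns (blues, summary dict)."""
    work = exclude_underreplicated(t, trait, year, min_reps)
    work, n_out = remove_outliers_iterative(work, trait, year, outlier_alpha)
    blues = fit_blues(work, trait, year)
    s2g, s2e, h2 = fit_heritability(work, trait, year)
    summary = {"trait": trait, "year": str(year), "sigma2_g": s2g,
               "sigma2_e": s2e, "H2": h2, "n_outliers_removed": n_out}
    return blues, summary


def analyze_all(t: pd.DataFrame, traits: list[str], years: list[str] | None = None,
                min_reps: int = 2, gate_n_traits: int | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the trait-year workflow across the table and apply the normality
    gate across traits.  Returns (long BLUE table, summary table)."""
    years = years or sorted(t["year"].unique())
    gate_n = gate_n_traits or len(traits)
    blues_rows, summaries = [], []
    for trait in traits:
        for year in years:
            blues, summ = analyze_trait_year(t, trait, year, min_reps)
            vals, lam, shp = normality_gate_boxcox(blues["blue"].to_numpy(), gate_n)
            summ["boxcox_lambda"] = lam
            summ["shapiro_p"] = shp
            summaries.append(summ)
            for gname, val, se in zip(blues.index, vals, blues["se"]):
                blues_rows.append((trait, str(year), gname, float(val), float(se)))
    blue_table = pd.DataFrame(blues_rows,
                              columns=["trait", "year", "genotype", "blue", "se"])
    return blue_table, pd.DataFrame(summaries)
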