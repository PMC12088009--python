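"""Descriptive statistics for soil and leaf ion tables.

IQR outlier screening (conventional 1.5-fence by default; the literal
"outside Q1..Q3" rule is kept as an explicit mode), coefficient of
variation, Kruskal-Wallis group tests, pairwise-complete Pearson
correlation matrices with significance flags, and a scaled-PCA variance
decomposition with per-variable cos2 and contributions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def iqr_filter(values, rule: str = "fences", k: float = 1.5
               ) -> tuple[np.ndarray, np.ndarray]:
    """Split values into (kept, removed) by an interquartile-range rule.

    ``fences`` removes points outside [Q1 - k*IQR, Q3 + k*IQR];
    ``literal`` removes everything outside [Q1, Q3] (which discards about
    half of any continuous sample — offered only to mirror a verbatim
    quartile rule).  Quartiles use linear interpolation.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        logger.warning("iqr_filter: fewer than 4 values, nothing removed")
        return v, np.array([])
    q1, q3 = np.percentile(v, [25, 75])
    if rule == "fences":
        lo, hi = q1 - k * (q3 - q1), q3 + k * (q3 - q1)
    elif rule == "literal":
        lo, hi = q1, q3
    else:
        raise ValueError(f"unknown rule {rule!r}")
    keep = (v >= lo) & (v <= hi)
    return v[keep], v[~keep]


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 * sample SD (n-1) / mean."""
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p across group labels."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    res = stats.kruskal(*[v[g == lv] for lv in levels])
    return float(res.statistic), float(res.pvalue)


def correlation_matrix(table: pd.DataFrame, conf: float = 0.95) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations in long format.

    Columns: ion_a, ion_b, r, p, n, significant (p < 1 - conf).  Cells
    with fewer than 3 complete pairs or a zero-variance column come back
    with NaN r/p and significant=False.
    """
    cols = list(table.columns)
    rows = []
    alpha = 1.0 - conf
    for i, a in enumerate(cols):
        for b in cols[i:]:
            x, y = table[a].to_numpy(float), table[b].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            n = int(ok.sum())
            if n < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rows.append((a, b, np.nan, np.nan, n, False))
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append((a, b, float(r), float(p), n, bool(p < alpha)))
    return pd.DataFrame(rows, columns=["ion_a", "ion_b", "r", "p", "n",
                                       "significant"])


def pca_variance(table: pd.DataFrame) -> dict:
    """PCA of centered, unit-scaled columns via SVD.

    Returns a dict with ``percent_variance`` (sums to 100), ``loadings``
    (variables x components, correlation-scaled), ``scores``, ``cos2``
    and ``contributions`` (percent per variable per axis).  Constant
    columns are dropped with a warning.
    """
    X = table.to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        logger.warning("pca_variance: dropping %d constant columns",
                       int((~keep).sum()))
    X = X[:, keep]
    names = [c for c, k in zip(table.columns, keep) if k]
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 complete rows and columns")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    var = s ** 2 / (X.shape[0] - 1)
    pct = 100.0 * var / var.sum()
    loadings = vt.T * np.sqrt(var)  # variable-component correlations
    cos2 = loadings ** 2
    contrib = 100.0 * cos2 / cos2.sum(axis=0, keepdims=True)
    return {
        "variables": names,
        "percent_variance": pct,
        "loadings": pd.DataFrame(loadings, index=names,
                                 columns=[f"Dim{i+1}" for i in range(len(pct))]),
        "scores": u * s,
        "cos2": pd.DataFrame(cos2, index=names,
                             columns=[f"Dim{i+1}" for i in range(len(pct))]),
        "contributions": pd.DataFrame(contrib, index=names,
                                      columns=[f"Dim{i+1}" for i in range(len(pct))]),
    }
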