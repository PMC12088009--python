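"""Ancestry estimation by nonnegative matrix factorization and genotype imputation.

The dosage matrix, rescaled to ALT-allele frequencies ``X = dosage / 2``,
is factorized as ``X ~ Q F`` where the rows of Q (one per individual) are
admixture proportions on the probability simplex and F holds ancestral ALT
frequencies in [0, 1].  The number of ancestral groups K is chosen by a
masked cross-entropy criterion: a fraction of observed entries is held out
per replicate, and the binomial deviance of the predicted frequencies on
those entries scores each (K, replicate) fit.  Missing genotypes are then
imputed from the fitted expectation ``2 Q F``.

The optimizer is block projected-gradient descent with exact 1/L step
sizes and an expectation–maximization fill-in of missing entries, which
makes the training loss monotonically non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-6


@dataclass
class AncestryModel:
    """Fitted admixture model: ``K`` groups, ``Q`` (n x K), ``F`` (K x m)."""

    K: int
    Q: np.ndarray
    F: np.ndarray
    cross_entropy: dict = field(default_factory=dict)  # (K, replicate) -> masked CE
    loss_history: np.ndarray | None = None  # training loss of the selected fit
    converged: bool = True


def project_simplex_rows(Q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = Q.shape
    u = np.sort(Q, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1  # last true index
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(Q - theta[:, None], 0.0)


def _binomial_deviance(dose_half: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(np.mean(-(dose_half * np.log(p) + (1.0 - dose_half) * np.log(1.0 - p))))


def _fit_qf(X: np.ndarray, obs: np.ndarray, K: int, rng: np.random.Generator,
            max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Fit X ~ QF on observed entries.  Returns (Q, F, loss_history, converged).

    Each outer iteration fills unobserved entries with the current model
    prediction (an MM step for the observed-entry squared loss) and then
    takes one exact-step projected-gradient update per block, so the
    recorded training loss never increases.
    """
    n, m = X.shape
    n_obs = obs.sum()
    Q = rng.dirichlet(np.ones(K), size=n)
    col_mean = np.where(obs.any(axis=0),
                        np.nansum(np.where(obs, X, 0.0), axis=0) / np.maximum(obs.sum(axis=0), 1),
                        0.5)
    F = np.clip(col_mean[None, :] + 0.05 * rng.standard_normal((K, m)), _EPS, 1 - _EPS)

    losses = []
    converged = False
    for it in range(max_iter):
        P = Q @ F
        Xc = np.where(obs, X, P)
        loss = float(np.sum((np.where(obs, X - P, 0.0)) ** 2) / n_obs)
        losses.append(loss)
        if it >= 2 and losses[-2] - loss < tol * max(losses[0], 1e-12):
            converged = True
            break
        # Q block: one projected-gradient step with exact Lipschitz step size
        G = (Q @ F - Xc) @ F.T
        L_q = np.linalg.norm(F @ F.T, 2)
        Q = project_simplex_rows(Q - G / max(L_q, _EPS))
        # F block (refresh the fill so each block step is a descent step)
        Xc = np.where(obs, X, Q @ F)
        G = Q.T @ (Q @ F - Xc)
        L_f = np.linalg.norm(Q.T @ Q, 2)
        F = np.clip(F - G / max(L_f, _EPS), 0.0, 1.0)
    return Q, F, np.asarray(losses), converged


def estimate_ancestry(g: GenotypeMatrix, K_range=range(1, 11), replicates: int = 10,
                      mask_fraction: float = 0.05, seed: int = 0,
                      max_iter: int = 200, tol: float = 1e-7) -> AncestryModel:
    """Fit admixture models over ``K_range`` and select by masked cross-entropy.

    For each (K, replicate), ``mask_fraction`` of the observed entries is
    held out, the factorization fitted on the rest, and the binomial
    deviance of the predicted ALT frequency against held-out dosage/2
    recorded.  The fit minimizing that loss is returned; pass a single-K
    range to fix K manually.
    """
    obs_all = g.observed_mask()
    if not obs_all.any(axis=0).all():
        raise ValueError("every marker needs at least one observed call")
    X = np.where(obs_all, g.dosages, 0).astype(float) / 2.0
    rng = np.random.default_rng(seed)
    obs_idx = np.flatnonzero(obs_all.ravel())

    best = None
    ce = {}
    for K in K_range:
        for rep in range(replicates):
            n_mask = max(1, int(round(mask_fraction * obs_idx.size)))
            mask_flat = rng.choice(obs_idx, size=n_mask, replace=False)
            obs_fit = obs_all.copy()
            obs_fit.ravel()[mask_flat] = False
            if not obs_fit.any(axis=0).all():  # keep every marker identifiable
                lonely = ~obs_fit.any(axis=0)
                cols = np.flatnonzero(lonely)
                drop = np.isin(mask_flat % X.shape[1], cols)
                obs_fit.ravel()[mask_flat[drop]] = True
                mask_flat = mask_flat[~drop]
            Q, F, losses, conv = _fit_qf(X, obs_fit, K, rng, max_iter, tol)
            if not conv:
                logger.warning("ancestry fit K=%d rep=%d: max_iter reached", K, rep)
            P = (Q @ F).ravel()
            ce[(K, rep)] = _binomial_deviance(X.ravel()[mask_flat], P[mask_flat])
            if best is None or ce[(K, rep)] < best[0]:
                best = (ce[(K, rep)], K, Q, F, losses, conv)
    _, K, Q, F, losses, conv = best
    logger.info("estimate_ancestry: selected K=%d (masked CE %.5f)", K, best[0])
    return AncestryModel(K=K, Q=Q, F=F, cross_entropy=ce, loss_history=losses,
                         converged=conv)


def masked_cross_entropy(g: GenotypeMatrix, Q: np.ndarray, F: np.ndarray,
                         entries: np.ndarray) -> float:
    """Binomial deviance of ``Q F`` predictions at flat ``entries`` indices."""
    X = g.dosages.astype(float).ravel() / 2.0
    P = (Q @ F).ravel()
    return _binomial_deviance(X[entries], P[entries])


def estimate_inbreeding(g: GenotypeMatrix) -> float:
    """Panel-level inbreeding coefficient from the heterozygote deficit,
    ``F = 1 - observed het / expected HWE het`` (clipped to [0, 1])."""
    obs = g.observed_mask()
    p = g.alt_freq()
    exp_het = float(np.nansum(2.0 * p * (1.0 - p) * obs.sum(axis=0)))
    obs_het = float((g.dosages == 1).sum())
    if exp_het <= 0:
        return 0.0
    return float(np.clip(1.0 - obs_het / exp_het, 0.0, 1.0))


def impute_missing(g: GenotypeMatrix, model: AncestryModel,
                   mode: str = "class", continuous: bool = False):
    """Fill missing dosages from the ancestry expectation ``p = Q F``.

    ``mode='class'`` (default) assigns the most probable genotype class
    under inbreeding-adjusted frequencies: with the panel's estimated
    inbreeding coefficient f, P(0) = (1-p)^2 + f p(1-p),
    P(1) = 2 p (1-p) (1-f), P(2) = p^2 + f p(1-p).  For a mostly
    homozygous panel this rarely imputes heterozygotes.  ``mode='round'``
    instead takes the genotype class nearest the expected dosage ``2 p``.
    Observed calls are untouched.  With ``continuous=True`` the raw
    expected dosages are returned as a float matrix.
    """
    if model.Q.shape[0] != g.n_samples or model.F.shape[1] != g.n_markers:
        raise ValueError("ancestry model dimensions do not match genotype matrix")
    P = np.clip(model.Q @ model.F, _EPS, 1.0 - _EPS)
    obs = g.observed_mask()
    if continuous:
        out = g.dosages.astype(float)
        out[~obs] = (2.0 * P)[~obs]
        return out
    if mode == "round":
        filled = np.clip(np.rint(2.0 * P), 0, 2).astype(np.int8)
    elif mode == "class":
        f = estimate_inbreeding(g)
        het = 2.0 * P * (1.0 - P)
        probs = np.stack([(1.0 - P) ** 2 + f * P * (1.0 - P),
                          het * (1.0 - f),
                          P ** 2 + f * P * (1.0 - P)])
        filled = np.argmax(probs, axis=0).astype(np.int8)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    dos = g.dosages.copy()
    dos[~obs] = filled[~obs]
    return GenotypeMatrix(dos, list(g.sample_ids), g.markers, g.skipped_records)
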