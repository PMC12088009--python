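"""Synthetic admixed genotype panels and incomplete-block field-trial phenotypes.

The generator emulates the data structure of a two-season ionomics field
study on a mostly-inbred diversity panel: an admixed population built
from the Balding–Nichols model (K ancestral groups, Dirichlet admixture,
divergence parameter F), near-complete homozygosity, uniform missing
calls; and a completely-randomized-block trial (years x replicates x
sub-blocks x plots) producing plot-level ion concentrations driven by
planted QTLs, a kinship-structured polygenic background, design effects,
a flowering-time confounder and correlated residuals.  The ground truth
(ancestry matrices, QTL positions/effects, variance components) is
returned alongside so downstream recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, _marker_frame

#: Leaf ions carried through the trial model (17 elements, mg/kg).
ION_TRAITS = ["As", "Ca", "Cd", "Co", "Cu", "Fe", "K", "Mg", "Mn",
              "Mo", "Na", "Ni", "P", "Rb", "S", "Sr", "Zn"]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the admixed genotype panel generator."""

    n_individuals: int = 150
    n_markers: int = 5000
    n_chromosomes: int = 7
    chrom_length_bp: int = 100_000_000
    K_ancestral: int = 4
    admixture_concentration: float = 0.3  # Dirichlet alpha
    allele_freq_divergence: float = 0.2   # Balding–Nichols F
    missing_rate: float = 0.0
    het_retention: float = 0.05           # fraction of heterozygous draws kept
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_individuals", "n_markers", "n_chromosomes",
                     "chrom_length_bp", "K_ancestral"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_markers < self.n_chromosomes:
            raise ConfigError("n_markers must be >= n_chromosomes")
        for name in ("missing_rate", "het_retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0.0 < self.allele_freq_divergence < 1.0:
            raise ConfigError("allele_freq_divergence must be in (0, 1)")
        if self.admixture_concentration <= 0:
            raise ConfigError("admixture_concentration must be positive")


@dataclass
class QTLSpec:
    """A planted additive QTL: marker index, per-ALT-allele effect, or the
    fraction of phenotypic variance it should explain (effect derived)."""

    trait: str
    marker_index: int
    effect_size: float | None = None
    variance_fraction: float | None = None


@dataclass
class TrialDesign:
    """Two-year, replicated, sub-blocked trial layout and design-effect scales."""

    n_years: int = 2
    n_replicates: int = 4
    n_subblocks: int = 10
    plots_per_subblock: int = 16
    year_effect_sd: float = 1.0
    rep_effect_sd: float = 0.5
    block_effect_sd: float = 0.5
    residual_sd: float = 1.0  # fallback when a trait has no variance components

    def validate(self, n_individuals: int) -> None:
        if self.n_subblocks * self.plots_per_subblock < n_individuals:
            raise ConfigError("replicate capacity below number of genotypes")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study."""

    Q_true: np.ndarray
    F_true: np.ndarray
    qtls: list[QTLSpec] = field(default_factory=list)
    variance_components: dict = field(default_factory=dict)  # trait -> (s2_g, s2_e)
    flowering_effects: dict = field(default_factory=dict)    # trait -> slope
    genetic_values: pd.DataFrame | None = None               # genotype x trait
    flowering_time: pd.Series | None = None                  # genotype level


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Draw an admixed, mostly-homozygous SNP panel.

    Ancestral ALT frequencies follow the Balding–Nichols construction
    around a shared base frequency; each individual's marker-wise ALT
    frequency is the admixture mixture ``p_ij = sum_k q_ik f_kj``.  Two
    alleles are drawn per call; heterozygous draws are collapsed to a
    random homozygote with probability ``1 - het_retention``.  Missing
    calls are injected uniformly at ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m, K = config.n_individuals, config.n_markers, config.K_ancestral

    # marker map: markers split across chromosomes, sorted positions
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    chrom, pos = [], []
    for c, k in enumerate(per_chrom, start=1):
        chrom += [f"chr{c}"] * int(k)
        p = np.sort(rng.choice(config.chrom_length_bp, size=int(k), replace=False)) + 1
        pos += p.tolist()
    ids = [f"{c}_{p}" for c, p in zip(chrom, pos)]

    Fdiv = config.allele_freq_divergence
    base = rng.uniform(0.1, 0.9, size=m)
    a = base * (1.0 - Fdiv) / Fdiv
    b = (1.0 - base) * (1.0 - Fdiv) / Fdiv
    F_true = np.clip(rng.beta(a, b, size=(K, m)), 1e-4, 1 - 1e-4)
    Q_true = rng.dirichlet(np.full(K, config.admixture_concentration), size=n)

    P = Q_true @ F_true
    a1 = rng.random((n, m)) < P
    a2 = rng.random((n, m)) < P
    dos = (a1.astype(np.int8) + a2.astype(np.int8))
    het = dos == 1
    collapse = het & (rng.random((n, m)) >= config.het_retention)
    # selfing fixes a heterozygous lineage at either homozygote with equal
    # probability, so the marginal allele frequency is unchanged
    dos[collapse] = np.where(rng.random((n, m))[collapse] < 0.5, 2, 0)
    if config.missing_rate > 0:
        dos[rng.random((n, m)) < config.missing_rate] = MISSING

    samples = [f"G{i+1:03d}" for i in range(n)]
    g = GenotypeMatrix(dos, samples, _marker_frame(chrom, pos, ids,
                                                   ["A"] * m, ["T"] * m))
    return g, SyntheticTruth(Q_true=Q_true, F_true=F_true)


def _realized_kinship(dosages: np.ndarray) -> np.ndarray:
    # VanRaden genomic relationship on the simulated dosages
    p = dosages.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    W = dosages[:, keep] - 2.0 * p[keep]
    denom = 2.0 * np.sum(p[keep] * (1.0 - p[keep]))
    return W @ W.T / max(denom, 1e-12)


def _qtl_effect(q: QTLSpec, dos_var: float, s2_g: float, s2_e: float,
                vf_total: float) -> float:
    if q.effect_size is not None:
        return q.effect_size
    if q.variance_fraction is None:
        raise ConfigError("QTLSpec needs effect_size or variance_fraction")
    # total phenotypic variance so that the QTL explains its stated share
    s2_p = (s2_g + s2_e) / max(1.0 - vf_total, 1e-9)
    return float(np.sqrt(q.variance_fraction * s2_p / max(dos_var, 1e-12)))


def simulate_trial(genotypes: GenotypeMatrix, truth: SyntheticTruth,
                   design: TrialDesign, seed: int,
                   traits: list[str] | None = None,
                   trait_corr: np.ndarray | None = None,
                   trait_means: dict | float = 100.0,
                   flowering_mean: float = 70.0,
                   flowering_sd: float = 5.0) -> pd.DataFrame:
    """Simulate plot-level trait values for a replicated, sub-blocked trial.

    Plot value = year effect + replicate effect + replicate:sub-block
    effect + genotypic value + residual, where the genotypic value sums
    planted QTL effects, a polygenic deviate with covariance proportional
    to the realized kinship, and a flowering-time confounding term.
    Genotypes are randomized to plots independently within each
    replicate-year.  Mutates ``truth`` with realized genetic values and
    flowering times.
    """
    design.validate(genotypes.n_samples)
    traits = list(traits) if traits is not None else sorted(
        set(truth.variance_components) | {q.trait for q in truth.qtls}) or ["trait"]
    for q in truth.qtls:
        if not 0 <= q.marker_index < genotypes.n_markers:
            raise ConfigError(f"QTL marker index {q.marker_index} out of range")
    rng = np.random.default_rng(seed)
    n, T = genotypes.n_samples, len(traits)
    dos = np.where(genotypes.observed_mask(), genotypes.dosages, 0).astype(float)

    C = np.eye(T) if trait_corr is None else np.linalg.cholesky(
        np.asarray(trait_corr) + 1e-10 * np.eye(T))
    K = _realized_kinship(dos)
    Lk = np.linalg.cholesky(K + 1e-6 * np.eye(n))

    s2g = np.array([truth.variance_components.get(t, (1.0, design.residual_sd ** 2))[0]
                    for t in traits])
    s2e = np.array([truth.variance_components.get(t, (1.0, design.residual_sd ** 2))[1]
                    for t in traits])

    # polygenic values, correlated across traits; columns standardized so the
    # realized genetic variance matches the requested component
    gval = Lk @ rng.standard_normal((n, T)) @ C.T
    sd = gval.std(axis=0, ddof=1)
    gval = gval / np.where(sd > 0, sd, 1.0) * np.sqrt(s2g)[None, :]

    # flowering time: its own polygenic basis at genotype level
    ft = flowering_mean + flowering_sd * (Lk @ rng.standard_normal(n))
    ft_c = ft - ft.mean()
    for j, t in enumerate(traits):
        slope = truth.flowering_effects.get(t, 0.0)
        gval[:, j] += slope * ft_c

    vf_tot = {t: sum(q.variance_fraction or 0.0 for q in truth.qtls if q.trait == t)
              for t in traits}
    for q in truth.qtls:
        j = traits.index(q.trait)
        d = dos[:, q.marker_index]
        beta = _qtl_effect(q, float(d.var()), s2g[j], s2e[j], vf_tot[q.trait])
        q.effect_size = beta
        gval[:, j] += beta * (d - d.mean())

    mu = np.array([trait_means.get(t, 0.0) if isinstance(trait_means, dict)
                   else float(trait_means) for t in traits])

    rows = []
    values = []
    for y in range(design.n_years):
        year = str(2021 + y)
        y_eff = rng.normal(0.0, design.year_effect_sd, size=T)
        for r in range(design.n_replicates):
            r_eff = rng.normal(0.0, design.rep_effect_sd, size=T)
            b_eff = rng.normal(0.0, design.block_effect_sd,
                               size=(design.n_subblocks, T))
            n_plots = design.n_subblocks * design.plots_per_subblock
            plot_order = rng.permutation(n_plots)[:n]
            for i in range(n):
                plot = int(plot_order[i])
                sb = plot // design.plots_per_subblock
                resid = (C @ rng.standard_normal(T)) * np.sqrt(s2e)
                val = mu + y_eff + r_eff + b_eff[sb] + gval[i] + resid
                rows.append((genotypes.sample_ids[i], year, f"R{r+1}", f"B{sb+1}",
                             float(ft[i])))
                values.append(val)
    table = pd.DataFrame(rows, columns=["genotype", "year", "rep", "subblock",
                                        "flowering_time"])
    table[traits] = np.asarray(values)
    truth.genetic_values = pd.DataFrame(gval, index=genotypes.sample_ids,
                                        columns=traits)
    truth.flowering_time = pd.Series(ft, index=genotypes.sample_ids,
                                     name="flowering_time")
    return table


def write_trial_tsv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_trial_tsv(path: str) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype={"genotype": str, "year": str,
                                           "rep": str, "subblock": str})
    return t


def write_truth_json(truth: SyntheticTruth, path: str) -> None:
    """Serialize ground truth (arrays as nested lists) for later scoring."""
    payload = {
        "Q_true": truth.Q_true.tolist(),
        "F_true": truth.F_true.tolist(),
        "qtls": [asdict(q) for q in truth.qtls],
        "variance_components": {t: list(v) for t, v in truth.variance_components.items()},
        "flowering_effects": dict(truth.flowering_effects),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
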