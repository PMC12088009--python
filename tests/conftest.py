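import numpy as np
import pytest

import ionogwas as ig
from ionogwas.genotypes import _marker_frame


def make_matrix(dosages, chrom=None, pos=None):
    """Small hand-built GenotypeMatrix for boundary tests."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    chrom = chrom or ["chr1"] * m
    pos = pos or list(range(1, m + 1))
    mk = _marker_frame(chrom, pos, [f"s{j}" for j in range(m)],
                       ["A"] * m, ["T"] * m)
    return ig.GenotypeMatrix(dosages, [f"I{i}" for i in range(n)], mk)


@pytest.fixture(scope="session")
def small_panel():
    """Admixed panel, 80 samples x 600 markers, 5% missing."""
    cfg = ig.SimulationConfig(n_individuals=80, n_markers=600, seed=42,
                              missing_rate=0.05)
    g, truth = ig.simulate_genotypes(cfg)
    return g, truth


@pytest.fixture(scope="session")
def clean_panel():
    """Complete (no missing) structured panel, 100 samples x 2000 markers."""
    cfg = ig.SimulationConfig(n_individuals=100, n_markers=2000, seed=7,
                              missing_rate=0.0)
    g, truth = ig.simulate_genotypes(cfg)
    return g, truth


@pytest.fixture(scope="session")
def trial_study():
    """Panel plus a two-year trial for one trait with H2 around 0.8."""
    cfg = ig.SimulationConfig(n_individuals=100, n_markers=600, seed=3)
    g, truth = ig.simulate_genotypes(cfg)
    truth.variance_components = {"Mg": (1.0, 1.0)}
    table = ig.simulate_trial(g, truth, ig.TrialDesign(), seed=30)
    return g, truth, table


def structured_null_phenotype(K: np.ndarray, seed: int) -> np.ndarray:
    """Polygenic + iid noise, the mixed-model engines' assumed null."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(K + 1e-6 * np.eye(K.shape[0]))
    return L @ rng.standard_normal(K.shape[0]) + rng.standard_normal(K.shape[0])
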