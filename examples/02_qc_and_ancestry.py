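"""Genotype quality control and ancestry estimation.

Applies the marker filters (missingness, MAF), the sample call-rate
filter and the heterozygosity cap, then factorizes the panel into
admixture proportions Q and ancestral allele frequencies F, selecting K
by masked cross-entropy, and imputes the remaining missing calls from
the fitted model.
"""

import numpy as np

import ionogwas as ig

g, _ = ig.simulate_genotypes(ig.SimulationConfig(
    n_individuals=120, n_markers=2000, K_ancestral=3, missing_rate=0.05,
    seed=21))

g1 = ig.filter_markers(g)            # >=50% missing or MAF < 5% out
g2 = ig.filter_samples(g1)           # call rate < 80% out
print(f"markers {g.n_markers} -> {g1.n_markers}, "
      f"samples {g.n_samples} -> {g2.n_samples}")

model = ig.estimate_ancestry(g2, K_range=range(1, 6), replicates=3, seed=0,
                             max_iter=150)
print(f"\nselected K = {model.K}")
print("best masked cross-entropy by K:")
best_by_k = {}
for (k, _rep), ce in model.cross_entropy.items():
    best_by_k[k] = min(ce, best_by_k.get(k, np.inf))
for k, ce in sorted(best_by_k.items()):
    marker = " <-- selected" if k == model.K else ""
    print(f"  K={k}: {ce:.4f}{marker}")

print(f"\nQ rows sum to one: max deviation "
      f"{np.abs(model.Q.sum(axis=1) - 1).max():.2e}")
dominant = model.Q.argmax(axis=1)
print("individuals per inferred group:",
      np.bincount(dominant, minlength=model.K).tolist())

imputed = ig.impute_missing(g2, model)
print(f"\nmissing calls before imputation: {(g2.dosages == -1).sum()}, "
      f"after: {(imputed.dosages == -1).sum()}")

g3 = ig.filter_heterozygosity(imputed)
print(f"heterozygosity cap: {imputed.n_markers} -> {g3.n_markers} markers")
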