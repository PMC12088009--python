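"""Simulate an admixed inbred panel and a two-year ionomics field trial.

The generator draws ancestral allele frequencies from a Balding-Nichols
model, mixes them through Dirichlet admixture proportions, collapses
heterozygotes to mimic a selfing crop, and lays out a replicated
incomplete-block trial with correlated ion traits and a flowering-time
confounder.
"""

import numpy as np

import ionogwas as ig

cfg = ig.SimulationConfig(n_individuals=150, n_markers=5000, K_ancestral=4,
                          missing_rate=0.03, seed=11)
g, truth = ig.simulate_genotypes(cfg)
print(f"panel: {g.n_samples} genotypes x {g.n_markers} SNPs "
      f"on {g.markers['chrom'].nunique()} chromosomes")
print(f"missing calls: {100 * (g.dosages == -1).mean():.1f}%  "
      f"heterozygous calls: {100 * (g.dosages == 1).mean():.2f}%")

# two ion traits with different heritability plus one planted QTL
truth.variance_components = {"Zn": (1.0, 1.0), "Fe": (0.3, 2.8)}
truth.flowering_effects = {"Fe": 0.05}
maf = g.maf()
qtl_marker = int(np.flatnonzero(maf > 0.3)[100])
truth.qtls.append(ig.QTLSpec("Zn", marker_index=qtl_marker,
                             variance_fraction=0.15))

trial = ig.simulate_trial(g, truth, ig.TrialDesign(), seed=12)
print(f"\ntrial table: {len(trial)} plots "
      f"({trial['year'].nunique()} years x {trial['rep'].nunique()} reps)")
print(trial.head(6).to_string(index=False))

ig.write_vcf(g, "panel.vcf")
ig.sim.write_trial_tsv(trial, "trial.tsv")
ig.sim.write_truth_json(truth, "truth.json")
print("\nwrote panel.vcf, trial.tsv, truth.json")
print(f"planted QTL for Zn at marker {g.markers['id'].iloc[qtl_marker]}")
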