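# ionogwas

Multi-stage genome-wide association pipeline for leaf-ionome field
trials in structured, selfing crop panels — from raw SNP matrix and
plot-level trait table to consensus marker–trait associations (MTAs),
QTL blocks and candidate-gene reports — plus a synthetic-data generator
that reproduces the study design (admixed inbred panel, two seasons,
replicated incomplete blocks, correlated ion traits, flowering-time
confounding) so every stage can be calibrated and power-tested on one
desktop CPU.

## The problem

Ionome GWAS in a diversity panel faces four compounding difficulties:

1. **Population structure and kinship** inflate single-marker tests, so
   association needs mixed models or latent-factor corrections rather
   than plain regression.
2. **Field noise**: each trait is measured on replicated plots in
   incomplete blocks over two seasons; genotype means must be adjusted
   for replicate and sub-block effects before association.
3. **Multiplicity with linkage**: thousands of correlated markers make
   raw Bonferroni both miscalibrated and punishing; false-discovery
   control needs an effective number of independent tests.
4. **Method disagreement**: different scan engines have different
   power/robustness trade-offs, so the study retains only markers that
   several engines flag consistently across seasons.

The pipeline mirrors that workflow:

| stage | module | what it does |
|---|---|---|
| simulate | `ionogwas.sim` | Balding–Nichols admixed panel, het collapse, two-year trial with planted QTLs |
| genotype QC | `ionogwas.genotypes`, `ionogwas.ancestry` | missingness/MAF/call-rate/heterozygosity filters; sNMF-style ancestry (Q, F) with masked cross-entropy K selection; model-based imputation |
| trait model | `ionogwas.phenotypes` | outlier screen, BLUEs from `Trait = rep + rep:subblock + genotype`, REML variance components, Cullis generalized H², Shapiro/Box-Cox gate |
| descriptives | `ionogwas.descriptives` | IQR screening, CV, Kruskal–Wallis, correlation matrices, scaled PCA |
| association | `ionogwas.assoc` | four engines: EMMA-style mixed model, LFMM-style latent factors, CMLM-style compressed kinship, BLINK-style pseudo-QTN conditioning |
| aggregation | `ionogwas.aggregate` | Fisher cross-year combination, LD pruning, BH/FDR thresholds, 2-method consensus, LD-block QTLs, flowering-time residual pass |
| reporting | `ionogwas.reporting`, `ionogwas.cli` | candidate genes from GFF3, allele-class effects, expression join, Manhattan/QQ exports, genomic inflation |

## Worked example

```python
import numpy as np
import ionogwas as ig

# an admixed panel with one planted QTL explaining 15% of variance
g, truth = ig.simulate_genotypes(ig.SimulationConfig(
    n_individuals=150, n_markers=3000, K_ancestral=4, seed=41))
truth.variance_components = {"Zn": (1.0, 1.0)}
qtl = int(np.flatnonzero(g.maf() > 0.3)[250])
truth.qtls.append(ig.QTLSpec("Zn", marker_index=qtl, variance_fraction=0.15))
trial = ig.simulate_trial(g, truth, ig.TrialDesign(n_years=1), seed=42)

blues = ig.fit_blues(trial, "Zn", "2021")["blue"]
scan = ig.scan_mlm(blues, g, ig.kinship(g))
```

Running `examples/04_scan_engines.py` (exactly the code above plus the
other three engines) prints:

```
planted QTL: chr2_26491839

engine       top marker        -log10 p   p at QTL  lambda
EMMA-style   chr2_26491839          7.7    2.2e-08   1.029
LFMM-style   chr2_26491839          6.2    6.8e-07   1.042
CMLM-style   chr2_26491839          6.0    9.3e-07   1.138
BLINK-style  chr2_26491839          6.9    1.2e-07   1.258
```

All four engines rank the planted marker first, with genomic inflation
close to 1 under the polygenic background.  The full cross-year
consensus (engines × seasons, FDR thresholds from an LD-pruned
independent set, Fisher combination, QTL blocks) is one call:

```python
result = ig.run_gwas_study(g, blue_table, flowering=flowering_series)
```

See `examples/` for one short narrative script per capability
(simulation, QC + ancestry, BLUEs + heritability, scan engines,
consensus + QTL blocks, candidate reporting), and `ionogwas --help` for
the equivalent shell workflow (`simulate`, `qc`, `blues`,
`descriptives`, `gwas`, `combine`, `qtl`, `report`).

## Notes

`docs/methods.md` documents the statistical model behind each stage,
the numerical choices (eigendecomposition-based REML, projected-gradient
factorization, P3D approximation) and the known limitations of the
synthetic generator.
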