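"""Candidate genes, allele effects and expression for a QTL block.

Screens gene models from a GFF3 file against a QTL window, reports
overlap or signed distance from the top marker, summarizes phenotype
means per genotype class at the top marker, and joins per-tissue
expression values onto the candidate list.
"""

import textwrap

import numpy as np
import pandas as pd

import ionogwas as ig

g, truth = ig.simulate_genotypes(ig.SimulationConfig(
    n_individuals=150, n_markers=2000, seed=61))
truth.variance_components = {"Zn": (1.0, 1.0)}
qtl = int(np.flatnonzero(g.maf() > 0.3)[80])
truth.qtls.append(ig.QTLSpec("Zn", marker_index=qtl, variance_fraction=0.2))
trial = ig.simulate_trial(g, truth, ig.TrialDesign(n_years=1), seed=62)
blues = ig.fit_blues(trial, "Zn", "2021")["blue"]

marker = g.markers.iloc[qtl]
pos = int(marker["pos"])
block = ig.QTLBlock(name="Zn_Cont1-1", trait="Zn", chrom=str(marker["chrom"]),
                    start=max(1, pos - 25_000), end=pos + 25_000,
                    top_marker=str(marker["id"]))

with open("genes.gff3", "w") as fh:
    fh.write(textwrap.dedent(f"""\
        ##gff-version 3
        {block.chrom}\tdemo\tgene\t{pos - 4000}\t{pos + 1500}\t.\t+\t.\tID=gene_inside;Note=metal transporter
        {block.chrom}\tdemo\tgene\t{pos + 60_000}\t{pos + 65_000}\t.\t-\t.\tID=gene_downstream
        """))
genes = ig.read_gff3("genes.gff3")
cands = ig.genes_in_qtl(block, genes, top_marker_pos=pos)
print(f"QTL window {block.chrom}:{block.start:,}-{block.end:,} "
      f"(top marker {block.top_marker})")
print(cands[["gene_id", "distance_bp", "location", "annotation"]]
      .to_string(index=False))

print("\nallele classes at the top marker:")
effects = ig.allele_effect_summary(g.dosages[:, qtl], blues,
                                   alleles=(marker["ref"], marker["alt"]))
print(effects.round(3).to_string(index=False))

expr = pd.DataFrame({"gene_id": ["gene_inside"],
                     "leaf": [8.4], "root": [1.1]})
joined = ig.join_expression(cands, expr)
print("\nwith expression:")
print(joined[["gene_id", "location", "leaf", "root", "expression_status"]]
      .to_string(index=False))
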