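"""Assign cis-regulatory variants to their nearest genes and test term
enrichment.

Each variant links to the single nearest TSS within 1 Mb; target sets per
ancestry are intersected (Venn counts) and one gene set is tested for
GO-term enrichment against a background with one planted term.
"""

import numpy as np
import pandas as pd

from introcre import genetargets
from introcre.synthdata import EpigenomeConfig, simulate_epigenome

rng = np.random.default_rng(3)
pos = np.sort(rng.choice(np.arange(1, 5_000_000), 600, replace=False))
variants = pd.DataFrame(
    {
        "variant_id": [f"1:{p}" for p in pos],
        "chrom": "1",
        "pos": pos,
        "ref": "A",
        "alt": "G",
        "group": rng.permutation(
            ["DENISOVAN"] * 200 + ["NEANDERTHAL"] * 150 + ["CONTROL"] * 250
        ),
    }
)
epi = simulate_epigenome(EpigenomeConfig(n_genes=80, seed=3), variants, "1", 5_000_000)

assigned = genetargets.assign_nearest_gene(variants, epi.genes)
assigned = assigned.merge(variants[["variant_id", "group"]], on="variant_id")
print(f"{len(assigned)} of {len(variants)} variants assigned to a gene within 1 Mb")
print(f"median distance to TSS: {assigned['distance'].median():.0f} bp")

sets = {g: grp for g, grp in assigned.groupby("group")}
venn = genetargets.target_overlap(sets)
print("\nTarget-gene Venn regions:")
for region, count in venn["counts"].items():
    print(f"  {region:30s} {count:4d}  ({100 * venn['fractions'][region]:.1f}%)")

background = sorted(set(assigned["gene"]))
targets = sorted(set(sets["DENISOVAN"]["gene"]))
# plant one term on the Denisovan targets to demonstrate detection
go_map = pd.concat(
    [epi.go_map, pd.DataFrame({"gene": targets, "term": "GO:planted"})],
    ignore_index=True,
)
terms = genetargets.term_enrichment(targets, background, go_map)
print("\nTop enriched terms (hypergeometric, BH q < 0.01 flagged):")
print(terms.nsmallest(5, "p").round(6).to_string(index=False))
# The planted term tops the table with q far below 0.01; random terms do not.
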