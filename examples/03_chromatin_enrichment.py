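"""Chromatin-state and tissue enrichment with a planted effect.

Plants a 4-fold concentration of Denisovan variants in enhancer chromatin
(Enh) within Blood & T-cell cell types, annotates every variant against
per-cell-type 15-state segmentations, and recovers the effect with odds
ratios, Fisher's exact test and BH correction.
"""

import numpy as np
import pandas as pd

from introcre import chromannot, enrich
from introcre.synthdata import EpigenomeConfig, simulate_epigenome

rng = np.random.default_rng(0)
n = 2000
pos = np.sort(rng.choice(np.arange(1, 20_000_000), 2 * n, replace=False))
variants = pd.DataFrame(
    {
        "variant_id": [f"1:{p}" for p in pos],
        "pos": pos,
        "ref": "A",
        "alt": "G",
        "group": rng.permutation(["DENISOVAN"] * n + ["CONTROL"] * n),
    }
)

cfg = EpigenomeConfig(planted_or={("Enh", "Blood & T-cell"): 4.0}, seed=0)
epi = simulate_epigenome(cfg, variants, "1", 20_000_000)

ann = chromannot.annotate_states(variants, epi.segmentations, epi.tissue_map)
ann = ann.merge(variants[["variant_id", "group"]], on="variant_id")
case = ann[ann["group"] == "DENISOVAN"]
ctrl = ann[ann["group"] == "CONTROL"]

states = enrich.run_state_enrichment({"DENISOVAN": case}, ctrl)
print("Per-state enrichment (counting unit: variant x cell-type pairs):")
print(states[["combo", "a", "c", "oddsratio", "p", "q", "stars"]].round(4).to_string(index=False))

tissues = enrich.run_tissue_enrichment({"DENISOVAN": case}, ctrl)
print("\nPer-tissue enrichment within CRE states:")
print(tissues[["combo", "oddsratio", "q", "stars"]].round(4).to_string(index=False))
# Enh carries the planted excess; Blood & T-cell is the enriched tissue.
# Because tissue odds ratios compare shares of the pooled CRE annotations,
# a genuine concentration in one tissue necessarily surfaces as mild
# depletion of the others — the comparisons are compositional.
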