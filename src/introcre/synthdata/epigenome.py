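"""Simulate per-cell-type chromatin segmentations and gene-level annotations
with planted, known enrichment effects.

States are drawn per (variant, cell type) from a baseline genome-wide state
distribution; for planted (state, tissue) combinations the in-state
probability of archaic-group variants is tilted so that the odds of being
in the state, relative to control variants, equal the configured odds
ratio.  Each cell type's segmentation is then built as a tiling of the
chromosome whose segment containing each variant carries that variant's
drawn state — so downstream interval annotation recovers the planted
memberships exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..states import CHROMATIN_STATES
from .config import EpigenomeConfig

# Rough genome-wide state frequencies (quiescent chromatin dominates).
DEFAULT_STATE_PROBS = {
    "TssA": 0.015,
    "TssAFlnk": 0.015,
    "TxFlnk": 0.005,
    "Tx": 0.09,
    "TxWk": 0.12,
    "EnhG": 0.015,
    "Enh": 0.06,
    "ZNF/Rpts": 0.01,
    "Het": 0.05,
    "TssBiv": 0.005,
    "BivFlnk": 0.005,
    "EnhBiv": 0.01,
    "ReprPC": 0.02,
    "ReprPCWk": 0.06,
    "Quies": 0.52,
}


@dataclass
class EpigenomeData:
    segmentations: dict
    tissue_map: pd.DataFrame
    elements: pd.DataFrame
    genes: pd.DataFrame
    go_map: pd.DataFrame
    eqtls: pd.DataFrame
    bstat: pd.DataFrame
    truth_states: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path

        from .. import io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_segmentations(self.segmentations, outdir / "segmentations")
        io.write_table(self.tissue_map, outdir / "tissue_map.tsv")
        io.write_bed(self.elements, outdir / "elements.bed", ["element_class"])
        io.write_table(self.genes, outdir / "genes.tsv")
        io.write_table(self.go_map, outdir / "go_map.tsv")
        io.write_table(self.eqtls, outdir / "eqtls.tsv")
        io.write_bed(self.bstat, outdir / "bstat.bed", ["b"])
        io.write_table(self.truth_states, outdir / "truth_states.tsv")


def _state_probs(config: EpigenomeConfig) -> np.ndarray:
    probs = dict(DEFAULT_STATE_PROBS)
    if config.baseline_state_probs:
        probs.update(config.baseline_state_probs)
    p = np.array([probs[s] for s in CHROMATIN_STATES], dtype=float)
    return p / p.sum()


def _tilt(baseline: np.ndarray, state_idx: int, oddsratio: float) -> np.ndarray:
    """Probability vector whose odds for ``state_idx`` are ``oddsratio``
    times the baseline odds; other states share the remainder
    proportionally."""
    p0 = baseline[state_idx]
    odds = oddsratio * p0 / (1.0 - p0)
    p1 = odds / (1.0 + odds)
    out = baseline * (1.0 - p1) / (1.0 - p0)
    out[state_idx] = p1
    return out


def simulate_epigenome(
    config: EpigenomeConfig,
    variants: pd.DataFrame,
    chrom: str,
    chrom_length: int,
    control_group: str = "CONTROL",
) -> EpigenomeData:
    """Generate segmentations, tissue map, elements, genes, GO map, eQTLs
    and B-statistic intervals for a variant table.

    ``variants`` columns: variant_id, pos, ref, alt, group; groups other
    than ``control_group`` receive the planted odds ratios.
    """
    if variants["pos"].max() > chrom_length:
        raise ValueError("variant positions exceed the chromosome length")
    rng = np.random.default_rng(config.seed)
    baseline = _state_probs(config)
    state_arr = np.array(CHROMATIN_STATES)
    state_idx = {s: i for i, s in enumerate(CHROMATIN_STATES)}

    variants = variants.sort_values("pos", kind="mergesort").reset_index(drop=True)
    pos = variants["pos"].to_numpy()
    is_case = (variants["group"] != control_group).to_numpy()

    tissue_map = pd.DataFrame(
        {"cell_type": list(config.cell_types), "tissue": list(config.cell_types.values())}
    )

    segmentations: dict[str, pd.DataFrame] = {}
    truth_rows = []
    bounds = np.concatenate([[0], (pos[:-1] + pos[1:]) // 2, [chrom_length]])
    for cell_type, tissue in config.cell_types.items():
        probs_case = baseline.copy()
        for (state, t), oddsratio in config.planted_or.items():
            if t is None or t == tissue:
                probs_case = _tilt(probs_case, state_idx[state], oddsratio)
        draws_ctrl = rng.choice(len(state_arr), size=len(pos), p=baseline)
        draws_case = rng.choice(len(state_arr), size=len(pos), p=probs_case)
        states = np.where(is_case, draws_case, draws_ctrl)
        seg = pd.DataFrame(
            {
                "chrom": chrom,
                "start": bounds[:-1],
                "end": bounds[1:],
                "state": state_arr[states],
            }
        )
        segmentations[cell_type] = seg
        truth_rows.append(
            pd.DataFrame(
                {
                    "variant_id": variants["variant_id"],
                    "cell_type": cell_type,
                    "state": state_arr[states],
                    "tissue": tissue,
                }
            )
        )
    truth_states = pd.concat(truth_rows, ignore_index=True)

    # gene models: TSS positions, simple gene bodies for element classes
    tss = np.sort(rng.choice(np.arange(5000, chrom_length - 10_000), size=config.n_genes, replace=False))
    genes = pd.DataFrame(
        {
            "gene": [f"GENE{i + 1:04d}" for i in rng.permutation(config.n_genes)],
            "chrom": chrom,
            "tss": tss,
            "strand": rng.choice(["+", "-"], size=config.n_genes),
        }
    )
    el_rows = []
    for t in tss:
        el_rows += [
            {"chrom": chrom, "start": max(0, t - 2000), "end": t, "element_class": "promoter"},
            {"chrom": chrom, "start": t, "end": t + 200, "element_class": "UTR"},
            {"chrom": chrom, "start": t + 500, "end": t + 800, "element_class": "CDS"},
            {"chrom": chrom, "start": t + 800, "end": t + 2000, "element_class": "intron"},
            {"chrom": chrom, "start": t + 2000, "end": t + 2300, "element_class": "CDS"},
        ]
    elements = pd.DataFrame(el_rows).sort_values(["start", "end"]).reset_index(drop=True)

    terms = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    go_rows = []
    for g in genes["gene"]:
        for t in rng.choice(terms, size=rng.integers(1, 5), replace=False):
            go_rows.append({"gene": g, "term": t})
    go_map = pd.DataFrame(go_rows)

    n_eq = min(config.n_eqtls, len(variants))
    picked = variants.iloc[
        np.sort(rng.choice(len(variants), size=n_eq, replace=False))
    ].copy()
    swap = rng.random(n_eq) < config.eqtl_swap_fraction
    eq_ref = np.where(swap, picked["alt"], picked["ref"])
    eq_alt = np.where(swap, picked["ref"], picked["alt"])
    eqtls = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": picked["pos"].to_numpy(),
            "ref": eq_ref,
            "alt": eq_alt,
            "gene": rng.choice(genes["gene"].to_numpy(), size=n_eq),
            "qval": rng.uniform(0, 0.05, size=n_eq).round(6),
        }
    )

    edges = np.linspace(0, chrom_length, config.n_bstat_intervals + 1).astype(int)
    bstat = pd.DataFrame(
        {
            "chrom": chrom,
            "start": edges[:-1],
            "end": edges[1:],
            "b": np.clip(rng.normal(800, 120, size=config.n_bstat_intervals), 1, 1000).astype(int),
        }
    )

    return EpigenomeData(
        segmentations=segmentations,
        tissue_map=tissue_map,
        elements=elements,
        genes=genes,
        go_map=go_map,
        eqtls=eqtls,
        bstat=bstat,
        truth_states=truth_states,
    )
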