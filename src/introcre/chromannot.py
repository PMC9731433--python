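"""Annotation of variants against genomic elements, chromatin states,
eQTL tables and background-selection (B-statistic) intervals.

Interval semantics throughout: BED inputs are 0-based half-open; 1-based
variant positions are converted before lookup, so a variant at 1-based
position p falls in [start, end) iff start < p <= end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .states import UNANNOTATED

__all__ = [
    "annotate_elements",
    "coding_depletion_table",
    "annotate_states",
    "pleiotropy",
    "overlap_eqtls",
    "overlay_bstat",
]


def _ensure_sorted(bed: pd.DataFrame) -> pd.DataFrame:
    if not bed["start"].is_monotonic_increasing:
        bed = bed.sort_values(["start", "end"], kind="mergesort").reset_index(drop=True)
    return bed


def annotate_elements(calls: pd.DataFrame, elements: pd.DataFrame) -> pd.DataFrame:
    """All element classes overlapping each variant (long frame
    ``variant_id, element_class``); variants overlapping nothing are
    labelled ``intergenic``."""
    elements = _ensure_sorted(elements)
    starts = elements["start"].to_numpy()
    ends = elements["end"].to_numpy()
    classes = elements["element_class"].to_numpy()
    rows = []
    for vid, pos in zip(calls["variant_id"], calls["pos"]):
        p0 = pos - 1  # 0-based
        hit = (starts <= p0) & (p0 < ends)
        if hit.any():
            for cl in np.unique(classes[hit]):
                rows.append({"variant_id": vid, "element_class": cl})
        else:
            rows.append({"variant_id": vid, "element_class": "intergenic"})
    return pd.DataFrame(rows)


def coding_depletion_table(
    case_elements: pd.DataFrame, control_elements: pd.DataFrame, coding_class: str = "CDS"
) -> tuple[int, int, int, int]:
    """2x2 counts (case coding, case non-coding, control coding, control
    non-coding) of variants overlapping at least one coding interval."""

    def split(ann: pd.DataFrame) -> tuple[int, int]:
        coding = ann.loc[ann["element_class"] == coding_class, "variant_id"].nunique()
        total = ann["variant_id"].nunique()
        return coding, total - coding

    a, b = split(case_elements)
    c, d = split(control_elements)
    return a, b, c, d


def annotate_states(
    calls: pd.DataFrame,
    segmentations: dict[str, pd.DataFrame],
    tissue_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """State of each variant in each cell type (long frame with columns
    ``variant_id, cell_type, state[, tissue]``).

    Each segmentation is assumed to tile its chromosome; a position outside
    all segments of a cell type is flagged UNANNOTATED and excluded from
    downstream counts."""
    pos0 = calls["pos"].to_numpy() - 1
    vids = calls["variant_id"].to_numpy()
    frames = []
    for cell_type, seg in segmentations.items():
        seg = _ensure_sorted(seg)
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        st = seg["state"].to_numpy()
        j = np.searchsorted(starts, pos0, side="right") - 1
        ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, len(ends) - 1)])
        state = np.where(ok, st[np.clip(j, 0, len(st) - 1)], UNANNOTATED)
        frames.append(
            pd.DataFrame(
                {"variant_id": vids, "cell_type": cell_type, "state": state}
            )
        )
    ann = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["variant_id", "cell_type", "state"]
    )
    ann = ann[ann["state"] != UNANNOTATED].reset_index(drop=True)
    if tissue_map is not None:
        ann = ann.merge(tissue_map, on="cell_type", how="left")
    return ann


def pleiotropy(state_matrix: pd.DataFrame) -> pd.DataFrame:
    """Number of cell types annotating each variant in the same state — a
    proxy for the pleiotropic activity of the element carrying it."""
    out = (
        state_matrix.groupby(["variant_id", "state"], sort=True)["cell_type"]
        .nunique()
        .reset_index(name="n_cell_types")
    )
    return out


def overlap_eqtls(calls: pd.DataFrame, eqtls: pd.DataFrame) -> dict:
    """Variants matching a significant cis-eQTL on (chrom, pos, ref, alt).

    Matching is strict and orientation-sensitive (no allele flipping); a
    variant associated with several eGenes counts once.  Returns the matched
    subset, the count, and the fraction of the supplied call set."""
    key = ["chrom", "pos", "ref", "alt"]
    eq = eqtls.drop_duplicates(subset=key)[key]
    merged = calls.merge(eq, on=key, how="inner").drop_duplicates(subset="variant_id")
    n = len(calls)
    return {
        "matched": merged,
        "count": int(len(merged)),
        "fraction": len(merged) / n if n else np.nan,
    }


def overlay_bstat(
    call_sets: dict[str, pd.DataFrame], bstat: pd.DataFrame
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """B-statistic value of each variant's containing interval, per call
    set, plus pairwise two-sided Mann-Whitney comparisons of the resulting
    distributions.  Variants outside every interval are dropped (counted via
    the returned array lengths)."""
    bstat = _ensure_sorted(bstat)
    starts = bstat["start"].to_numpy()
    ends = bstat["end"].to_numpy()
    bvals = bstat["b"].to_numpy(dtype=float)
    values: dict[str, np.ndarray] = {}
    for name, calls in call_sets.items():
        pos0 = calls["pos"].to_numpy() - 1
        j = np.searchsorted(starts, pos0, side="right") - 1
        ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, len(ends) - 1)])
        values[name] = bvals[np.clip(j, 0, len(bvals) - 1)][ok]
    names = list(values)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va, vb = values[a], values[b]
            if min(len(va), len(vb)) < 2 or (
                len(np.unique(np.concatenate([va, vb]))) < 2
            ):
                p = np.nan
            else:
                p = stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue
            rows.append({"set_a": a, "set_b": b, "n_a": len(va), "n_b": len(vb), "p": p})
    return values, pd.DataFrame(rows)
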