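"""Odds-ratio enrichment of archaic variants across chromatin states and tissues.

For every combination of interest (a chromatin state, or a CRE state-group x
tissue pair) we build a 2x2 table of archaic vs control counting units in /
out of the combination, estimate the odds ratio, test it with Fisher's exact
test, and correct within each ancestry by Benjamini-Hochberg.

The counting unit defaults to (variant, cell type) annotation pairs, pooling
information across all cell types; ``unit="distinct_variants"`` instead
counts each variant once if it carries the state in at least one cell type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .states import CHROMATIN_STATES, CRE_STATES

__all__ = [
    "EnrichmentResult",
    "bh_adjust",
    "fisher_exact",
    "build_contingency",
    "run_state_enrichment",
    "run_tissue_enrichment",
    "significance_stars",
]


@dataclass
class EnrichmentResult:
    """One 2x2 enrichment outcome: ``a``/``b`` are case units in/out of the
    combination, ``c``/``d`` the control units."""

    combo: str
    ancestry: str
    a: int
    b: int
    c: int
    d: int
    oddsratio: float
    p: float
    q: float = math.nan


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaNs are excluded from the ranking and propagated unchanged.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards, cap at 1
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table ``[[a, b], [c, d]]``.

    Returns ``(oddsratio, p)``.  The p-value uses the point-probability
    rule on the conditional hypergeometric distribution.  The odds ratio is
    the sample estimate a*d/(b*c), with the Haldane-Anscombe +0.5 correction
    applied to every cell when any cell is zero.  A zero margin makes the
    odds ratio undefined (NaN) with p = 1.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("contingency table entries must be non-negative integers")
    if min(a + b, c + d, a + c, b + d) == 0:
        return math.nan, 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        oddsratio = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oddsratio = (a * d) / (b * c)
    return oddsratio, p


def _combo_mask(ann: pd.DataFrame, combo: str, level: str) -> pd.Series:
    if level == "state":
        if combo not in CHROMATIN_STATES:
            raise ValueError(
                f"unknown state combo {combo!r}; valid: {sorted(CHROMATIN_STATES)}"
            )
        return ann["state"] == combo
    if level == "tissue":
        tissues = ann["tissue"].unique()
        if combo not in tissues:
            raise ValueError(f"unknown tissue combo {combo!r}; valid: {sorted(tissues)}")
        return (ann["tissue"] == combo) & ann["state"].isin(CRE_STATES)
    if level == "state_tissue":
        state, tissue = combo
        if state not in CHROMATIN_STATES:
            raise ValueError(
                f"unknown state {state!r}; valid: {sorted(CHROMATIN_STATES)}"
            )
        return (ann["state"] == state) & (ann["tissue"] == tissue)
    raise ValueError(f"unknown level {level!r}")


def build_contingency(
    case_ann: pd.DataFrame,
    control_ann: pd.DataFrame,
    combo: str,
    level: str = "state",
    unit: str = "variant_celltype_pairs",
) -> tuple[int, int, int, int]:
    """Count case/control units in and out of ``combo``.

    ``case_ann``/``control_ann`` are long state-annotation frames with
    columns ``variant_id, cell_type, state`` (plus ``tissue`` for tissue
    combos).  For ``level="tissue"`` both in- and out-of-combo counts are
    restricted to CRE-state annotations, mirroring the restriction of the
    tissue analysis to cis-regulatory elements.
    """
    if unit not in ("variant_celltype_pairs", "distinct_variants"):
        raise ValueError(f"unknown counting unit {unit!r}")

    def count(ann: pd.DataFrame) -> tuple[int, int]:
        if level == "state":
            universe = ann
        elif level == "tissue":
            universe = ann[ann["state"].isin(CRE_STATES)]
        else:  # state_tissue: in/out within the combo's tissue
            universe = ann[ann["tissue"] == combo[1]]
        mask = _combo_mask(universe, combo, level)
        if unit == "variant_celltype_pairs":
            a = int(mask.sum())
            total = len(universe)
        else:
            a = universe.loc[mask, "variant_id"].nunique()
            total = universe["variant_id"].nunique()
        return a, total - a

    a, b = count(case_ann)
    c, d = count(control_ann)
    return a, b, c, d


def _run(
    annotations: dict[str, pd.DataFrame],
    control_ann: pd.DataFrame,
    combos,
    level: str,
    unit: str,
) -> pd.DataFrame:
    rows = []
    for ancestry, ann in annotations.items():
        for combo in combos:
            a, b, c, d = build_contingency(ann, control_ann, combo, level, unit)
            oddsratio, p = fisher_exact([[a, b], [c, d]])
            rows.append(
                {
                    "combo": combo,
                    "ancestry": ancestry,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "oddsratio": oddsratio,
                    "p": p,
                }
            )
    res = pd.DataFrame(rows)
    # BH family: all combos within one ancestry
    res["q"] = np.nan
    for ancestry in annotations:
        sel = res["ancestry"] == ancestry
        res.loc[sel, "q"] = bh_adjust(res.loc[sel, "p"].to_numpy())
    res["stars"] = [significance_stars(q) for q in res["q"]]
    return res


def run_state_enrichment(
    annotations: dict[str, pd.DataFrame],
    control_ann: pd.DataFrame,
    unit: str = "variant_celltype_pairs",
) -> pd.DataFrame:
    """Enrichment of each ancestry vs the control set across all 15 states."""
    return _run(annotations, control_ann, CHROMATIN_STATES, "state", unit)


def run_tissue_enrichment(
    annotations: dict[str, pd.DataFrame],
    control_ann: pd.DataFrame,
    unit: str = "variant_celltype_pairs",
) -> pd.DataFrame:
    """Enrichment across tissues, restricted to CRE-state annotations."""
    tissues = sorted(control_ann["tissue"].dropna().unique())
    return _run(annotations, control_ann, tissues, "tissue", unit)


def significance_stars(q: float) -> str:
    """Star code for a BH-adjusted p-value (thresholds 0.05/0.01/0.001/0.0001)."""
    if not np.isfinite(q):
        return ""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if q <= cut:
            return stars
    return ""
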