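"""Per-site population differentiation (Weir-Cockerham Fst) and cross-
population sharing of classified variants.

The Fst estimator is the Weir & Cockerham (1984) variance-component form
for diploid data and two populations: at each biallelic site the among-
population (a), among-individual-within-population (b) and within-individual
(c) components are computed from sample sizes, allele frequencies and
observed heterozygosities, and Fst = a / (a + b + c).  Negative estimates
are retained; a site monomorphic in both populations is NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["wc_fst_counts", "wc_fst", "sharing_tally", "compare_fst"]


def wc_fst_counts(counts1, counts2, return_components: bool = False):
    """Weir-Cockerham Fst from per-population diploid genotype counts.

    ``counts1``/``counts2`` are arrays of shape (..., 3): numbers of
    (hom-ref, het, hom-alt) individuals at each site.  Broadcasts over any
    leading shape.  Invariant under swapping the ref/alt labels.
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    n1 = c1.sum(axis=-1)
    n2 = c2.sum(axis=-1)
    r = 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = (c1[..., 1] + 2 * c1[..., 2]) / (2 * n1)
        p2 = (c2[..., 1] + 2 * c2[..., 2]) / (2 * n2)
        h1 = c1[..., 1] / n1
        h2 = c2[..., 1] / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        fst = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    if return_components:
        return fst, a, b, c
    return fst


def _geno_counts(geno: np.ndarray) -> np.ndarray:
    """Collapse a (sites, 2N) haplotype matrix into (sites, 3) genotype
    counts, dropping individuals with any missing allele at a site."""
    n_ind = geno.shape[1] // 2
    pairs = geno[:, : 2 * n_ind].reshape(geno.shape[0], n_ind, 2)
    ok = (pairs >= 0).all(axis=2)
    dosage = pairs.sum(axis=2)
    out = np.zeros((geno.shape[0], 3))
    for d in (0, 1, 2):
        out[:, d] = ((dosage == d) & ok).sum(axis=1)
    return out


def wc_fst(geno_pop1: np.ndarray, geno_pop2: np.ndarray) -> np.ndarray:
    """Per-site Fst from phased haplotype matrices of two populations."""
    return wc_fst_counts(_geno_counts(geno_pop1), _geno_counts(geno_pop2))


def sharing_tally(
    calls_pop1: pd.DataFrame,
    calls_pop2: pd.DataFrame,
    require_retained: bool = False,
) -> pd.DataFrame:
    """Per-ancestry counts and fractions of population-1 variants that also
    segregate within same-ancestry haplotypes in population 2.

    A variant is shared iff population 2 classifies the same (chrom, pos)
    to the same ancestry; ``require_retained`` additionally demands it
    survived population 2's filter cascade.
    """
    p2 = calls_pop2
    if require_retained:
        p2 = p2[~p2["excluded"]]
    key2 = set(zip(p2["chrom"], p2["pos"], p2["ancestry"]))
    rows = []
    for ancestry, grp in calls_pop1.groupby("ancestry", sort=True):
        if not ancestry:
            continue
        shared = sum(
            (ch, pos, ancestry) in key2 for ch, pos in zip(grp["chrom"], grp["pos"])
        )
        rows.append(
            {
                "ancestry": ancestry,
                "n_total": len(grp),
                "n_shared": int(shared),
                "fraction": shared / len(grp) if len(grp) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def compare_fst(fst_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests between per-site Fst
    distributions (NaN-filtered)."""
    clean = {}
    for name, vals in fst_by_group.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 1:
            raise ValueError(f"group {name!r} has no finite Fst values")
        clean[name] = v
    names = list(clean)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            p = stats.mannwhitneyu(
                clean[a], clean[b], alternative="two-sided", method="asymptotic"
            ).pvalue
            rows.append(
                {"group_a": a, "group_b": b, "n_a": len(clean[a]), "n_b": len(clean[b]),
                 "p": float(p)}
            )
    return pd.DataFrame(rows)
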