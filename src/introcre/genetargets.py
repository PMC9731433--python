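"""Gene-target assignment for cis-regulatory variants and term enrichment.

Each variant is linked to the single nearest gene (distance to the
strand-aware transcription start site) within 1 Mb, so no variant yields
multiple gene associations.  Target-set overlaps across ancestries are
summarised as Venn region counts, and gene-set term enrichment uses the
one-sided hypergeometric upper tail with BH correction (significant at
q < 0.01).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["assign_nearest_gene", "target_overlap", "term_enrichment"]


def assign_nearest_gene(
    calls: pd.DataFrame, tss_table: pd.DataFrame, max_dist: float = 1_000_000
) -> pd.DataFrame:
    """Nearest-TSS gene within ``max_dist`` for each variant.

    ``tss_table`` columns: gene, chrom, tss (1-based), strand.  Exactly
    equidistant ties go to the lexicographically smaller gene id.  Variants
    beyond ``max_dist`` of every gene are omitted from the result.
    """
    rows = []
    for chrom, grp in calls.groupby("chrom", sort=True):
        genes = tss_table[tss_table["chrom"].astype(str) == str(chrom)]
        if genes.empty:
            continue
        # collapse genes sharing a TSS coordinate to the lexicographically
        # smallest id up front; remaining ties (left vs right neighbour at
        # equal distance) resolve the same way below
        per_tss = genes.groupby("tss", sort=True)["gene"].min()
        tss = per_tss.index.to_numpy()
        names = per_tss.to_numpy()
        pos = grp["pos"].to_numpy()
        j = np.searchsorted(tss, pos)
        for vid, p, jj in zip(grp["variant_id"], pos, j):
            cand = []
            if jj > 0:
                cand.append((abs(p - tss[jj - 1]), names[jj - 1]))
            if jj < len(tss):
                cand.append((abs(p - tss[jj]), names[jj]))
            dist, gene = min(cand, key=lambda t: (t[0], t[1]))
            if dist <= max_dist:
                rows.append({"variant_id": vid, "gene": gene, "distance": int(dist)})
    return pd.DataFrame(rows, columns=["variant_id", "gene", "distance"])


def target_overlap(assignments_by_ancestry: dict[str, set | pd.DataFrame]) -> dict:
    """Venn region counts and fractions for three ancestry target-gene sets.

    Accepts gene sets, or assignment frames with a ``gene`` column.  Region
    keys are '+'-joined sorted ancestry names; fractions are over the union.
    """
    sets = {
        name: set(v["gene"]) if isinstance(v, pd.DataFrame) else set(v)
        for name, v in assignments_by_ancestry.items()
    }
    if len(sets) != 3:
        raise ValueError("target_overlap expects exactly three ancestry sets")
    names = sorted(sets)
    union = set().union(*sets.values())
    counts = {}
    for mask in range(1, 8):
        members = [names[i] for i in range(3) if mask >> i & 1]
        region = set(union)
        for i, name in enumerate(names):
            region &= sets[name] if mask >> i & 1 else union - sets[name]
        counts["+".join(members)] = len(region)
    total = len(union)
    return {
        "counts": counts,
        "total": total,
        "fractions": {k: v / total if total else np.nan for k, v in counts.items()},
    }


def term_enrichment(
    target_genes,
    background_genes,
    term_map: pd.DataFrame,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of ``target_genes`` against
    ``background_genes`` (targets must be a subset of the background).

    ``term_map`` columns: gene, term.  For each term with K background
    genes, of which k are targets, p = P(X >= k) for X hypergeometric
    (N background, K term genes, n targets).  Empty terms are skipped.
    """
    targets = set(target_genes)
    background = set(background_genes)
    if not targets <= background:
        missing = sorted(targets - background)[:5]
        raise ValueError(f"target genes absent from background: {missing} ...")
    tm = term_map[term_map["gene"].isin(background)]
    big_n, n = len(background), len(targets)
    rows = []
    for term, grp in tm.groupby("term", sort=True):
        term_genes = set(grp["gene"])
        big_k = len(term_genes)
        if big_k == 0:
            continue
        k = len(term_genes & targets)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"term": term, "k": k, "K": big_k, "n": n, "N": big_n, "p": p})
    res = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(res):
        from .enrich import bh_adjust

        res["q"] = bh_adjust(res["p"].to_numpy())
        res["significant"] = res["q"] < q_threshold
    return res
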