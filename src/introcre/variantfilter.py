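"""Classification of cohort variants into Denisovan / Neanderthal / non-archaic.

The cascade mirrors the high-confidence aSNP filtering strategy:

1. biallelic SNPs only;
2. singletons removed (minor-allele count exactly 1);
3. polarisation against an ancestral-allele table (sites lacking a call, or
   whose ancestral allele matches neither observed allele, are excluded);
4. ancestry assignment from haplotype tracts; variants segregating in tracts
   of both ancestries are disambiguated first by the class-specific frequency
   of the main introgressed allele, then by matching it against the Altai
   Denisovan / Neanderthal reference genotypes, else labelled ambiguous;
5. frequency computation: the main introgressed allele frequency (MIAF) and
   derived allele frequency (DAF) use the total-chromosome denominator, while
   the archaic / non-archaic class frequencies use class-specific denominators;
6. removal of archaic variants whose signed archaic-minus-non-archaic class
   frequency difference is below 0.25;
7. removal of variants whose focal allele segregates at frequency >= 0.005 in
   the outgroup panel;
8. labelling as low (< 0.05) or common-to-high (>= 0.05) frequency.

A variant "falls within archaic haplotypes" when at least one haplotype
carrying its derived allele lies inside an archaic tract at that position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synthdata.config import AMBIGUOUS, DENISOVAN, NEANDERTHAL, NONARCHAIC

# terminal exclusion reasons
MULTIALLELIC = "MULTIALLELIC"
SINGLETON = "SINGLETON"
NO_ANCESTRAL = "NO_ANCESTRAL"
ANCESTRAL_MISMATCH = "ANCESTRAL_MISMATCH"
AMBIGUOUS_ANCESTRY = "AMBIGUOUS_ANCESTRY"
NO_DATA = "NO_DATA"
FREQ_DIFF = "FREQ_DIFF"
OUTGROUP = "OUTGROUP"

LOW = "LOW"
COMMON_TO_HIGH = "COMMON_TO_HIGH"

_CTX_NONE, _CTX_DEN, _CTX_NEA = 0, 1, 2


@dataclass
class VariantSet:
    """Genotype matrix plus per-haplotype ancestry context.

    ``geno``: (n_sites, n_haplotypes) int8, 0 = ref, 1 = alt, -1 missing.
    ``context``: same shape, 0 = none, 1 = Denisovan, 2 = Neanderthal tract.
    """

    chrom: str
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    geno: np.ndarray
    context: np.ndarray
    multiallelic: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.positions)

    def take(self, idx) -> "VariantSet":
        return replace(
            self,
            positions=self.positions[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            geno=self.geno[idx],
            context=self.context[idx],
            multiallelic=None if self.multiallelic is None else self.multiallelic[idx],
        )


def build_context(positions, tracts: pd.DataFrame, samples) -> np.ndarray:
    """Per-(site, haplotype) ancestry context from tract intervals.

    Tract coordinates are 0-based half-open; positions are 1-based.  Where
    tracts of both ancestries overlap on one haplotype, the Denisovan label
    wins (applied first)."""
    positions = np.asarray(positions)
    sample_idx = {s: i for i, s in enumerate(samples)}
    ctx = np.zeros((len(positions), 2 * len(samples)), dtype=np.int8)
    codes = {DENISOVAN: _CTX_DEN, NEANDERTHAL: _CTX_NEA}
    for ancestry in (DENISOVAN, NEANDERTHAL):
        code = codes[ancestry]
        for row in tracts[tracts["ancestry"] == ancestry].itertuples(index=False):
            hap = 2 * sample_idx[row.sample] + int(row.hap_index)
            mask = (positions > row.start) & (positions <= row.end)
            free = ctx[:, hap] == _CTX_NONE
            ctx[mask & free, hap] = code
    return ctx


def from_cohort(cohort) -> VariantSet:
    return VariantSet(
        chrom=cohort.chrom,
        positions=cohort.positions,
        ref=cohort.ref,
        alt=cohort.alt,
        geno=cohort.geno,
        context=build_context(cohort.positions, cohort.tracts, cohort.samples),
        multiallelic=np.zeros(len(cohort.positions), dtype=bool),
    )


# ---------------------------------------------------------------------------
# individual filter steps


def minor_allele_counts(geno: np.ndarray) -> np.ndarray:
    nm = geno >= 0
    alt = ((geno == 1) & nm).sum(axis=1)
    total = nm.sum(axis=1)
    return np.minimum(alt, total - alt)


def remove_singletons(vs: VariantSet) -> VariantSet:
    """Drop variants whose minor-allele count is exactly 1."""
    return vs.take(minor_allele_counts(vs.geno) != 1)


def polarize(vs: VariantSet, ancestral: pd.DataFrame):
    """Derived allele per site from the ancestral-allele table.

    Returns ``(derived, reason)`` arrays; ``derived`` is '' where the site
    is excluded, with ``reason`` NO_ANCESTRAL or ANCESTRAL_MISMATCH.
    """
    table = {
        (str(r.chrom), int(r.pos)): str(r.allele)
        for r in ancestral.itertuples(index=False)
    }
    derived = np.empty(len(vs), dtype=object)
    reason = np.empty(len(vs), dtype=object)
    for i, pos in enumerate(vs.positions):
        anc = table.get((str(vs.chrom), int(pos)))
        if anc is None or anc == ".":
            derived[i], reason[i] = "", NO_ANCESTRAL
        elif anc == vs.ref[i]:
            derived[i], reason[i] = vs.alt[i], ""
        elif anc == vs.alt[i]:
            derived[i], reason[i] = vs.ref[i], ""
        else:
            derived[i], reason[i] = "", ANCESTRAL_MISMATCH
    return derived, reason


def _site_arrays(vs: VariantSet, i: int):
    g = vs.geno[i]
    c = vs.context[i]
    nm = g >= 0
    return g, c, nm


def assign_ancestry(vs: VariantSet, i: int, derived_allele: str, altai_row) -> dict:
    """Ancestry call for one variant (see module docstring for the rules).

    ``altai_row`` is ``(denisovan_allele, neanderthal_allele)`` or ``None``.
    Returns ancestry, dual-site flag, and the main introgressed allele for
    archaic calls.
    """
    g, c, nm = _site_arrays(vs, i)
    if (c > 0).any() and not ((c > 0) & nm).sum():
        raise ValueError(
            f"site {vs.positions[i]}: archaic context present but all archaic "
            "haplotypes ungenotyped"
        )
    dcode = 1 if derived_allele == vs.alt[i] else 0
    carriers = (g == dcode) & nm
    in_den = bool((carriers & (c == _CTX_DEN)).any())
    in_nea = bool((carriers & (c == _CTX_NEA)).any())
    if not (in_den or in_nea):
        return {"ancestry": NONARCHAIC, "dual": False, "mia": ""}

    arch = (c > 0) & nm
    n_alt = int((g[arch] == 1).sum())
    n_ref = int(arch.sum() - n_alt)
    if n_alt > n_ref:
        mia = vs.alt[i]
    elif n_ref > n_alt:
        mia = vs.ref[i]
    else:
        mia = vs.alt[i]  # tie broken toward alt
    mcode = 1 if mia == vs.alt[i] else 0

    if in_den != in_nea:
        return {
            "ancestry": DENISOVAN if in_den else NEANDERTHAL,
            "dual": False,
            "mia": mia,
        }

    den_haps = (c == _CTX_DEN) & nm
    nea_haps = (c == _CTX_NEA) & nm
    k_den, n_den = int((g[den_haps] == mcode).sum()), int(den_haps.sum())
    k_nea, n_nea = int((g[nea_haps] == mcode).sum()), int(nea_haps.sum())
    # strict comparison of k_den/n_den vs k_nea/n_nea without float ties
    lhs, rhs = k_den * n_nea, k_nea * n_den
    if lhs > rhs:
        return {"ancestry": DENISOVAN, "dual": True, "mia": mia}
    if rhs > lhs:
        return {"ancestry": NEANDERTHAL, "dual": True, "mia": mia}
    if altai_row is not None:
        den_match = mia == altai_row[0]
        nea_match = mia == altai_row[1]
        if den_match != nea_match:
            return {
                "ancestry": DENISOVAN if den_match else NEANDERTHAL,
                "dual": True,
                "mia": mia,
            }
    return {"ancestry": AMBIGUOUS, "dual": True, "mia": mia}


def compute_frequencies(vs: VariantSet, i: int, ancestry: str, derived: str, mia: str) -> dict:
    """MIAF / DAF (total-chromosome denominator) and class frequencies
    (class-specific denominators) for one called variant."""
    g, c, nm = _site_arrays(vs, i)
    n_chrom = int(nm.sum())
    if n_chrom == 0:
        return {"excluded": True, "reason": NO_DATA}
    out = {"n_chrom": n_chrom, "excluded": False, "reason": ""}
    if ancestry == NONARCHAIC:
        dcode = 1 if derived == vs.alt[i] else 0
        k = int(((g == dcode) & (c == _CTX_NONE) & nm).sum())
        out.update(
            miaf=np.nan,
            daf=k / n_chrom,
            focal_count=k,
            freq_archaic=np.nan,
            freq_nonarchaic=np.nan,
        )
    else:
        mcode = 1 if mia == vs.alt[i] else 0
        arch = (c > 0) & nm
        non = (c == _CTX_NONE) & nm
        k_arch = int((g[arch] == mcode).sum())
        k_non = int((g[non] == mcode).sum())
        out.update(
            miaf=k_arch / n_chrom,
            daf=np.nan,
            focal_count=k_arch,
            freq_archaic=k_arch / arch.sum() if arch.any() else 0.0,
            freq_nonarchaic=k_non / non.sum() if non.any() else 0.0,
        )
    return out


def frequency_difference_filter(
    calls: pd.DataFrame, min_diff: float = 0.25, abs_diff: bool = False
) -> pd.DataFrame:
    """Mark archaic calls whose archaic-minus-non-archaic class frequency
    difference falls below ``min_diff``.  The difference is signed by
    default: archaic alleles commoner on non-archaic haplotypes (negative
    difference) are removed."""
    calls = calls.copy()
    diff = calls["freq_archaic"] - calls["freq_nonarchaic"]
    if abs_diff:
        diff = diff.abs()
    hit = (
        calls["ancestry"].isin([DENISOVAN, NEANDERTHAL])
        & ~calls["excluded"]
        & (diff < min_diff)
    )
    calls.loc[hit, "excluded"] = True
    calls.loc[hit, "exclusion_reason"] = FREQ_DIFF
    return calls


def outgroup_filter(
    calls: pd.DataFrame, outgroup: pd.DataFrame, max_af: float = 0.005
) -> pd.DataFrame:
    """Remove calls whose focal allele (main introgressed allele for aSNPs,
    derived allele for naSNPs) reaches frequency >= ``max_af`` in the
    outgroup panel.  Alleles absent from the panel count as frequency 0."""
    freqs = {
        (str(r.chrom), int(r.pos), str(r.allele)): float(r.freq)
        for r in outgroup.itertuples(index=False)
    }
    calls = calls.copy()
    focal = np.where(
        calls["ancestry"].isin([DENISOVAN, NEANDERTHAL]),
        calls["main_introgressed_allele"],
        calls["derived_allele"],
    )
    af = np.array(
        [
            freqs.get((str(ch), int(p), str(a)), 0.0)
            for ch, p, a in zip(calls["chrom"], calls["pos"], focal)
        ]
    )
    hit = ~calls["excluded"].to_numpy() & (af >= max_af) & (focal != "")
    calls.loc[hit, "excluded"] = True
    calls.loc[hit, "exclusion_reason"] = OUTGROUP
    return calls


# ---------------------------------------------------------------------------
# cascade


def run_filter_cascade(
    vs: VariantSet,
    ancestral: pd.DataFrame,
    altai: pd.DataFrame,
    outgroup: pd.DataFrame,
    min_freq_diff: float = 0.25,
    max_outgroup_af: float = 0.005,
    abs_diff: bool = False,
):
    """Run the full cascade; returns ``(calls, ledger)``.

    ``calls`` has one row per input variant: every variant lands in exactly
    one terminal bucket (an ancestry call, or an exclusion reason).
    ``ledger`` records the survivor count after each ordered step.
    """
    n0 = len(vs)
    ledger_rows = [("input", n0)]

    excluded: dict[int, str] = {}  # original index -> reason

    multi = (
        vs.multiallelic
        if vs.multiallelic is not None
        else np.zeros(n0, dtype=bool)
    )
    for i in np.flatnonzero(multi):
        excluded[i] = MULTIALLELIC
    ledger_rows.append(("biallelic", n0 - len(excluded)))

    mac = minor_allele_counts(vs.geno)
    for i in np.flatnonzero((mac == 1) & ~multi):
        excluded[i] = SINGLETON
    ledger_rows.append(("singletons_removed", n0 - len(excluded)))

    derived, pol_reason = polarize(vs, ancestral)
    for i in range(n0):
        if i not in excluded and pol_reason[i]:
            excluded[i] = pol_reason[i]
    ledger_rows.append(("polarized", n0 - len(excluded)))

    altai_map = {
        (str(r.chrom), int(r.pos)): (str(r.denisovan_allele), str(r.neanderthal_allele))
        for r in altai.itertuples(index=False)
    } if len(altai) else {}

    rows = []
    for i in range(n0):
        pos = int(vs.positions[i])
        base = {
            "variant_id": f"{vs.chrom}:{pos}",
            "chrom": vs.chrom,
            "pos": pos,
            "ref": vs.ref[i],
            "alt": vs.alt[i],
            "ancestry": "",
            "derived_allele": derived[i] if i not in excluded else "",
            "main_introgressed_allele": "",
            "miaf": np.nan,
            "daf": np.nan,
            "focal_count": -1,
            "n_chrom": -1,
            "freq_archaic": np.nan,
            "freq_nonarchaic": np.nan,
            "freq_class": "",
            "dual": False,
            "excluded": i in excluded,
            "exclusion_reason": excluded.get(i, ""),
        }
        if i in excluded:
            rows.append(base)
            continue
        call = assign_ancestry(vs, i, derived[i], altai_map.get((str(vs.chrom), pos)))
        base["ancestry"] = call["ancestry"]
        base["dual"] = call["dual"]
        base["main_introgressed_allele"] = call["mia"]
        if call["ancestry"] == AMBIGUOUS:
            base["excluded"] = True
            base["exclusion_reason"] = AMBIGUOUS_ANCESTRY
            rows.append(base)
            continue
        freqs = compute_frequencies(vs, i, call["ancestry"], derived[i], call["mia"])
        if freqs["excluded"]:
            base["excluded"] = True
            base["exclusion_reason"] = freqs["reason"]
            rows.append(base)
            continue
        base.update(
            miaf=freqs["miaf"],
            daf=freqs["daf"],
            focal_count=freqs["focal_count"],
            n_chrom=freqs["n_chrom"],
            freq_archaic=freqs["freq_archaic"],
            freq_nonarchaic=freqs["freq_nonarchaic"],
        )
        rows.append(base)

    columns = [
        "variant_id", "chrom", "pos", "ref", "alt", "ancestry", "derived_allele",
        "main_introgressed_allele", "miaf", "daf", "focal_count", "n_chrom",
        "freq_archaic", "freq_nonarchaic", "freq_class", "dual", "excluded",
        "exclusion_reason",
    ]
    calls = pd.DataFrame(rows, columns=columns)
    calls["excluded"] = calls["excluded"].astype(bool)
    ledger_rows.append(("ancestry_assigned", int((~calls["excluded"]).sum())))

    calls = frequency_difference_filter(calls, min_freq_diff, abs_diff)
    ledger_rows.append(("frequency_difference", int((~calls["excluded"]).sum())))

    calls = outgroup_filter(calls, outgroup, max_outgroup_af)
    ledger_rows.append(("outgroup", int((~calls["excluded"]).sum())))

    keep = ~calls["excluded"]
    freq = calls["miaf"].fillna(calls["daf"])
    calls.loc[keep, "freq_class"] = np.where(
        freq[keep] >= 0.05, COMMON_TO_HIGH, LOW
    )
    ledger_rows.append(("frequency_class", int(keep.sum())))

    ledger = pd.DataFrame(ledger_rows, columns=["step", "retained"])
    return calls, ledger


def dual_site_partition(calls: pd.DataFrame) -> dict:
    """Counts of dual-ancestry sites resolved to each bucket; the three
    buckets partition the dual-site total exactly."""
    dual = calls[calls["dual"]]
    return {
        DENISOVAN: int((dual["ancestry"] == DENISOVAN).sum()),
        NEANDERTHAL: int((dual["ancestry"] == NEANDERTHAL).sum()),
        AMBIGUOUS: int((dual["ancestry"] == AMBIGUOUS).sum()),
        "total": int(len(dual)),
    }
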