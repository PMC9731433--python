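"""Simulate a phased diploid cohort carrying labelled archaic haplotype tracts.

The generator works at the level of *tract loci*: a tract locus is a genomic
interval introgressed from one archaic ancestry and shared identically by a
set of carrier haplotypes (introgressed segments are inherited as blocks, so
carriers of the same segment share its boundaries).  Introgressed alleles are
then planted on the carriers of a locus, which realises the configured
introgressed-allele-count spectrum; non-archaic derived alleles are placed on
haplotypes outside any tract at their site, following a neutral 1/i spectrum.

Dual-ancestry sites (alleles segregating in tracts of both ancestries, the
product of incomplete lineage sorting) are planted at intersections of a
Denisovan and a Neanderthal locus; a configurable fraction of them are exact
frequency ties whose ancestry is only resolvable through the Altai reference
genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    ARCHAIC_ANCESTRIES,
    DENISOVAN,
    NEANDERTHAL,
    NONARCHAIC,
    CohortConfig,
)

BASES = np.array(["A", "C", "G", "T"])


@dataclass
class TractLocus:
    ancestry: str
    start: int  # 0-based, half-open
    end: int
    carriers: np.ndarray  # global haplotype indices


@dataclass
class CohortData:
    """In-memory result of :func:`simulate_cohort`.

    ``geno`` is an (n_sites, n_haplotypes) int8 matrix with 0 = ref,
    1 = alt, -1 = missing; haplotype ``2*i + j`` is haplotype ``j`` of
    sample ``i``.  ``truth`` carries one row per emitted variant with its
    planted ancestry label and allele count.
    """

    config: CohortConfig
    chrom: str
    chrom_length: int
    samples: list
    positions: np.ndarray  # 1-based
    ref: np.ndarray
    alt: np.ndarray
    geno: np.ndarray
    tracts: pd.DataFrame
    ancestral: pd.DataFrame
    altai: pd.DataFrame
    outgroup: pd.DataFrame
    truth: pd.DataFrame
    loci: list = field(default_factory=list, repr=False)

    @property
    def n_haplotypes(self) -> int:
        return len(self.samples) * 2

    def variant_ids(self) -> np.ndarray:
        return np.array([f"{self.chrom}:{p}" for p in self.positions])

    def write(self, outdir) -> None:
        from .. import io

        io.write_cohort(self, outdir)


def _normalize_spectrum(spectrum: dict | None, n_chrom: int) -> tuple[np.ndarray, np.ndarray]:
    if spectrum is None:
        counts = np.arange(2, n_chrom // 2 + 1)
        weights = 1.0 / counts
    else:
        counts = np.array(sorted(spectrum), dtype=int)
        weights = np.array([spectrum[c] for c in counts], dtype=float)
    return counts, weights / weights.sum()


def _simulate_loci(cfg: CohortConfig, rng: np.random.Generator) -> list[TractLocus]:
    n_hap = cfg.n_chromosomes
    counts, probs = _normalize_spectrum(cfg.miaf_spectrum, n_hap)
    mean_carriers = float(counts @ probs)
    loci: list[TractLocus] = []
    for ancestry in ARCHAIC_ANCESTRIES:
        coverage = cfg.ancestry_mix.get(ancestry, 0.0)
        if coverage == 0.0:
            continue
        n_loci = max(
            1,
            int(round(coverage * cfg.chrom_length * n_hap / (cfg.tract_mean_len * mean_carriers))),
        )
        for _ in range(n_loci):
            length = max(1000, int(rng.exponential(cfg.tract_mean_len)))
            start = int(rng.integers(0, max(1, cfg.chrom_length - length)))
            c = int(rng.choice(counts, p=probs))
            carriers = rng.choice(n_hap, size=c, replace=False)
            loci.append(TractLocus(ancestry, start, min(start + length, cfg.chrom_length), np.sort(carriers)))
    return loci


def _covered_haps(loci: list[TractLocus], pos: int) -> dict[str, set]:
    """Haplotypes covered by a tract of each ancestry at 1-based ``pos``.

    A haplotype carrying overlapping tracts of both ancestries keeps the
    Denisovan label (first-listed ancestry wins; such conflicts are rare by
    construction)."""
    out: dict[str, set] = {a: set() for a in ARCHAIC_ANCESTRIES}
    for locus in loci:
        if locus.start < pos <= locus.end:
            out[locus.ancestry].update(locus.carriers.tolist())
    conflict = out[DENISOVAN] & out[NEANDERTHAL]
    out[NEANDERTHAL] -= conflict
    return out


def simulate_cohort(config: CohortConfig) -> CohortData:
    """Generate genotypes, tracts, ancestral/Altai/outgroup tables and truth."""
    rng = np.random.default_rng(config.seed)
    n_hap = config.n_chromosomes
    loci = _simulate_loci(config, rng)
    den_loci = [l for l in loci if l.ancestry == DENISOVAN]
    nea_loci = [l for l in loci if l.ancestry == NEANDERTHAL]

    n_archaic = int(round(config.archaic_site_fraction * config.n_sites))
    n_dual = int(round(config.dual_site_fraction * n_archaic))
    mix = config.ancestry_mix
    total_mix = sum(mix.values()) or 1.0
    n_den = int(round((n_archaic - n_dual) * mix.get(DENISOVAN, 0.0) / total_mix))
    n_nea = n_archaic - n_dual - n_den
    n_na = config.n_sites - n_archaic

    used_pos: set[int] = set()
    records: list[dict] = []
    geno_rows: list[np.ndarray] = []

    def new_pos(lo: int, hi: int) -> int:
        # 1-based position in [lo, hi], unique across sites
        for _ in range(1000):
            p = int(rng.integers(lo, hi + 1))
            if p not in used_pos:
                used_pos.add(p)
                return p
        raise RuntimeError("could not place a unique variant position")

    def weighted_locus(pool: list[TractLocus]) -> TractLocus:
        lengths = np.array([l.end - l.start for l in pool], dtype=float)
        return pool[int(rng.choice(len(pool), p=lengths / lengths.sum()))]

    def plant(pos, carriers_alt, ancestry, true_count, dual=False, tie=False):
        row = np.zeros(n_hap, dtype=np.int8)
        row[list(carriers_alt)] = 1
        geno_rows.append(row)
        records.append(
            {
                "pos": pos,
                "true_ancestry": ancestry,
                "true_count": true_count,
                "dual": dual,
                "tie": tie,
                "bg_leak": False,
            }
        )

    # --- single-ancestry archaic sites ------------------------------------
    for ancestry, n_sites_a, pool in (
        (DENISOVAN, n_den, den_loci),
        (NEANDERTHAL, n_nea, nea_loci),
    ):
        for _ in range(n_sites_a):
            locus = weighted_locus(pool)
            pos = new_pos(locus.start + 1, locus.end)
            k = len(locus.carriers)
            if k > 2 and rng.random() < 0.3:
                k = int(rng.integers(2, len(locus.carriers)))
            carriers = rng.choice(locus.carriers, size=k, replace=False)
            carriers = set(carriers.tolist())
            plant(pos, carriers, ancestry, len(carriers))
            if config.archaic_background_leak and rng.random() < config.archaic_background_leak:
                # haplotype-calling error: the allele also rides on many
                # non-archaic haplotypes, defeating the frequency contrast
                covered = set().union(*_covered_haps(loci, pos).values())
                eligible = sorted(set(range(n_hap)) - covered)
                n_extra = min(len(eligible), int(0.6 * n_hap))
                extra = rng.choice(eligible, size=n_extra, replace=False)
                geno_rows[-1][extra] = 1
                records[-1]["bg_leak"] = True
                records[-1]["true_count"] = int(geno_rows[-1].sum())

    # --- dual-ancestry sites ----------------------------------------------
    pairs = [
        (d, n)
        for d in den_loci
        for n in nea_loci
        if d.start < n.end and n.start < d.end
    ]
    for i in range(n_dual):
        if pairs:
            d, n = pairs[int(rng.integers(len(pairs)))]
        else:
            # force an overlap: mirror a Denisovan locus with a Neanderthal
            # one carried by disjoint haplotypes
            d = weighted_locus(den_loci) if den_loci else weighted_locus(nea_loci)
            eligible = sorted(set(range(n_hap)) - set(d.carriers.tolist()))
            c = min(len(eligible), max(2, len(d.carriers)))
            n = TractLocus(NEANDERTHAL, d.start, d.end, np.sort(rng.choice(eligible, c, replace=False)))
            loci.append(n)
            nea_loci.append(n)
            pairs.append((d, n))
        lo, hi = max(d.start, n.start) + 1, min(d.end, n.end)
        pos = new_pos(lo, hi)
        pool_d = set(d.carriers.tolist())
        pool_n = set(n.carriers.tolist()) - pool_d
        if not pool_n:
            continue  # degenerate overlap, skip (rare)
        tie = rng.random() < config.dual_tie_fraction
        truth = DENISOVAN if rng.random() < mix.get(DENISOVAN, 0.0) / total_mix else NEANDERTHAL
        if tie:
            carriers = pool_d | pool_n
        else:
            win, lose = (pool_d, pool_n) if truth == DENISOVAN else (pool_n, pool_d)
            k_lose = max(0, min(len(lose) - 1, len(lose) // 2))
            carriers = set(win)
            if k_lose:
                carriers |= set(rng.choice(sorted(lose), size=k_lose, replace=False).tolist())
        plant(pos, carriers, truth, len(carriers), dual=True, tie=tie)

    # --- non-archaic sites -------------------------------------------------
    na_counts = np.arange(1, n_hap)
    na_probs = (1.0 / na_counts) / (1.0 / na_counts).sum()
    for _ in range(n_na):
        pos = None
        for _ in range(50):
            cand = new_pos(1, config.chrom_length)
            covered = set().union(*_covered_haps(loci, cand).values())
            eligible = sorted(set(range(n_hap)) - covered)
            if len(eligible) >= 2:
                pos = cand
                break
            used_pos.discard(cand)
        if pos is None:  # pathological coverage; place anyway
            pos = new_pos(1, config.chrom_length)
            covered = set().union(*_covered_haps(loci, pos).values())
            eligible = sorted(set(range(n_hap)) - covered) or [0, 1]
        k = min(len(eligible), int(rng.choice(na_counts, p=na_probs)))
        carriers = set(rng.choice(eligible, size=max(1, k), replace=False).tolist())
        plant(pos, carriers, NONARCHAIC, len(carriers))

    # --- assemble, sorted by position --------------------------------------
    order = np.argsort([r["pos"] for r in records], kind="mergesort")
    records = [records[i] for i in order]
    geno = np.array([geno_rows[i] for i in order], dtype=np.int8)
    positions = np.array([r["pos"] for r in records], dtype=np.int64)

    ref_idx = rng.integers(0, 4, size=len(records))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(records))) % 4
    ref = BASES[ref_idx]
    alt = BASES[alt_idx]

    samples = [f"PAP{i + 1:03d}" for i in range(config.n_individuals)]

    tract_rows = [
        {
            "chrom": config.chrom,
            "start": locus.start,
            "end": locus.end,
            "sample": samples[h // 2],
            "hap_index": h % 2,
            "ancestry": locus.ancestry,
        }
        for locus in loci
        for h in locus.carriers
    ]
    tracts = pd.DataFrame(tract_rows).sort_values(
        ["start", "end", "sample", "hap_index"], kind="mergesort"
    ).reset_index(drop=True)

    # ancestral-state table (emulating a primate-alignment call set)
    anc_rows = []
    for i, r in enumerate(records):
        u = rng.random()
        if u < config.ancestral_missing_rate:
            continue
        if u < config.ancestral_missing_rate + config.ancestral_mismatch_rate:
            allele = BASES[(ref_idx[i] + alt_idx[i]) % 4]
            if allele in (ref[i], alt[i]):  # pick a base that is neither
                allele = next(b for b in BASES if b not in (ref[i], alt[i]))
        else:
            allele = ref[i]
        anc_rows.append({"chrom": config.chrom, "pos": r["pos"], "allele": allele})
    ancestral = pd.DataFrame(anc_rows)

    altai_rows = []
    for i, r in enumerate(records):
        if r["true_ancestry"] == NONARCHAIC:
            continue
        den = alt[i] if r["true_ancestry"] == DENISOVAN else ref[i]
        nea = alt[i] if r["true_ancestry"] == NEANDERTHAL else ref[i]
        altai_rows.append(
            {"chrom": config.chrom, "pos": r["pos"], "denisovan_allele": den, "neanderthal_allele": nea}
        )
    altai = pd.DataFrame(altai_rows)

    out_rows = []
    leak_flags = []
    for i, r in enumerate(records):
        leaked = (
            r["true_ancestry"] != NONARCHAIC
            and rng.random() < config.outgroup_leak_rate
        )
        leak_flags.append(leaked)
        alt_freq = float(rng.uniform(0.005, 0.05)) if leaked else 0.0
        out_rows.append(
            {"chrom": config.chrom, "pos": r["pos"], "allele": ref[i], "freq": round(1.0 - alt_freq, 6)}
        )
        if alt_freq > 0:
            out_rows.append(
                {"chrom": config.chrom, "pos": r["pos"], "allele": alt[i], "freq": round(alt_freq, 6)}
            )
    outgroup = pd.DataFrame(out_rows)

    truth = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": positions,
            "ref": ref,
            "alt": alt,
            "true_ancestry": [r["true_ancestry"] for r in records],
            "true_count": [r["true_count"] for r in records],
            "dual": [r["dual"] for r in records],
            "tie": [r["tie"] for r in records],
            "bg_leak": [r["bg_leak"] for r in records],
            "outgroup_leaked": leak_flags,
        }
    )
    truth["variant_id"] = truth["chrom"] + ":" + truth["pos"].astype(str)

    return CohortData(
        config=config,
        chrom=config.chrom,
        chrom_length=config.chrom_length,
        samples=samples,
        positions=positions,
        ref=ref,
        alt=alt,
        geno=geno,
        tracts=tracts,
        ancestral=ancestral,
        altai=altai,
        outgroup=outgroup,
        truth=truth,
        loci=loci,
    )
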