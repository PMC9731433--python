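"""Classification cascade: rule-level examples plus a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from introcre import variantfilter as vf
from introcre.synthdata import AMBIGUOUS, DENISOVAN, NEANDERTHAL, NONARCHAIC

from conftest import ancestral_table, make_variant_set


class TestSingletons:
    def test_singleton_removed_doubleton_retained(self):
        geno = np.zeros((3, 112), dtype=np.int8)
        geno[0, 0] = 1          # alt count 1 -> removed
        geno[1, :2] = 1         # alt count 2 -> retained
        geno[2, 1:] = 1         # ref count 1 -> removed (minor allele)
        vs = make_variant_set(geno, np.zeros_like(geno))
        out = vf.remove_singletons(vs)
        assert list(out.positions) == [2]

    def test_missing_genotypes_do_not_count(self):
        geno = np.zeros((1, 8), dtype=np.int8)
        geno[0, :2] = 1
        geno[0, 2] = -1
        vs = make_variant_set(geno, np.zeros_like(geno))
        assert len(vf.remove_singletons(vs)) == 1  # minor count 2


class TestPolarize:
    def test_rules(self):
        geno = np.zeros((3, 4), dtype=np.int8)
        vs = make_variant_set(geno, np.zeros_like(geno), ref=["A"] * 3, alt=["G"] * 3)
        anc = pd.DataFrame(
            {"chrom": "1", "pos": [1, 3], "allele": ["A", "T"]}  # pos 2 missing
        )
        derived, reason = vf.polarize(vs, anc)
        assert derived[0] == "G" and reason[0] == ""
        assert reason[1] == vf.NO_ANCESTRAL
        assert reason[2] == vf.ANCESTRAL_MISMATCH

    def test_ancestral_equal_alt_polarizes_to_ref(self):
        geno = np.zeros((1, 4), dtype=np.int8)
        vs = make_variant_set(geno, np.zeros_like(geno), ref=["A"], alt=["G"])
        derived, reason = vf.polarize(vs, ancestral_table(vs, alleles=["G"]))
        assert derived[0] == "A" and reason[0] == ""


class TestAssignAncestry:
    def _vs(self, geno, ctx):
        return make_variant_set(np.array([geno]), np.array([ctx]))

    def test_single_context(self):
        vs = self._vs([1, 1, 0, 0], [1, 1, 0, 0])
        call = vf.assign_ancestry(vs, 0, "G", None)
        assert call["ancestry"] == DENISOVAN and not call["dual"]

    def test_no_archaic_carrier_is_nonarchaic(self):
        # tracts cover the site but no covered haplotype carries the derived allele
        vs = self._vs([0, 0, 1, 1], [1, 2, 0, 0])
        assert vf.assign_ancestry(vs, 0, "G", None)["ancestry"] == NONARCHAIC

    def test_dual_resolved_by_class_frequency(self):
        # Denisovan-class haps: 4/5 carry alt; Neanderthal-class: 1/3
        geno = [1, 1, 1, 1, 0] + [1, 0, 0] + [0, 0]
        ctx = [1] * 5 + [2] * 3 + [0, 0]
        call = vf.assign_ancestry(self._vs(geno, ctx), 0, "G", None)
        assert call["ancestry"] == DENISOVAN and call["dual"]

    def test_dual_tie_resolved_by_altai_then_ambiguous(self):
        geno = [1, 1, 1, 1, 0, 0]
        ctx = [1, 1, 2, 2, 0, 0]  # both class frequencies 1.0
        vs = self._vs(geno, ctx)
        nea = vf.assign_ancestry(vs, 0, "G", ("A", "G"))  # alt matches Altai Nean only
        assert nea["ancestry"] == NEANDERTHAL
        both = vf.assign_ancestry(vs, 0, "G", ("G", "G"))  # matches both
        assert both["ancestry"] == AMBIGUOUS
        neither = vf.assign_ancestry(vs, 0, "G", None)  # no Altai data
        assert neither["ancestry"] == AMBIGUOUS

    def test_all_archaic_haps_missing_raises(self):
        vs = self._vs([-1, 1, 0], [1, 0, 0])
        with pytest.raises(ValueError):
            vf.assign_ancestry(vs, 0, "G", None)


class TestFrequencies:
    def test_miaf_uses_total_chromosome_denominator(self):
        # 10 archaic haplotypes all alt, 112 chromosomes total
        geno = np.zeros((1, 112), dtype=np.int8)
        geno[0, :10] = 1
        ctx = np.zeros((1, 112), dtype=np.int8)
        ctx[0, :10] = 1
        vs = make_variant_set(geno, ctx)
        out = vf.compute_frequencies(vs, 0, DENISOVAN, "G", "G")
        assert out["miaf"] == pytest.approx(10 / 112)
        assert out["freq_archaic"] == 1.0
        assert out["freq_nonarchaic"] == 0.0

    def test_daf_counts_derived_in_nonarchaic_haps_only(self):
        geno = np.zeros((1, 112), dtype=np.int8)
        geno[0, :6] = 1     # six derived copies outside tracts
        geno[0, 110] = 1    # one inside a tract: not counted in DAF
        ctx = np.zeros((1, 112), dtype=np.int8)
        ctx[0, 110] = 2
        vs = make_variant_set(geno, ctx)
        out = vf.compute_frequencies(vs, 0, NONARCHAIC, "G", "")
        assert out["daf"] == pytest.approx(6 / 112)

    def test_all_missing_is_no_data(self):
        geno = np.full((1, 4), -1, dtype=np.int8)
        vs = make_variant_set(geno, np.zeros_like(geno))
        out = vf.compute_frequencies(vs, 0, NONARCHAIC, "G", "")
        assert out["excluded"] and out["reason"] == vf.NO_DATA


def _calls_frame(freq_archaic, freq_nonarchaic):
    return pd.DataFrame(
        {
            "ancestry": [DENISOVAN],
            "freq_archaic": [freq_archaic],
            "freq_nonarchaic": [freq_nonarchaic],
            "excluded": [False],
            "exclusion_reason": [""],
        }
    )


class TestFrequencyDifferenceFilter:
    @pytest.mark.parametrize(
        "fa,fn,kept",
        [
            (0.60, 0.36, False),  # diff 0.24: below threshold
            (0.60, 0.35, True),   # diff exactly 0.25: kept
            (0.30, 0.60, False),  # negative signed difference: removed
        ],
    )
    def test_signed_threshold(self, fa, fn, kept):
        out = vf.frequency_difference_filter(_calls_frame(fa, fn))
        assert bool(~out["excluded"][0]) is kept

    def test_abs_diff_flag_rescues_negative(self):
        out = vf.frequency_difference_filter(_calls_frame(0.30, 0.60), abs_diff=True)
        assert not out["excluded"][0]

    def test_nonarchaic_passes_through(self):
        calls = _calls_frame(0.0, 0.0)
        calls["ancestry"] = NONARCHAIC
        assert not vf.frequency_difference_filter(calls)["excluded"][0]


class TestOutgroupFilter:
    def _calls(self):
        return pd.DataFrame(
            {
                "chrom": ["1"] * 3,
                "pos": [10, 20, 30],
                "ancestry": [DENISOVAN, DENISOVAN, NONARCHAIC],
                "main_introgressed_allele": ["G", "G", ""],
                "derived_allele": ["", "", "T"],
                "excluded": [False] * 3,
                "exclusion_reason": [""] * 3,
            }
        )

    def test_inclusive_boundary_and_absence(self):
        outgroup = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "pos": [10, 20],
                "allele": ["G", "G"],
                "freq": [0.005, 0.0049],
            }
        )
        out = vf.outgroup_filter(self._calls(), outgroup)
        assert out["excluded"].tolist() == [True, False, False]
        assert out["exclusion_reason"].tolist() == [vf.OUTGROUP, "", ""]


# ---------------------------------------------------------------------------
# whole-cascade properties


def naive_recount(cohort):
    """Independent per-site recount of frequencies for the oracle check."""
    from introcre.variantfilter import build_context

    ctx = build_context(cohort.positions, cohort.tracts, cohort.samples)
    anc = {int(r.pos): r.allele for r in cohort.ancestral.itertuples(index=False)}
    out = {}
    for i, pos in enumerate(cohort.positions):
        g = cohort.geno[i]
        alleles = [cohort.ref[i] if x == 0 else cohort.alt[i] for x in g if x >= 0]
        n = len(alleles)
        a = anc.get(int(pos))
        if a is None or a not in (cohort.ref[i], cohort.alt[i]):
            continue
        derived = cohort.alt[i] if a == cohort.ref[i] else cohort.ref[i]
        arch_alleles = [
            (cohort.ref[i] if g[h] == 0 else cohort.alt[i])
            for h in range(len(g))
            if ctx[i, h] > 0 and g[h] >= 0
        ]
        non_alleles = [
            (cohort.ref[i] if g[h] == 0 else cohort.alt[i])
            for h in range(len(g))
            if ctx[i, h] == 0 and g[h] >= 0
        ]
        rec = {"daf": non_alleles.count(derived) / n}
        if arch_alleles:
            n_alt = arch_alleles.count(cohort.alt[i])
            n_ref = len(arch_alleles) - n_alt
            mia = cohort.alt[i] if n_alt >= n_ref else cohort.ref[i]
            rec.update(
                miaf=arch_alleles.count(mia) / n,
                freq_archaic=arch_alleles.count(mia) / len(arch_alleles),
                freq_nonarchaic=(
                    non_alleles.count(mia) / len(non_alleles) if non_alleles else 0.0
                ),
            )
        out[int(pos)] = rec
    return out


class TestCascade:
    def test_frequencies_match_bruteforce_recount(self, messy_cohort, messy_calls):
        calls, _ = messy_calls
        oracle = naive_recount(messy_cohort)
        checked = 0
        for row in calls.itertuples(index=False):
            o = oracle.get(row.pos)
            if o is None or row.excluded and row.exclusion_reason not in (
                vf.FREQ_DIFF,
                vf.OUTGROUP,
            ):
                continue
            if row.ancestry in (DENISOVAN, NEANDERTHAL):
                if "miaf" not in o:
                    continue  # oracle had no archaic-context haps; rule differs
                assert row.miaf == pytest.approx(o["miaf"])
                assert row.freq_archaic == pytest.approx(o["freq_archaic"])
                assert row.freq_nonarchaic == pytest.approx(o["freq_nonarchaic"])
                checked += 1
            elif row.ancestry == NONARCHAIC:
                assert row.daf == pytest.approx(o["daf"])
                checked += 1
        assert checked > 100

    def test_every_variant_in_exactly_one_terminal_bucket(self, messy_calls):
        calls, ledger = messy_calls
        excluded = calls["excluded"]
        assert ((calls["exclusion_reason"] != "") == excluded).all()
        assert (calls.loc[~excluded, "ancestry"] != "").all()
        # ledger is monotone non-increasing and consistent with the frame
        assert (np.diff(ledger["retained"]) <= 0).all()
        assert ledger["retained"].iloc[0] == len(calls)
        assert ledger["retained"].iloc[-1] == int((~excluded).sum())

    def test_frequency_times_chromosomes_is_integer(self, messy_calls):
        calls, _ = messy_calls
        kept = calls[~calls["excluded"]]
        freq = kept["miaf"].fillna(kept["daf"])
        prod = freq * kept["n_chrom"]
        assert np.allclose(prod, np.round(prod))

    def test_dual_partition_closure(self, messy_calls):
        calls, _ = messy_calls
        part = vf.dual_site_partition(calls)
        assert (
            part[DENISOVAN] + part[NEANDERTHAL] + part[AMBIGUOUS] == part["total"]
        )

    def test_classification_accuracy_on_clean_cohort(self, clean_cohort, clean_calls):
        calls, _ = clean_calls
        merged = calls.merge(
            clean_cohort.truth[["variant_id", "true_ancestry"]], on="variant_id"
        )
        kept = merged[~merged["excluded"]]
        acc = (kept["ancestry"] == kept["true_ancestry"]).mean()
        assert acc >= 0.95
        assert len(kept) > 400

    def test_empty_input(self):
        vs = make_variant_set(
            np.zeros((0, 4), dtype=np.int8), np.zeros((0, 4), dtype=np.int8)
        )
        calls, ledger = vf.run_filter_cascade(
            vs,
            pd.DataFrame(columns=["chrom", "pos", "allele"]),
            pd.DataFrame(columns=["chrom", "pos", "denisovan_allele", "neanderthal_allele"]),
            pd.DataFrame(columns=["chrom", "pos", "allele", "freq"]),
        )
        assert len(calls) == 0
        assert (ledger["retained"] == 0).all()
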