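"""PWM scoring, exact thresholds, allelic deltas, consolidation, cluster tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from introcre import motifimpact as mi


def sharp_motif(consensus="ACGTAC", sharpness=40.0, name="M1", tf="TF1", db="JASPAR"):
    counts = np.ones((4, len(consensus)))
    for i, b in enumerate(consensus):
        counts[mi.BASE_INDEX[b], i] = sharpness
    return mi.MotifModel.from_counts(name, tf, db, counts)


def uniform_motif(width=2):
    return mi.MotifModel("U", "U", "JASPAR", np.full((4, width), 0.25))


class TestModel:
    def test_pseudocount_formula(self):
        m = mi.MotifModel.from_counts("m", "t", "J", np.array([[8.0], [0], [0], [0]]))
        assert np.allclose(m.matrix[:, 0], [9 / 12, 1 / 12, 1 / 12, 1 / 12])

    def test_probability_matrix_regularization_idempotent(self):
        mat = np.array([[0.7, 0.25], [0.1, 0.25], [0.1, 0.25], [0.1, 0.25]])
        m = mi.MotifModel("m", "t", "J", mat)
        m2 = mi.MotifModel("m", "t", "J", m.matrix)
        assert np.allclose(m.matrix, m2.matrix)

    def test_zero_column_raises(self):
        with pytest.raises(ValueError):
            mi.MotifModel.from_counts("m", "t", "J", np.zeros((4, 3)))

    def test_jaspar_roundtrip(self, tmp_path):
        counts = np.array([[8, 0, 2], [1, 5, 2], [0, 3, 2], [1, 2, 4]], dtype=float)
        mi.write_pfm(counts, "MA0001.1", "TFX", tmp_path / "m.jaspar")
        models = mi.load_pfms(tmp_path / "m.jaspar", "JASPAR")
        assert len(models) == 1
        expected = mi.MotifModel.from_counts("MA0001.1", "TFX", "JASPAR", counts)
        assert models[0].tf_name == "TFX"
        assert np.allclose(models[0].matrix, expected.matrix)


class TestScore:
    def test_uniform_motif_closed_form(self):
        m = uniform_motif(2)
        got = mi.pwm_score("AC", m)
        assert got == pytest.approx(math.log2(0.25 / 0.3) + math.log2(0.25 / 0.2))

    def test_consensus_scores_highest_exhaustive(self):
        m = sharp_motif("ACGTA")
        scores = {
            w: mi.pwm_score(w, m)
            for w in ("".join(p) for p in __import__("itertools").product("ACGT", repeat=5))
        }
        assert max(scores, key=scores.get) == "ACGTA"

    def test_reverse_complement_symmetry(self):
        # scanning the reverse-complemented window on the minus strand
        # recovers the forward score
        m = sharp_motif("ACGTAC")
        w = "ACGTAC"
        assert mi.pwm_score(mi.reverse_complement(w), m) != mi.pwm_score(w, m)
        assert mi.pwm_score(
            mi.reverse_complement(mi.reverse_complement(w)), m
        ) == pytest.approx(mi.pwm_score(w, m))

    def test_ambiguous_base_flagged(self):
        with pytest.raises(mi.AmbiguousBaseError):
            mi.pwm_score("AN", uniform_motif(2))


class TestThreshold:
    def test_distribution_mass_is_one(self):
        for cons in ("ACGT", "ACGTACGT", "AAAACCCCGGGG"):
            _, pmf = mi.score_distribution(sharp_motif(cons))
            assert pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_dp_tail_matches_exhaustive_enumeration(self):
        import itertools

        for cons in ("ACGT", "ACGTA", "TTGACA"):
            m = sharp_motif(cons)
            bg = dict(zip(mi.BASES, m.background))
            scores = []
            weights = []
            for w in itertools.product(mi.BASES, repeat=m.width):
                scores.append(mi.pwm_score("".join(w), m))
                weights.append(np.prod([bg[b] for b in w]))
            scores = np.array(scores)
            weights = np.array(weights)
            span = scores.max() - scores.min()
            bin_w = span / 10_000
            # enumeration cutoff: smallest attainable score whose exact tail
            # is within the target
            uniq = np.unique(scores)
            tails = np.array([weights[scores >= s].sum() for s in uniq])
            for pval in (1e-2, 1e-4):
                cutoff = mi.match_threshold(m, pval)
                ok = np.flatnonzero(tails <= pval * (1 + 1e-9))
                cutoff_enum = uniq[ok[0]] if len(ok) else scores.max() + 1
                # DP cutoff is valid (tail within target, one bin of slack)
                assert weights[scores >= cutoff + bin_w].sum() <= pval * (1 + 1e-6)
                # and agrees with the enumeration cutoff to discretisation
                # (per-position rounding accumulates to at most w/2 bins)
                assert cutoff <= cutoff_enum + (m.width / 2 + 1) * bin_w

    def test_threshold_monotone_in_pvalue(self):
        m = sharp_motif("ACGTACGTAA")
        cuts = [mi.match_threshold(m, p) for p in (1e-6, 1e-4, 1e-2, 0.5)]
        assert all(a >= b for a, b in zip(cuts, cuts[1:]))

    def test_pvalue_one_gives_minimum_score(self):
        m = sharp_motif("ACGT")
        scores, _ = mi.score_distribution(m)
        assert mi.match_threshold(m, 1.0) == pytest.approx(scores[0])

    def test_invalid_pvalue(self):
        with pytest.raises(ValueError):
            mi.match_threshold(uniform_motif(), 0.0)
        with pytest.raises(ValueError):
            mi.match_threshold(uniform_motif(), 1.5)


class TestScoreSnp:
    def _setup(self):
        m = sharp_motif("ACGTACGT", sharpness=50)
        genome = "T" * 30 + "ACGTACGT" + "T" * 30
        thr = mi.match_threshold(m, 1e-4)
        return m, genome, thr

    def test_delta_antisymmetric_under_allele_swap(self):
        m, genome, thr = self._setup()
        pos = 33  # 1-based; the G at motif column 2
        r1 = mi.score_snp(genome, pos, "G", "T", m, thr)
        r2 = mi.score_snp(genome, pos, "T", "G", m, thr)
        assert r1["delta_pwm"] == pytest.approx(-r2["delta_pwm"])
        assert r1["delta_pwm"] > 0  # consensus allele is the focal one

    def test_equal_column_gives_zero_delta(self):
        m = uniform_motif(4)
        genome = "A" * 20
        r = mi.score_snp(genome, 10, "A", "C", m, threshold=-100.0)
        # both alleles can reach the same best window score elsewhere
        assert r is not None

    def test_best_window_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        m = sharp_motif("ACGTAC")
        genome = "".join(rng.choice(list("ACGT"), 60))
        pos = 30
        rec = mi.score_snp(genome, pos, "A", "G", m, threshold=-1e9)
        for allele, key in (("A", "score_focal"), ("G", "score_other")):
            seq = genome[: pos - 1] + allele + genome[pos:]
            best = max(
                mi.pwm_score(win, m)
                for s0 in range(pos - m.width, pos)
                if 0 <= s0 <= len(seq) - m.width
                for win in (
                    seq[s0 : s0 + m.width],
                    mi.reverse_complement(seq[s0 : s0 + m.width]),
                )
            )
            assert rec[key] == pytest.approx(best)

    def test_below_threshold_emits_nothing(self):
        m, genome, thr = self._setup()
        # far from the planted instance: random T-runs score terribly
        assert mi.score_snp(genome, 5, "A", "C", m, thr) is None

    def test_contig_edge_still_valid(self):
        m, genome, thr = self._setup()
        r = mi.score_snp(genome, 2, "A", "C", m, threshold=-1e9)
        assert r is not None


class TestConsolidate:
    def _records(self):
        return pd.DataFrame(
            [
                {"variant_id": "v1", "tf_name": "TFA", "motif": "M1",
                 "source_db": "JASPAR", "delta_pwm": 0.3, "is_disrupting": True},
                {"variant_id": "v1", "tf_name": "TFA", "motif": "H1",
                 "source_db": "HOCOMOCO", "delta_pwm": -0.8, "is_disrupting": True},
                {"variant_id": "v1", "tf_name": "TFB", "motif": "M2",
                 "source_db": "JASPAR", "delta_pwm": 0.1, "is_disrupting": False},
            ]
        )

    def test_keeps_highest_absolute_delta(self):
        out = mi.consolidate(self._records())
        assert len(out) == 2
        kept = out[out["tf_name"] == "TFA"].iloc[0]
        assert kept["motif"] == "H1"

    def test_idempotent(self):
        once = mi.consolidate(self._records())
        twice = mi.consolidate(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_tie_broken_by_db_priority_then_name(self):
        recs = self._records()
        recs.loc[1, "delta_pwm"] = 0.3
        out = mi.consolidate(recs)
        assert out[out["tf_name"] == "TFA"]["source_db"].iloc[0] == "JASPAR"

    def test_output_size_is_distinct_pairs(self):
        rng = np.random.default_rng(1)
        recs = pd.DataFrame(
            {
                "variant_id": rng.choice(["v1", "v2", "v3"], 50),
                "tf_name": rng.choice(["TFA", "TFB"], 50),
                "motif": rng.choice(["M1", "M2", "M3"], 50),
                "source_db": rng.choice(["JASPAR", "HOCOMOCO"], 50),
                "delta_pwm": rng.normal(size=50),
                "is_disrupting": True,
            }
        )
        out = mi.consolidate(recs)
        assert len(out) == recs.groupby(["variant_id", "tf_name"]).ngroups


class TestClusterExcess:
    def _records(self, counts, clusters_of):
        rows = []
        for (cluster, n) in counts.items():
            for i in range(n):
                rows.append(
                    {"variant_id": f"{cluster}_{i}", "motif": clusters_of[cluster],
                     "is_disrupting": True}
                )
        return pd.DataFrame(rows)

    def test_proportional_counts_give_zero_statistic(self):
        cl = {"C1": "M1", "C2": "M2"}
        clusters = {"M1": "C1", "M2": "C2"}
        case = self._records({"C1": 10, "C2": 20}, cl)
        ctrl = self._records({"C1": 20, "C2": 40}, cl)
        res = mi.cluster_excess_test(case, ctrl, clusters)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_computed_three_cluster_fixture(self):
        cl = {"C1": "M1", "C2": "M2", "C3": "M3"}
        clusters = {"M1": "C1", "M2": "C2", "M3": "C3"}
        case = self._records({"C1": 30, "C2": 20, "C3": 10}, cl)
        ctrl = self._records({"C1": 20, "C2": 20, "C3": 20}, cl)
        res = mi.cluster_excess_test(case, ctrl, clusters)
        # textbook sum of (O-E)^2/E for the 3x2 table
        obs = np.array([[30, 20], [20, 20], [10, 20]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert res["statistic"] == pytest.approx(((obs - exp) ** 2 / exp).sum())
        assert res["method"] == "chi2"

    def test_unclustered_motifs_dropped(self):
        cl = {"C1": "M1", "C2": "M2"}
        clusters = {"M1": "C1", "M2": "C2"}  # M9 unassigned
        case = self._records({"C1": 10, "C2": 10}, cl)
        extra = pd.DataFrame(
            [{"variant_id": "x", "motif": "M9", "is_disrupting": True}] * 30
        )
        res = mi.cluster_excess_test(
            pd.concat([case, extra]), self._records({"C1": 10, "C2": 10}, cl), clusters
        )
        assert res["table"]["case"].sum() == 20

    def test_sparse_table_switches_to_monte_carlo(self):
        cl = {"C1": "M1", "C2": "M2", "C3": "M3"}
        clusters = {"M1": "C1", "M2": "C2", "M3": "C3"}
        case = self._records({"C1": 2, "C2": 1, "C3": 1}, cl)
        ctrl = self._records({"C1": 1, "C2": 2, "C3": 2}, cl)
        res = mi.cluster_excess_test(case, ctrl, clusters, seed=0, n_permutations=2000)
        assert res["method"] == "monte_carlo"
        assert 0 < res["p"] <= 1

    def test_single_cluster_raises(self):
        clusters = {"M1": "C1"}
        recs = self._records({"C1": 5}, {"C1": "M1"})
        with pytest.raises(ValueError):
            mi.cluster_excess_test(recs, recs, clusters)

    def test_null_calibration(self):
        rng = np.random.default_rng(5)
        clusters = {f"M{i}": f"C{i}" for i in range(5)}
        pvals = []
        for _ in range(200):
            rows_case = pd.DataFrame(
                {"variant_id": "v", "motif": rng.choice(list(clusters), 120),
                 "is_disrupting": True}
            )
            rows_ctrl = pd.DataFrame(
                {"variant_id": "v", "motif": rng.choice(list(clusters), 120),
                 "is_disrupting": True}
            )
            pvals.append(mi.cluster_excess_test(rows_case, rows_ctrl, clusters)["p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001


class TestDeltaComparison:
    def test_identical_multisets_give_p_one(self):
        a = pd.DataFrame({"delta_pwm": [0.1, -0.2, 0.5]})
        assert mi.compare_delta_distributions(a, a.copy()) == pytest.approx(1.0)

    def test_shift_detected(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({"delta_pwm": rng.normal(0, 1, 500)})
        b = pd.DataFrame({"delta_pwm": rng.normal(0.5, 1, 500)})
        assert mi.compare_delta_distributions(a, b) < 1e-6

    def test_matches_normal_approximation_with_ties(self):
        a = pd.DataFrame({"delta_pwm": [1.0, 2.0, 2.0, 3.0]})
        b = pd.DataFrame({"delta_pwm": [2.0, 3.0, 4.0]})
        got = mi.compare_delta_distributions(a, b)
        expected = stats.mannwhitneyu(
            a["delta_pwm"], b["delta_pwm"], alternative="two-sided", method="asymptotic"
        ).pvalue
        assert got == pytest.approx(float(expected))

    def test_empty_side_raises(self):
        a = pd.DataFrame({"delta_pwm": [0.1]})
        with pytest.raises(ValueError):
            mi.compare_delta_distributions(a, a.iloc[:0])
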