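"""Funnel statistics against independent oracles, plus the set logic that
assembles the candidate panel."""

import math
import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import saltgrn as sg

NO_SHRINKAGE = sg.ShrinkagePrior(d0=0.0, s0_sq=1.0)


def _pooled_t_oracle(a, b):
    """Textbook pooled two-sample t, written independently of the package."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), df=na + nb - 2)
    return t, p


class TestModeratedT:
    def test_d0_zero_matches_pooled_t_hand_example(self):
        """Groups (1,2,3) vs (2,3,4): pooled s2 = 1, t = -1/sqrt(2/3)."""
        m = pd.DataFrame([[1.0, 2.0, 3.0, 2.0, 3.0, 4.0]], index=["g"],
                         columns=list("abcdef"))
        tab = sg.moderated_t_test(m, ["a", "b", "c"], ["d", "e", "f"], prior=NO_SHRINKAGE)
        expected_t = -1.0 / math.sqrt(2.0 / 3.0)
        assert tab.loc["g", "t_mod"] == pytest.approx(expected_t, abs=1e-12)
        assert tab.loc["g", "p"] == pytest.approx(2 * stats.t.sf(abs(expected_t), 4), abs=1e-12)

    def test_d0_zero_matches_pooled_t_on_random_matrix(self, rng):
        m = pd.DataFrame(rng.normal(size=(200, 9)),
                         columns=[f"s{i}" for i in range(9)])
        ga, gb = [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 9)]
        tab = sg.moderated_t_test(m, ga, gb, prior=NO_SHRINKAGE)
        for g in m.index[:50]:
            t, p = _pooled_t_oracle(m.loc[g, ga], m.loc[g, gb])
            assert tab.loc[g, "t_mod"] == pytest.approx(t, abs=1e-8)
            assert tab.loc[g, "p"] == pytest.approx(p, abs=1e-8)

    def test_equal_means_give_null_statistic(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]], index=["g"],
                         columns=list("abcdef"))
        tab = sg.moderated_t_test(m, ["a", "b", "c"], ["d", "e", "f"], prior=NO_SHRINKAGE)
        assert tab.loc["g", "t_mod"] == 0.0
        assert tab.loc["g", "p"] == 1.0

    def test_huge_d0_pins_posterior_variance_at_prior(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 8)), columns=[f"s{i}" for i in range(8)])
        prior = sg.ShrinkagePrior(d0=1e9, s0_sq=0.7)
        ga, gb = [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]
        tab = sg.moderated_t_test(m, ga, gb, prior=prior)
        # reconstruct s2_post from t: s2_post = (lfc / t)^2 / (1/na + 1/nb)
        s2_post = (tab["log2_fc"] / tab["t_mod"]) ** 2 / 0.5
        np.testing.assert_allclose(s2_post, 0.7, rtol=1e-5)

    def test_shrinkage_interpolates_between_gene_and_prior_variance(self, rng):
        m = pd.DataFrame(rng.normal(size=(100, 10)), columns=[f"s{i}" for i in range(10)])
        ga, gb = [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)]
        prior = sg.ShrinkagePrior(d0=4.0, s0_sq=1.3)
        tab = sg.moderated_t_test(m, ga, gb, prior=prior)
        s2_post = (prior.d0 * prior.s0_sq + tab["d_g"] * tab["s2_g"]) / (prior.d0 + tab["d_g"])
        lo = np.minimum(tab["s2_g"], prior.s0_sq)
        hi = np.maximum(tab["s2_g"], prior.s0_sq)
        assert ((s2_post >= lo - 1e-12) & (s2_post <= hi + 1e-12)).all()

    def test_estimated_prior_matches_limma_oracle(self, rng, tmp_path):
        """Independent cross-check of the whole moderated pipeline (prior
        estimation, t, p) against the reference R implementation."""
        m = pd.DataFrame(rng.normal(5, 1, size=(80, 7)),
                         index=[f"g{i:03d}" for i in range(80)],
                         columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(3)])
        m.iloc[:15, :4] += 2.0
        mat = tmp_path / "mat.tsv"
        m.to_csv(mat, sep="\t")
        script = tmp_path / "oracle.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("{mat}", row.names=1))
            grp <- factor(c(rep("A",4), rep("B",3)), levels=c("B","A"))
            fit <- eBayes(lmFit(m, model.matrix(~grp)))
            out <- data.frame(gene=rownames(m), t=fit$t[,2], p=fit$p.value[,2])
            write.table(out, "{tmp_path}/limma.tsv", sep="\\t", quote=FALSE, row.names=FALSE)
        """))
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        oracle = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)
        tab = sg.moderated_t_test(m, list(m.columns[:4]), list(m.columns[4:]), prior="estimate")
        np.testing.assert_allclose(tab["t_mod"], oracle["t"], atol=1e-10)
        np.testing.assert_allclose(tab["p"], oracle["p"], atol=1e-10)

    def test_group_validation(self, toy_matrix):
        with pytest.raises(ValueError):
            sg.moderated_t_test(toy_matrix, ["a1", "a2"], ["a2", "b1"])
        with pytest.raises(ValueError):
            sg.moderated_t_test(toy_matrix, ["a1"], ["b1", "b2"])
        with pytest.raises(ValueError):
            sg.moderated_t_test(toy_matrix, ["a1", "zz"], ["b1", "b2"])

    def test_constant_matrix_rejected_under_estimation(self):
        m = pd.DataFrame(np.ones((5, 6)), columns=list("abcdef"))
        with pytest.raises(ValueError):
            sg.moderated_t_test(m, list("abc"), list("def"), prior="estimate")


def _bh_oracle(p):
    """Brute-force step-up: p(i) * m / i with cumulative-min from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBHAdjust:
    def test_single_value_identity(self):
        assert sg.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_stepup_example(self):
        np.testing.assert_allclose(
            sg.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(sg.bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sg.bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            sg.bh_adjust([0.5, np.nan])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_bruteforce_oracle(self, p):
        np.testing.assert_allclose(sg.bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_adjusted_never_below_raw_and_monotone(self, rng):
        p = rng.uniform(size=300)
        adj = sg.bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestCallDegs:
    table = pd.DataFrame(
        {
            "log2_fc": [1.0, 0.9, -1.5, 3.0],
            "p": [0.001, 1e-6, 0.0005, 0.2],
            "p_adj": [0.001, 1e-5, 0.0008, 0.4],
        },
        index=["boundary", "lowfc", "down", "weak"],
    )

    def test_boundary_gene_is_retained_inclusively(self):
        """log2_fc exactly 1.0 and p exactly at the cutoff pass (>= / <=)."""
        degs = sg.call_degs(self.table, 1.0, 0.001, use_adjusted=False)
        assert "boundary" in degs

    def test_below_fold_change_excluded_despite_tiny_p(self):
        degs = sg.call_degs(self.table, 1.0, 0.001, use_adjusted=False)
        assert "lowfc" not in degs

    def test_direction_handling(self):
        assert sg.call_degs(self.table, 1.0, 0.001, use_adjusted=False, direction="up") == {"boundary"}
        assert sg.call_degs(self.table, 1.0, 0.001, use_adjusted=False, direction="down") == {"down"}

    def test_permissive_thresholds_return_universe(self):
        assert sg.call_degs(self.table, 0.0, 1.0) == set(self.table.index)

    def test_empty_table_gives_empty_set(self):
        empty = self.table.iloc[:0]
        assert sg.call_degs(empty, 1.0, 0.05) == set()

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            sg.call_degs(self.table, 1.0, 0.05, direction="sideways")


class TestSetLogic:
    def test_overlap_partition(self):
        ov = sg.overlap_sets({"g1", "g2", "g3"}, {"g2", "g3", "g4"})
        assert ov.intersection == {"g2", "g3"}
        assert ov.a_only == {"g1"}
        assert ov.b_only == {"g4"}

    def test_overlap_disjoint_and_subset(self):
        assert sg.overlap_sets({"a"}, {"b"}).intersection == set()
        ov = sg.overlap_sets({"a", "b"}, {"a", "b", "c"})
        assert ov.a_only == set() and len(ov.intersection) == 2

    def test_overlap_counts_partition_set_a(self, rng):
        a = {f"g{i}" for i in rng.choice(200, 80, replace=False)}
        b = {f"g{i}" for i in rng.choice(200, 80, replace=False)}
        ov = sg.overlap_sets(a, b)
        assert len(ov.intersection) + len(ov.a_only) == len(a)

    def test_study_shaped_panel_has_94_entries(self):
        """91 overlap-filtered one-hybrid hits + 2 known regulators + the
        target, all distinct, assemble into a panel of exactly 94."""
        y1h = {f"hit{i:03d}" for i in range(120)}
        overlap = {f"hit{i:03d}" for i in range(91)} | {f"deg{i}" for i in range(500)}
        cand = sg.build_candidate_list(overlap, y1h, {"known1", "known2"}, "target0")
        assert len(cand) == 94
        assert cand.genes[0] == "target0"

    def test_provenance_precedence_known_over_one_hybrid(self):
        cand = sg.build_candidate_list({"a", "b"}, {"a", "b"}, {"a"}, "t")
        assert dict(cand.entries)["a"] == "known-regulator"
        assert len(cand) == 3

    def test_minimal_panel(self):
        cand = sg.build_candidate_list(set(), set(), {"a", "b"}, "t")
        assert cand.genes == ["t", "a", "b"]

    def test_size_identity(self, rng):
        y1h = {f"g{i}" for i in rng.choice(100, 40, replace=False)}
        overlap = {f"g{i}" for i in rng.choice(100, 60, replace=False)}
        known = {"k1", "g5"}
        cand = sg.build_candidate_list(overlap, y1h, known, "t")
        kept = y1h & overlap
        assert len(cand) == len(kept | known) + ("t" not in kept | known)

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            sg.build_candidate_list(set(), set(), set(), "")
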