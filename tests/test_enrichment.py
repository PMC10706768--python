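"""GO-group enrichment, permutation null, contrasting selection, clusters."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from symcore import enrichment as enr


class TestPEnrich:
    def test_expectation_gives_one(self):
        assert enr.p_enrich(5, 50, 100, 1000) == pytest.approx(1.0)

    def test_double_expectation(self):
        assert enr.p_enrich(10, 50, 100, 1000) == pytest.approx(2.0)

    def test_zero_observed(self):
        assert enr.p_enrich(0, 50, 100, 1000) == 0.0

    def test_scale_invariance(self):
        a = enr.p_enrich(7, 40, 90, 800)
        b = enr.p_enrich(21, 120, 270, 2400)
        assert a == pytest.approx(b)

    def test_zero_sizes_rejected(self):
        with pytest.raises(ValueError):
            enr.p_enrich(1, 0, 10, 100)


class TestPermutationTest:
    def test_deterministic_under_seed(self):
        obs = enr.p_enrich(10, 50, 100, 1000)
        p1 = enr.permutation_test(
            50, 100, 1000, obs, 2000, np.random.default_rng(5)
        ).permutation_p
        p2 = enr.permutation_test(
            50, 100, 1000, obs, 2000, np.random.default_rng(5)
        ).permutation_p
        assert p1 == p2

    def test_zero_observed_p_near_one(self):
        res = enr.permutation_test(
            50, 100, 1000, 0.0, 1000, np.random.default_rng(0)
        )
        assert res.permutation_p > 0.99

    def test_p_floor(self):
        res = enr.permutation_test(
            5, 10, 1000, 100.0, 500, np.random.default_rng(0)
        )
        assert res.permutation_p >= 1 / 501

    def test_null_p_values_uniform(self):
        # draw the group membership at random, test, collect p: under the
        # null the p distribution is ~uniform once the count statistic has
        # a fine support (genome-scale sizes); coarse supports make the
        # discrete p conservative rather than uniform
        rng = np.random.default_rng(42)
        n_genome, s_sep, n_sep = 5000, 500, 1500
        pvals = []
        for _ in range(200):
            n_obs = rng.hypergeometric(s_sep, n_genome - s_sep, n_sep)
            obs = enr.p_enrich(int(n_obs), s_sep, n_sep, n_genome)
            pvals.append(
                enr.permutation_test(
                    s_sep, n_sep, n_genome, obs, 500, rng
                ).permutation_p
            )
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


def make_gogs(mean_table, pool_means):
    gogs = []
    for go_id, (p_ori, p_off, d_ori, d_off) in mean_table.items():
        g = enr.GOGRecord(go_id, ["g1", "g2"])
        g.mean_p = {"orientalis": p_ori, "officinalis": p_off}
        g.mean_dnds = {"orientalis": d_ori, "officinalis": d_off}
        gogs.append(g)
    return gogs


class TestSelectContrasting:
    pool_p = {"orientalis": 0.05, "officinalis": 0.01}

    def test_planted_outlier_detected(self):
        table = {
            f"GO:{i:07d}": (0.05 + 0.001 * (i % 3), 0.01, 1.0, 1.0)
            for i in range(10)
        }
        table["GO:planted"] = (0.5, 0.01, 1.0, 1.0)
        gogs = make_gogs(table, self.pool_p)
        selected, thr = enr.select_contrasting_gogs(gogs, "p", self.pool_p)
        assert [g.go_id for g in selected] == ["GO:planted"]
        assert thr["orientalis"] > 0

    def test_no_variation_nothing_selected(self):
        table = {f"GO:{i:07d}": (0.05, 0.01, 1.0, 1.0) for i in range(5)}
        gogs = make_gogs(table, self.pool_p)
        selected, _ = enr.select_contrasting_gogs(gogs, "p", self.pool_p)
        assert selected == []

    def test_zero_pool_mean_rejected(self):
        gogs = make_gogs({"GO:1": (0.1, 0.1, 1, 1), "GO:2": (0.2, 0.2, 1, 1)},
                         self.pool_p)
        with pytest.raises(ValueError):
            enr.select_contrasting_gogs(
                gogs, "p", {"orientalis": 0.0, "officinalis": 0.01}
            )


class TestClusterContingency:
    def _gog(self, go_id, cp, cs):
        g = enr.GOGRecord(go_id, [])
        g.cluster_pol, g.cluster_sel = cp, cs
        return g

    def test_single_cell(self):
        gogs = [self._gog(f"GO:{i}", "IV", "IV") for i in range(5)]
        table = enr.cluster_contingency(gogs)
        assert table.loc["C_sel-IV", "C_pol-IV"] == 5
        assert table.loc["Total", "Total"] == 5
        assert table.drop("Total").drop(columns="Total").to_numpy().sum() == 5

    def test_margins_sum_to_total(self, rng):
        quads = ["I", "II", "III", "IV"]
        gogs = [
            self._gog(f"GO:{i}", rng.choice(quads), rng.choice(quads))
            for i in range(40)
        ]
        table = enr.cluster_contingency(gogs)
        inner = table.drop("Total").drop(columns="Total")
        assert table.loc["Total", "Total"] == 40
        assert (inner.sum(axis=1) == table.drop("Total")["Total"]).all()
        assert (inner.sum(axis=0) == table.loc["Total"].drop("Total")).all()

    def test_hand_tabulated_fixture(self):
        labels = [
            ("I", "I"), ("I", "I"), ("I", "IV"), ("II", "III"),
            ("IV", "IV"), ("IV", "IV"), ("IV", "I"), ("III", "II"),
            ("II", "II"), ("IV", "III"),
        ]
        gogs = [self._gog(f"GO:{i}", cp, cs) for i, (cp, cs) in enumerate(labels)]
        table = enr.cluster_contingency(gogs)
        assert table.loc["C_sel-I", "C_pol-I"] == 2
        assert table.loc["C_sel-IV", "C_pol-IV"] == 2
        assert table.loc["C_sel-I", "C_pol-IV"] == 1
        assert table.loc["Total", "Total"] == 10


class TestHighInHigh:
    def _gogs(self, pairs):
        out = []
        for i, (ep, ed) in enumerate(pairs):
            g = enr.GOGRecord(f"GO:{i}", [])
            g.enrich_p = {"orientalis": ep}
            g.enrich_dnds = {"orientalis": ed}
            out.append(g)
        return out

    def test_perfect_association(self):
        gogs = self._gogs([(2.0, 2.0)] * 6 + [(0.5, 0.5)] * 6)
        hh, hl, cmp = enr.high_in_high(gogs, "orientalis")
        assert hh.estimate == 1.0
        assert hl.estimate == 0.0

    def test_independence_matches_marginal(self):
        # 2x2 independence: elevated-b frequency 0.5 in both strata
        gogs = self._gogs(
            [(2, 2)] * 3 + [(2, 0.5)] * 3 + [(0.5, 2)] * 3 + [(0.5, 0.5)] * 3
        )
        hh, hl, cmp = enr.high_in_high(gogs, "orientalis")
        assert hh.estimate == pytest.approx(0.5)
        assert hl.estimate == pytest.approx(0.5)

    def test_counts_9_of_12_vs_3_of_12(self):
        gogs = self._gogs(
            [(2, 2)] * 9 + [(2, 0.5)] * 3 + [(0.5, 2)] * 3 + [(0.5, 0.5)] * 9
        )
        hh, hl, cmp = enr.high_in_high(gogs, "orientalis")
        assert hh.estimate == pytest.approx(0.75)
        assert hl.estimate == pytest.approx(0.25)
        expected_t = (0.75 - 0.25) / math.sqrt(
            0.75 * 0.25 / 12 + 0.25 * 0.75 / 12
        )
        assert cmp.t == pytest.approx(expected_t, rel=1e-12)

    def test_empty_stratum_flagged(self):
        gogs = self._gogs([(2.0, 2.0)] * 4)
        hh, hl, cmp = enr.high_in_high(gogs, "orientalis")
        assert cmp is None


class TestBuildGogs:
    def test_membership_restricted_to_pool(self):
        gene2go = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "g2", "g3", "g4"],
                "go_id": ["GO:1", "GO:1", "GO:1", "GO:2", "GO:2", "GO:2"],
            }
        )
        metrics = pd.DataFrame(
            {
                "p_orientalis": [0.1, 0.2, 0.3],
                "p_officinalis": [0.1, 0.2, 0.3],
                "dnds_orientalis": [1.0, 1.0, 1.0],
                "dnds_officinalis": [1.0, 1.0, 1.0],
            },
            index=["g1", "g2", "g3"],
        )
        gogs = enr.build_gogs(
            gene2go, metrics, ("orientalis", "officinalis")
        )
        by_id = {g.go_id: g for g in gogs}
        assert by_id["GO:1"].genes == ["g1", "g2", "g3"]
        assert by_id["GO:2"].genes == ["g2", "g3"]  # g4 not in pool
        assert by_id["GO:1"].mean_p["orientalis"] == pytest.approx(0.2)
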