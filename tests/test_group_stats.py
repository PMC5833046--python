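"""Kruskal-Wallis and Dunn's post-hoc against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from placscreen.group_stats import (
    dunn_posthoc, flag_significant, group_test_table, kruskal_wallis,
    kruskal_wallis_matrix, p_stars,
)


class TestKruskalWallis:
    def test_three_group_worked_example(self):
        res = kruskal_wallis([1, 2, 3, 4, 5, 6, 7, 8, 9],
                             ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.h == pytest.approx(7.2)
        assert res.df == 2

    def test_all_values_identical_defines_h_zero_p_one(self):
        res = kruskal_wallis([5.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.h == 0.0 and res.p == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scipy_including_ties(self, seed):
        rng = np.random.default_rng(seed)
        g = int(rng.integers(2, 5))
        sizes = rng.integers(3, 9, size=g)
        # discretized values force ties
        samples = [np.round(rng.normal(size=n), 1) for n in sizes]
        values = np.concatenate(samples)
        groups = [i for i, n in enumerate(sizes) for _ in range(n)]
        mine = kruskal_wallis(values, groups)
        ref = sps.kruskal(*samples)
        assert mine.h == pytest.approx(ref.statistic, abs=1e-10)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_vectorized_matches_scalar(self, rng):
        groups = ["a"] * 5 + ["b"] * 4 + ["c"] * 6
        mat = np.round(rng.normal(size=(20, 15)), 1)
        vec = kruskal_wallis_matrix(mat, groups)
        for i in range(20):
            res = kruskal_wallis(mat[i], groups)
            assert vec["h"].iloc[i] == pytest.approx(res.h, abs=1e-10)
            assert vec["p"].iloc[i] == pytest.approx(res.p, abs=1e-10)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transformation(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=12)
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        base = kruskal_wallis(values, groups)
        for transform in (np.exp, lambda v: 3 * v + 11, np.cbrt):
            res = kruskal_wallis(transform(values), groups)
            assert res.h == pytest.approx(base.h, abs=1e-9)

    def test_exact_mode_agrees_with_sampled_permutation_null(self, rng):
        values = rng.normal(size=10)
        groups = ["a"] * 4 + ["b"] * 3 + ["c"] * 3
        exact = kruskal_wallis(values, groups, method="exact")
        h_obs = kruskal_wallis(values, groups).h
        draws = []
        ranks = sps.rankdata(values)
        for _ in range(20000):
            perm = rng.permutation(ranks)
            sums = [perm[:4].sum(), perm[4:7].sum(), perm[7:].sum()]
            h = 12 / (10 * 11) * sum(s * s / n for s, n in zip(sums, (4, 3, 3))) - 33
            draws.append(h >= h_obs - 1e-12)
        p_mc = np.mean(draws)
        se = np.sqrt(p_mc * (1 - p_mc) / 20000)
        assert exact.p == pytest.approx(p_mc, abs=4 * se)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])


class TestDunn:
    def test_identical_values_give_null_z(self):
        res = dunn_posthoc([1.0] * 6, ["term"] * 3 + ["g"] * 3)
        assert res.loc[0, "z"] == 0.0 and res.loc[0, "p_raw"] == 1.0

    def test_bonferroni_over_four_comparisons(self, rng):
        values = rng.normal(size=25)
        groups = (["term"] * 5 + ["preterm"] * 5 + ["IUGR"] * 5
                  + ["PE"] * 5 + ["PE+IUGR"] * 5)
        res = dunn_posthoc(values, groups).set_index("group")
        assert len(res) == 4
        assert np.allclose(res["p_adj"], np.minimum(1.0, 4 * res["p_raw"]))

    def test_z_antisymmetric_under_group_exchange(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=4) + 1
        values = np.concatenate([a, b])
        z1 = dunn_posthoc(values, ["term"] * 5 + ["g"] * 4).loc[0, "z"]
        swapped = np.concatenate([b, a])
        z2 = dunn_posthoc(swapped, ["term"] * 4 + ["g"] * 5).loc[0, "z"]
        assert z1 == pytest.approx(-z2)

    def test_hand_computed_two_group_example(self):
        # term {1, 2, 3}, g {4, 5}: ranks 1..5, mean ranks 2 and 4.5;
        # no ties, variance term = 5*6/12 = 2.5
        res = dunn_posthoc([1, 2, 3, 4, 5], ["term"] * 3 + ["g"] * 2)
        z_expected = (2.0 - 4.5) / np.sqrt(2.5 * (1 / 3 + 1 / 2))
        assert res.loc[0, "z"] == pytest.approx(z_expected)

    def test_unchanged_by_relabeling_other_groups(self, rng):
        values = list(rng.normal(size=12))
        groups = ["term"] * 4 + ["g1"] * 4 + ["g2"] * 4
        z_before = dunn_posthoc(values, groups).set_index("group").loc["g1", "z"]
        # swap the g2 values among themselves (ranks unaffected)
        relabeled = values[:8] + values[8:][::-1]
        z_after = dunn_posthoc(relabeled, groups).set_index("group").loc["g1", "z"]
        assert z_before == pytest.approx(z_after)

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            dunn_posthoc([1, 2, 3, 4], ["a", "a", "b", "b"], control="term")


class TestFlagsAndTable:
    def test_strict_alpha_boundary(self):
        table = pd.DataFrame({"p": [0.049, 0.05, 0.2]},
                             index=["g1", "g2", "g3"])
        assert flag_significant(table) == {"g1"}

    def test_empty_result_set(self):
        assert flag_significant(pd.DataFrame(columns=["p"])) == set()

    def test_star_bands(self):
        assert [p_stars(p) for p in (0.0005, 0.005, 0.04, 0.2)] == \
            ["***", "**", "*", "ns"]

    def test_table_runs_per_gene_and_is_rank_invariant(self, rng):
        rows = []
        groups = ["term"] * 5 + ["IUGR"] * 4 + ["PE"] * 4
        for gene in ("g1", "g2"):
            vals = rng.normal(size=13) + (1.0 if gene == "g1" else 0.0) * \
                np.array([0] * 5 + [1] * 4 + [0] * 4)
            for s, (v, g) in enumerate(zip(vals, groups)):
                rows.append({"gene": gene, "sample_id": f"s{s}", "group": g,
                             "log2_fc": v, "fc": 2.0 ** v})
        fc = pd.DataFrame(rows)
        on_log = group_test_table(fc, value_col="log2_fc")
        on_linear = group_test_table(fc, value_col="fc")
        assert np.allclose(on_log["h"], on_linear["h"])
        assert np.allclose(on_log["p"], on_linear["p"])
        assert set(on_log.columns) >= {"h", "df", "p", "stars", "significant"}
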