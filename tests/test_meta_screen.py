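"""Quantile normalization, moderated t and candidate-selection rules."""

import numpy as np
import pandas as pd
import pytest

from placscreen.meta_screen import (
    D0_CAP, DEResult, de_statistics, fit_variance_prior, moderated_t,
    quantile_normalize, rank_top_k, select_candidates,
)
from placscreen.synthetic_data import default_cohort_config, simulate_studies
from placscreen.tabular_io import ExpressionStudy


def _study(matrix: dict, groups: dict, study_id="S") -> ExpressionStudy:
    return ExpressionStudy(study_id, pd.DataFrame(matrix).T, dict(groups))


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        expected = [2.5, 3.5, 4.5]
        assert out["a"].tolist() == expected and out["b"].tolist() == expected

    def test_identical_columns_fixed_point(self, rng):
        col = rng.normal(size=20)
        m = pd.DataFrame({"a": col, "b": col, "c": col})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_column_means_equal_and_idempotent(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 5)) * [1, 2, 3, 4, 5])
        out = quantile_normalize(m)
        assert np.allclose(out.mean(axis=0), out.mean(axis=0).iloc[0])
        pd.testing.assert_frame_equal(quantile_normalize(out), out)

    def test_ties_get_mean_of_spanned_values(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        # reference = [1.5, 2.5, 5.5]; the tie in 'a' spans ranks 1-2
        assert out["a"].tolist() == [2.0, 2.0, 5.5]
        assert out["b"].tolist() == [1.5, 2.5, 5.5]

    def test_single_column_warns_and_returns_unchanged(self):
        m = pd.DataFrame({"a": [3.0, 1.0]})
        with pytest.warns(UserWarning, match="single-column"):
            out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)


class TestModeratedT:
    def test_identical_group_means_give_null_result(self):
        study = _study(
            {"g1": [5, 6, 5, 6], "g2": [1, 2, 3, 4]},
            {0: "control", 1: "control", 2: "IUGR", 3: "IUGR"},
        )
        de = de_statistics(study, "IUGR")
        row = de.table.loc["g1"]
        assert row["log2_fc"] == 0 and row["t"] == 0 and row["p"] == 1

    def test_fc_invariant_under_constant_shift(self, noisy_config):
        (study,), _ = simulate_studies(noisy_config)
        shifted = ExpressionStudy(
            study.study_id, study.matrix + 7.5, study.groups)
        a = de_statistics(study, "IUGR").table
        b = de_statistics(shifted, "IUGR").table
        assert np.allclose(a["log2_fc"], b["log2_fc"], atol=1e-12)

    def test_noise_free_planted_effect_recovered_exactly(self, noisefree_config):
        studies, _ = simulate_studies(noisefree_config)
        de = de_statistics(studies[0], "IUGR")
        assert de.table.loc["G1", "log2_fc"] == pytest.approx(1.0, abs=1e-12)

    def test_large_d0_limit_equals_prior_variance_t(self):
        fc = np.array([1.0, -0.5])
        s2 = np.array([0.3, 0.8])
        s0 = 0.5
        t, _, _ = moderated_t(fc, s2, 4, 4, d0=1e12, s0_sq=s0)
        expected = fc / np.sqrt(s0 * (1 / 4 + 1 / 4))
        assert np.allclose(t, expected, rtol=1e-5)

    def test_variance_prior_moment_fit_recovers_truth(self, rng):
        # draw s_g^2 from the scaled inverse-chi-square hierarchy and check
        # the moment fit recovers (d0, s0^2) approximately
        d0_true, s0_true, dg, n = 8.0, 0.25, 6, 4000
        prior_var = d0_true * s0_true / rng.chisquare(d0_true, size=n)
        s2 = prior_var * rng.chisquare(dg, size=n) / dg
        d0, s0_sq = fit_variance_prior(s2, dg)
        assert d0 == pytest.approx(d0_true, rel=0.25)
        assert s0_sq == pytest.approx(s0_true, rel=0.1)

    def test_variance_prior_capped_without_excess_variance(self):
        # constant variances: log-variance spread is below the chi-square
        # sampling floor, so the moment estimate diverges and is capped
        d0, _ = fit_variance_prior(np.full(100, 0.4), dg=6)
        assert d0 == D0_CAP


class TestRanking:
    def _de(self, fc_p: dict) -> DEResult:
        table = pd.DataFrame(
            {"log2_fc": [v[0] for v in fc_p.values()],
             "p": [v[1] for v in fc_p.values()]},
            index=pd.Index(fc_p.keys(), name="gene"))
        table["t"] = 0.0
        order_up = np.lexsort((table.index, table["p"], -table["log2_fc"]))
        table["rank_up"] = pd.Series(np.arange(1, len(table) + 1),
                                     index=table.index[order_up])
        order_down = np.lexsort((table.index, table["p"], table["log2_fc"]))
        table["rank_down"] = pd.Series(np.arange(1, len(table) + 1),
                                       index=table.index[order_down])
        return DEResult("S", "IUGR", table, 4.0, 1.0)

    def test_top_k_by_fold_change(self):
        de = self._de({"a": (2.0, 0.1), "b": (1.0, 0.1), "c": (-1.0, 0.1)})
        up, down = rank_top_k(de, k=2)
        assert up == ["a", "b"] and down == ["c", "b"]

    def test_equal_fc_tie_broken_by_smaller_p(self):
        de = self._de({"a": (1.0, 0.5), "b": (1.0, 0.01)})
        up, _ = rank_top_k(de, k=1)
        assert up == ["b"]

    def test_k_equal_to_n_returns_everything(self):
        de = self._de({"a": (2.0, 0.1), "b": (-1.0, 0.1)})
        up, down = rank_top_k(de, k=2)
        assert set(up) == set(down) == {"a", "b"}

    def test_k_larger_than_n_is_an_error(self):
        with pytest.raises(ValueError):
            rank_top_k(self._de({"a": (1.0, 0.1)}), k=2)


class TestSelection:
    def _results(self, per_study_fc: dict[str, dict[str, float]]) -> list:
        """One DEResult per study from explicit gene -> log2 FC mappings."""
        results = []
        for sid in sorted(per_study_fc):
            fcs = per_study_fc[sid]
            genes = sorted(fcs)
            table = pd.DataFrame(
                {"log2_fc": [fcs[g] for g in genes], "t": 1.0, "p": 0.5},
                index=pd.Index(genes, name="gene"))
            order_up = np.lexsort((table.index, -table["log2_fc"]))
            table["rank_up"] = pd.Series(np.arange(1, len(table) + 1),
                                         index=table.index[order_up])
            order_down = np.lexsort((table.index, table["log2_fc"]))
            table["rank_down"] = pd.Series(np.arange(1, len(table) + 1),
                                           index=table.index[order_down])
            results.append(DEResult(sid, "IUGR", table, 4.0, 1.0))
        return results

    def test_three_criteria(self):
        base = {"hit": 1.0, "dull": 0.1, "unflagged": 0.9,
                "sink": -1.0, "sink2": -0.9}
        per_study = {
            "S1": {**base, "few": 0.95},
            "S2": {**base, "few": 0.95},
            "S3": {**base, "few": 0.95},
            "S4": base,  # 'few' is measured in only 3 studies
        }
        results = self._results(per_study)
        flags = {"hit": True, "few": True, "dull": True,
                 "unflagged": False, "sink": False, "sink2": False}
        cands = select_candidates(results, flags, min_studies=4, k=2)
        # hit: 4 studies + top-2 up + flag -> selected
        # few: perfect but only 3 studies; dull: never top-2 in either
        # direction; unflagged/sink: no curation flag
        assert cands.selected == ["hit"]
        assert cands.table.loc["few", "n_studies"] == 3
        assert not cands.table.loc["dull", "in_top_k"]

    def test_adding_a_study_never_removes_a_candidate(self):
        per_study = {f"S{i}": {"hit": 1.0, "pad": 0.1, "sink": -1.0}
                     for i in range(1, 5)}
        flags = {"hit": True, "pad": False, "sink": False}
        before = select_candidates(self._results(per_study), flags,
                                   min_studies=4, k=1).selected
        per_study["S5"] = {"hit": 0.0, "pad": 0.5, "sink": -1.0}
        after = select_candidates(self._results(per_study), flags,
                                  min_studies=4, k=1).selected
        assert set(before) <= set(after)

    def test_fc_range_reported_across_studies(self):
        per_study = {f"S{i}": {"hit": fc, "sink": -2.0}
                     for i, fc in enumerate([-0.42, 0.89, 0.1, 0.2], 1)}
        cands = select_candidates(self._results(per_study), {"hit": True},
                                  min_studies=4, k=1)
        assert cands.table.loc["hit", "log2_fc_range"] == "-0.42~0.89"

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
    def test_planted_cohort_fully_recovered(self, seed):
        """Every planted non-null gene is selected from the 7-study screen."""
        cfg = default_cohort_config(n_genes=120, seed=seed, noise_sd=0.3)
        studies, truth = simulate_studies(cfg)
        results = []
        for study in studies:
            study.matrix = quantile_normalize(study.matrix)
            for contrast in ("IUGR", "PE"):
                if contrast in set(study.groups.values()):
                    results.append(de_statistics(study, contrast))
        flags = {g: True for g in cfg.genes}
        cands = select_candidates(results, flags)
        assert set(truth.non_null_genes) <= set(cands.selected)
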