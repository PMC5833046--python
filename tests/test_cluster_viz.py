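"""Correlation distance, UPGMA against brute-force and scipy oracles."""

import numpy as np
import pandas as pd
import pytest

from placscreen.cluster_viz import (
    average_linkage, build_heatmap, centered_correlation_distance,
)


def brute_force_upgma(dist: pd.DataFrame):
    """Independent UPGMA oracle: recompute every cluster-pair average from
    the original leaf distances at every step (no Lance-Williams update)."""
    labels = list(dist.index)
    d = dist.to_numpy(dtype=float)
    clusters: dict[int, frozenset[int]] = {
        i: frozenset([i]) for i in range(len(labels))}
    merges = []
    next_id = len(labels)
    while len(clusters) > 1:
        best = None
        for u in sorted(clusters):
            for v in sorted(clusters):
                if u >= v:
                    continue
                pairs = [(i, j) for i in clusters[u] for j in clusters[v]]
                avg = float(np.mean([d[i, j] for i, j in pairs]))
                key = tuple(sorted((min(labels[i] for i in clusters[u]),
                                    min(labels[j] for j in clusters[v]))))
                cand = (avg, key, u, v)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        height, _, u, v = best
        merges.append((u, v, height, next_id))
        clusters[next_id] = clusters.pop(u) | clusters.pop(v)
        next_id += 1
    return merges


def _random_distance(rng, n):
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = rng.uniform(0.05, 2.0, size=len(iu[0]))
    m += m.T
    labels = [f"L{i:02d}" for i in range(n)]
    return pd.DataFrame(m, index=labels, columns=labels)


class TestDistance:
    def test_scaled_vector_has_zero_distance(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]], index=["v", "w"])
        assert centered_correlation_distance(m).loc["v", "w"] == \
            pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_vector_has_distance_two(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]],
                         index=["v", "w"])
        assert centered_correlation_distance(m).loc["v", "w"] == \
            pytest.approx(2.0, abs=1e-12)

    def test_hand_computed_pearson(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]], index=["v", "w"])
        assert centered_correlation_distance(m).loc["v", "w"] == \
            pytest.approx(0.5)

    def test_zero_variance_vector_reported_by_id(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                         index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            centered_correlation_distance(m)

    def test_uncentered_variant_differs(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 3.0, 5.0]], index=["v", "w"])
        centered = centered_correlation_distance(m, centered=True)
        uncentered = centered_correlation_distance(m, centered=False)
        assert centered.loc["v", "w"] != pytest.approx(
            uncentered.loc["v", "w"], abs=1e-6)


class TestUPGMA:
    def test_three_leaf_worked_example(self):
        d = pd.DataFrame([[0, 1, 4], [1, 0, 5], [4, 5, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        den = average_linkage(d)
        assert den.merges[0][:3] == (0, 1, 1.0)
        assert den.merges[1][2] == pytest.approx(4.5)

    def test_equal_distances_resolved_deterministically(self):
        labels = list("DACB")
        d = pd.DataFrame(np.ones((4, 4)) - np.eye(4),
                         index=labels, columns=labels)
        den = average_linkage(d)
        # first merge must take the lexicographically smallest label pair
        a, b, h, _ = den.merges[0]
        assert {labels[a], labels[b]} == {"A", "B"} and h == 1.0
        assert all(m[2] == pytest.approx(1.0) for m in den.merges)

    def test_heights_never_decrease(self, rng):
        for _ in range(20):
            d = _random_distance(rng, int(rng.integers(4, 9)))
            heights = [m[2] for m in average_linkage(d).merges]
            assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = _random_distance(rng, int(rng.integers(6, 11)))
        mine = average_linkage(d).merges
        oracle = brute_force_upgma(d)
        assert len(mine) == len(oracle)
        for (a1, b1, h1, n1), (a2, b2, h2, n2) in zip(mine, oracle):
            assert h1 == pytest.approx(h2, abs=1e-10)
            assert {a1, b1} == {a2, b2} and n1 == n2

    def test_matches_scipy_heights(self, rng):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        d = _random_distance(rng, 9)
        mine = sorted(m[2] for m in average_linkage(d).merges)
        ref = sorted(average(squareform(d.to_numpy()))[:, 2])
        assert np.allclose(mine, ref, atol=1e-10)

    def test_leaf_order_is_a_permutation(self, rng):
        d = _random_distance(rng, 8)
        order = average_linkage(d).leaf_order()
        assert sorted(order) == list(range(8))

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]], index=["a", "b"],
                         columns=["a", "b"], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            average_linkage(d)


class TestHeatmap:
    def _matrix(self, rng, n_genes=6, n_samples=5):
        labels = [f"g{i}" for i in range(n_genes)]
        cols = [f"s{i}" for i in range(n_samples)]
        return pd.DataFrame(rng.normal(size=(n_genes, n_samples)),
                            index=labels, columns=cols)

    def test_duplicated_genes_end_up_adjacent(self, rng):
        m = self._matrix(rng)
        m.loc["g5"] = m.loc["g0"]  # perfect correlation, distance 0
        tree = average_linkage(centered_correlation_distance(m))
        export = build_heatmap(m, tree, center="none")
        i, j = export.row_order.index("g0"), export.row_order.index("g5")
        assert abs(i - j) == 1

    def test_median_centering_and_annotations(self, rng):
        m = self._matrix(rng)
        tree = average_linkage(centered_correlation_distance(m))
        ann = {c: ("term" if i < 3 else "PE") for i, c in enumerate(m.columns)}
        export = build_heatmap(m, tree, annotations=ann)
        assert np.allclose(export.matrix.median(axis=1), 0.0, atol=1e-12)
        assert list(export.annotations.index) == export.col_order
        assert "red=up" in export.metadata["color_convention"]

    def test_mismatched_tree_rejected(self, rng):
        m = self._matrix(rng)
        other = self._matrix(rng).rename(index=lambda g: g + "x")
        tree = average_linkage(centered_correlation_distance(other))
        with pytest.raises(ValueError, match="do not match"):
            build_heatmap(m, tree)
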