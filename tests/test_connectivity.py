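"""Network construction: parcel averaging, FC, MST backbone, densification, masking."""

from __future__ import annotations

from itertools import product

import networkx as nx
import numpy as np
import pytest

from bindnet import (
    FCMatrix,
    apply_mask,
    densify_to_sparsity,
    fc_matrix,
    mst_backbone,
    parcel_average,
)
from bindnet._graph import is_connected
from bindnet.connectivity import target_edge_count


def random_fc(rng: np.random.Generator, n: int) -> FCMatrix:
    x = rng.normal(size=(4 * n, n))
    return fc_matrix(x)


class TestParcelAverage:
    def test_one_voxel_per_region_is_identity(self):
        rng = np.random.default_rng(0)
        vox = rng.normal(size=(20, 4))
        panel = parcel_average(vox, np.array(["a", "b", "c", "d"]))
        np.testing.assert_allclose(panel.data, vox)

    def test_two_voxel_mean(self):
        vox = np.array([[1.0, 3.0], [2.0, 6.0], [0.0, 4.0]])
        panel = parcel_average(vox, np.array([0, 0]))
        np.testing.assert_allclose(panel.data[:, 0], [2.0, 4.0, 2.0])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        vox = rng.normal(size=(15, 10))
        labels = rng.integers(0, 3, size=10)
        while len(np.unique(labels)) < 3:
            labels = rng.integers(0, 3, size=10)
        panel = parcel_average(vox, labels)
        for ri, r in enumerate(np.unique(labels)):
            for t in range(15):
                members = [v for v in range(10) if labels[v] == r]
                expected = sum(vox[t, v] for v in members) / len(members)
                assert panel.data[t, ri] == pytest.approx(expected)


class TestFCMatrix:
    def test_diagonal_is_one(self):
        fc = random_fc(np.random.default_rng(0), 5)
        np.testing.assert_allclose(np.diag(fc.r), 1.0)

    def test_anticorrelated_series(self):
        x = np.random.default_rng(0).normal(size=30)
        fc = fc_matrix(np.column_stack([x, -x, x + 0.0]))
        assert fc.r[0, 1] == pytest.approx(-1.0)
        assert fc.r[0, 2] == pytest.approx(1.0)

    def test_matches_longhand_definition_oracle(self):
        """3-region, 5-frame worked case vs covariance/sigma computed long-hand."""
        data = np.array(
            [
                [1.0, 2.0, 0.5],
                [2.0, 1.0, 1.5],
                [3.0, 4.0, 0.0],
                [4.0, 3.0, 2.0],
                [5.0, 5.0, 1.0],
            ]
        )
        fc = fc_matrix(data)
        for i, j in product(range(3), repeat=2):
            xi = data[:, i] - data[:, i].mean()
            xj = data[:, j] - data[:, j].mean()
            expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
            assert fc.r[i, j] == pytest.approx(expected)

    def test_zero_variance_region_named(self):
        data = np.random.default_rng(0).normal(size=(10, 3))
        data[:, 1] = 7.0
        with pytest.raises(ValueError, match="zero variance"):
            fc_matrix(data, region_labels=["a", "b", "c"])


class TestMSTBackbone:
    def test_two_regions(self):
        fc = random_fc(np.random.default_rng(2), 2)
        assert mst_backbone(fc).edge_count == 1

    def test_tree_shape(self):
        fc = random_fc(np.random.default_rng(3), 12)
        bb = mst_backbone(fc)
        assert bb.edge_count == 11
        assert is_connected(bb.mask)

    def test_matches_exhaustive_spanning_tree_enumeration(self):
        """5-node case: tree weight equals the max over all 125 labeled trees."""
        rng = np.random.default_rng(4)
        fc = random_fc(rng, 5)
        bb = mst_backbone(fc)
        got = fc.r[bb.mask].sum() / 2

        # Cayley: enumerate all 5^3 Prufer sequences -> all labeled trees
        best = -np.inf
        for seq in product(range(5), repeat=3):
            degree = [1] * 5
            for v in seq:
                degree[v] += 1
            seq_list = list(seq)
            weight = 0.0
            deg = degree[:]
            for v in seq_list:
                leaf = min(u for u in range(5) if deg[u] == 1)
                weight += fc.r[leaf, v]
                deg[leaf] -= 1
                deg[v] -= 1
            u, w = [x for x in range(5) if deg[x] == 1]
            weight += fc.r[u, w]
            best = max(best, weight)
        assert got == pytest.approx(best)

    def test_matches_networkx_maximum_spanning_tree_weight(self):
        fc = random_fc(np.random.default_rng(5), 15)
        bb = mst_backbone(fc)
        g = nx.Graph()
        for i in range(15):
            for j in range(i + 1, 15):
                g.add_edge(i, j, weight=fc.r[i, j])
        ref = nx.maximum_spanning_tree(g)
        assert fc.r[bb.mask].sum() / 2 == pytest.approx(
            ref.size(weight="weight"), rel=1e-12
        )

    def test_nonfinite_weights_rejected(self):
        fc = random_fc(np.random.default_rng(6), 4)
        fc.r[0, 1] = fc.r[1, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            mst_backbone(fc)


class TestDensify:
    def test_full_sparsity_gives_complete_graph(self):
        fc = random_fc(np.random.default_rng(7), 8)
        dense = densify_to_sparsity(fc, mst_backbone(fc), sparsity=1.0)
        assert dense.edge_count == 8 * 7 // 2

    def test_target_below_tree_returns_backbone(self):
        fc = random_fc(np.random.default_rng(8), 10)
        bb = mst_backbone(fc)
        dense = densify_to_sparsity(fc, bb, sparsity=0.01)  # ceil(0.45) = 1 < 9
        np.testing.assert_array_equal(dense.mask, bb.mask)

    def test_matches_sort_and_fill_oracle(self):
        """6-node, 50% sparsity: edge set equals an independently written ranker."""
        fc = random_fc(np.random.default_rng(9), 6)
        bb = mst_backbone(fc)
        dense = densify_to_sparsity(fc, bb, sparsity=0.5)

        target = int(np.ceil(0.5 * 15))
        chosen = {
            (i, j) for i in range(6) for j in range(i + 1, 6) if bb.mask[i, j]
        }
        candidates = sorted(
            (
                (i, j)
                for i in range(6)
                for j in range(i + 1, 6)
                if (i, j) not in chosen
            ),
            key=lambda e: (-fc.r[e], e),
        )
        for e in candidates:
            if len(chosen) == target:
                break
            chosen.add(e)
        got = {(i, j) for i in range(6) for j in range(i + 1, 6) if dense.mask[i, j]}
        assert got == chosen

    @pytest.mark.parametrize("n,sparsity", [(20, 0.1), (20, 0.3), (13, 0.25)])
    def test_structural_invariants(self, n, sparsity):
        fc = random_fc(np.random.default_rng(n), n)
        bb = mst_backbone(fc)
        dense = densify_to_sparsity(fc, bb, sparsity)
        assert (dense.mask | ~bb.mask).all()  # backbone subset of densified
        assert is_connected(dense.mask)
        assert dense.edge_count == max(n - 1, target_edge_count(n, sparsity))
        assert not dense.mask.diagonal().any()
        np.testing.assert_array_equal(dense.mask, dense.mask.T)

    def test_invariant_under_region_permutation(self):
        rng = np.random.default_rng(10)
        fc = random_fc(rng, 9)
        perm = rng.permutation(9)
        fc_p = FCMatrix(r=fc.r[np.ix_(perm, perm)])
        dense = densify_to_sparsity(fc, mst_backbone(fc), 0.3)
        dense_p = densify_to_sparsity(fc_p, mst_backbone(fc_p), 0.3)
        back = np.empty_like(dense_p.mask)
        back[np.ix_(perm, perm)] = dense_p.mask
        # tie-breaks depend on labels, but generic random weights have none
        np.testing.assert_array_equal(back, dense.mask)


class TestApplyMask:
    def test_complete_mask_returns_fc_with_zero_diagonal(self):
        fc = random_fc(np.random.default_rng(11), 6)
        dense = densify_to_sparsity(fc, mst_backbone(fc), 1.0)
        tw = apply_mask(fc, dense)
        expected = fc.r.copy()
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(tw.w, expected)

    def test_backbone_mask_keeps_exactly_tree_edges(self):
        fc = random_fc(np.random.default_rng(12), 7)
        bb = mst_backbone(fc)
        tw = apply_mask(fc, bb)
        assert np.count_nonzero(np.triu(tw.w, 1)) == 6

    def test_matches_elementwise_loop_oracle(self):
        fc = random_fc(np.random.default_rng(13), 5)
        dense = densify_to_sparsity(fc, mst_backbone(fc), 0.6)
        tw = apply_mask(fc, dense)
        for i in range(5):
            for j in range(5):
                expected = fc.r[i, j] * dense.mask[i, j] if i != j else 0.0
                assert tw.w[i, j] == pytest.approx(expected)

    def test_shape_mismatch_rejected(self):
        fc = random_fc(np.random.default_rng(14), 5)
        other = densify_to_sparsity(
            random_fc(np.random.default_rng(15), 6),
            mst_backbone(random_fc(np.random.default_rng(15), 6)),
            0.5,
        )
        with pytest.raises(ValueError, match="shapes differ"):
            apply_mask(fc, other)
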