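"""Weighted network, TOM, module detection, sign split, merge, pruning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielrhythm.network import (
    CoexpressionModule,
    NetworkConfig,
    NetworkError,
    apply_adjacency_threshold,
    build_modules,
    correlation_matrix,
    hierarchical_modules,
    merge_close_modules,
    module_representative,
    soft_adjacency,
    split_by_sign,
    topological_overlap,
)
from dielrhythm.preprocessing import zscore_rows
from dielrhythm.synthetic import OrganSpec, generate_organ_dataset


def _zdf(rows, ids=None):
    df = pd.DataFrame(rows, index=ids or [f"t{i}" for i in range(len(rows))])
    z, _ = zscore_rows(df)
    return z


class TestCorrelation:
    def test_self_and_negation(self):
        x = np.array([1.0, 2.0, 4.0, 3.0])
        df = pd.DataFrame([x, x, -x], index=["a", "b", "c"])
        corr = correlation_matrix(df)
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_random_rows_properties(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(30, 14)))
        corr = correlation_matrix(df)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        assert np.linalg.eigvalsh(corr).min() > -1e-8
        off = corr[~np.eye(30, dtype=bool)]
        assert np.quantile(np.abs(off), 0.95) < 0.8

    def test_constant_row_rejected(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["a", "flat"])
        with pytest.raises(NetworkError, match="flat"):
            correlation_matrix(df)


class TestSoftAdjacency:
    @pytest.mark.parametrize(
        "r, expected", [(1.0, 1.0), (0.0, 0.0), (0.9, 0.9**18)]
    )
    def test_point_values(self, r, expected):
        corr = np.array([[1.0, r], [r, 1.0]])
        adj = soft_adjacency(corr, 18)
        assert adj[0, 1] == pytest.approx(expected)
        assert adj[0, 0] == 0.0  # diagonal zeroed

    @given(
        r1=st.floats(-1, 1, allow_nan=False),
        r2=st.floats(-1, 1, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_monotone_in_abs_r_and_bounded(self, r1, r2):
        a = soft_adjacency(np.array([[1.0, r1], [r1, 1.0]]), 18)[0, 1]
        b = soft_adjacency(np.array([[1.0, r2], [r2, 1.0]]), 18)[0, 1]
        assert 0.0 <= a <= 1.0
        if abs(r1) <= abs(r2):
            assert a <= b + 1e-12


class TestTopologicalOverlap:
    def test_three_node_hand_computation(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        dissim = topological_overlap(a)
        # TOM12 = (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert dissim[0, 1] == pytest.approx(0.5)

    def test_perfectly_linked_pair(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        dissim = topological_overlap(a)
        assert dissim[0, 1] == pytest.approx(0.0)

    def test_empty_network(self):
        a = np.zeros((4, 4))
        dissim = topological_overlap(a)
        off = dissim[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_bounds_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(-1, 1, size=(20, 20))
        r = (r + r.T) / 2
        a = soft_adjacency(r, 6)
        d = topological_overlap(a)
        assert (d >= 0).all() and (d <= 1).all()
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(d), 0.0)

    def test_negative_entries_rejected(self):
        with pytest.raises(NetworkError):
            topological_overlap(np.array([[0.0, -0.1], [-0.1, 0.0]]))


class TestHierarchicalModules:
    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(2)
        t = np.arange(-2, 26, 2.0)
        block1 = [np.cos(2 * np.pi * t / 24) + rng.normal(0, 0.1, 14) for _ in range(15)]
        block2 = [np.cos(2 * np.pi * (t - 8) / 24) + rng.normal(0, 0.1, 14) for _ in range(15)]
        z = _zdf(block1 + block2)
        modules, adj, _ = build_modules(z, NetworkConfig(min_module_size=5), "L1")
        memberships = [set(m.member_ids) for m in modules]
        expected1 = {f"t{i}" for i in range(15)}
        expected2 = {f"t{i}" for i in range(15, 30)}
        assert expected1 in memberships and expected2 in memberships

    def test_all_identical_single_module(self):
        base = np.array([1.0, 2.0, 3.0, 2.0, 1.0, 0.5, 1.5, 2.5, 0.1, 0.6, 1.1, 2.1])
        z = _zdf([base + i * 0 for i in range(12)])
        d = np.zeros((12, 12))
        clusters, unassigned = hierarchical_modules(d, list(z.index), NetworkConfig())
        assert len(clusters) == 1 and not unassigned

    def test_too_few_all_unassigned(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        clusters, unassigned = hierarchical_modules(
            d, ["a", "b"], NetworkConfig(min_module_size=10)
        )
        assert clusters == {} and set(unassigned) == {"a", "b"}


class TestSplitBySign:
    def test_all_positive_single_group(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=10)
        z = _zdf([base + rng.normal(0, 0.05, 10) for _ in range(6)])
        groups = split_by_sign(z)
        assert set(groups) == {"plus"}
        assert len(groups["plus"]) == 6

    def test_x_and_minus_x(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        z = _zdf([x, -x], ids=["pos", "neg"])
        groups = split_by_sign(z)
        assert sorted(len(g) for g in groups.values()) == [1, 1]

    def test_antiphase_halves_recovered(self):
        rng = np.random.default_rng(4)
        t = np.arange(-2, 26, 2.0)
        up = [np.cos(2 * np.pi * t / 24) + rng.normal(0, 0.1, 14) for _ in range(8)]
        down = [-np.cos(2 * np.pi * t / 24) + rng.normal(0, 0.1, 14) for _ in range(8)]
        z = _zdf(up + down)
        groups = split_by_sign(z)
        sets = {k: set(v) for k, v in groups.items()}
        first_half = {f"t{i}" for i in range(8)}
        second_half = {f"t{i}" for i in range(8, 16)}
        assert sets.values() and set(map(frozenset, sets.values())) == {
            frozenset(first_half),
            frozenset(second_half),
        }


class TestRepresentative:
    def test_single_member(self):
        x = np.array([1.0, 2.0, 0.5, 3.0])
        df = pd.DataFrame([x], index=["a"])
        np.testing.assert_allclose(module_representative(df), x)

    def test_pointwise_median(self):
        s = np.array([0.0, 1.0, 2.0])
        t = np.array([10.0, -1.0, 5.0])
        df = pd.DataFrame([s, s, t])
        np.testing.assert_allclose(
            module_representative(df), np.median([s, s, t], axis=0)
        )

    def test_median_denoises_cosine(self, times):
        rng = np.random.default_rng(5)
        truth = np.cos(2 * np.pi * (times - 4) / 24)
        members = pd.DataFrame(
            [truth + rng.normal(0, 0.5, times.size) for _ in range(51)]
        )
        rep = module_representative(members)
        rms = np.sqrt(np.mean((rep - truth) ** 2))
        assert rms < 0.15


def _module(mid, ids, rep, sign="plus", organ="L1"):
    return CoexpressionModule(mid, organ, tuple(ids), sign, np.asarray(rep, float))


class TestMerge:
    def test_identical_representatives_merge(self):
        x = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 3.0])
        z = _zdf([x, x], ids=["a", "b"])
        mods = [
            _module("L1.M01+", ["a"], z.loc["a"].to_numpy()),
            _module("L1.M02+", ["b"], z.loc["b"].to_numpy()),
        ]
        merged = merge_close_modules(mods, 0.25, z)
        assert len(merged) == 1
        assert merged[0].module_id == "L1.M01+"
        assert set(merged[0].member_ids) == {"a", "b"}

    def test_anticorrelated_not_merged(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        z = _zdf([x, -x], ids=["a", "b"])
        mods = [
            _module("L1.M01+", ["a"], z.loc["a"].to_numpy()),
            _module("L1.M02-", ["b"], z.loc["b"].to_numpy(), sign="minus"),
        ]
        merged = merge_close_modules(mods, 0.25, z)
        assert len(merged) == 2  # dissimilarity ~2, far above 0.25

    def test_transitive_merge_by_recomputation(self, times):
        rng = np.random.default_rng(6)
        base = np.cos(2 * np.pi * times / 24)
        rows, ids = [], []
        for g in range(3):
            for i in range(5):
                rows.append(base + rng.normal(0, 0.15, times.size))
                ids.append(f"g{g}_{i}")
        z = _zdf(rows, ids=ids)
        mods = [
            _module(
                f"L1.M0{g + 1}+",
                [f"g{g}_{i}" for i in range(5)],
                module_representative(z.loc[[f"g{g}_{i}" for i in range(5)]]),
            )
            for g in range(3)
        ]
        merged = merge_close_modules(mods, 0.25, z)
        assert len(merged) == 1

    def test_merging_never_increases_count(self, small_multi_organ):
        ds = small_multi_organ["L1"]
        z, _ = zscore_rows(ds.matrix.values.iloc[:150])
        mods, adj, _ = build_modules(z, NetworkConfig(min_module_size=5), "L1")
        merged = merge_close_modules(mods, 0.25, z)
        assert len(merged) <= len(mods)


class TestAdjacencyThreshold:
    def _adj(self, ids, mat):
        return pd.DataFrame(np.asarray(mat, float), index=ids, columns=ids)

    def test_clique_fully_retained(self):
        ids = ["a", "b", "c"]
        a = np.ones((3, 3)) - np.eye(3)
        mods = [_module("M1", ids, np.arange(5.0))]
        out = apply_adjacency_threshold(mods, self._adj(ids, a), 0.175)
        assert out[0].member_ids == ("a", "b", "c")

    def test_isolated_member_pruned(self):
        ids = ["a", "b", "c"]
        a = np.array([[0, 1, 0.0], [1, 0, 0.0], [0.0, 0.0, 0]])
        mods = [_module("M1", ids, np.arange(5.0))]
        out = apply_adjacency_threshold(mods, self._adj(ids, a), 0.175)
        assert out[0].member_ids == ("a", "b")

    def test_boundary_value_retained(self):
        ids = ["a", "b"]
        a = np.array([[0.0, 0.175], [0.175, 0.0]])
        mods = [_module("M1", ids, np.arange(5.0))]
        out = apply_adjacency_threshold(mods, self._adj(ids, a), 0.175)
        assert out[0].member_ids == ("a", "b")

    def test_emptied_module_dropped(self):
        ids = ["a", "b"]
        a = np.zeros((2, 2))
        mods = [_module("M1", ids, np.arange(5.0))]
        assert apply_adjacency_threshold(mods, self._adj(ids, a), 0.175) == []


class TestPlantedStructureRecovery:
    def test_phase_groups_partition_with_high_ari(self, design):
        """Well-separated planted phase groups are recovered (ARI >= 0.8)."""
        spec = OrganSpec(
            n_transcripts=240,
            rhythmic_fraction=1.0,
            phase_law=((1 / 3, 0.0, 0.2), (1 / 3, 8.0, 0.2), (1 / 3, 16.0, 0.2)),
            noise_sd=0.25,
        )
        ds = generate_organ_dataset(design, spec, rng_seed=9)
        z, _ = zscore_rows(ds.matrix.values)
        cfg = NetworkConfig()
        mods, adj, _ = build_modules(z, cfg, "L1")
        mods = merge_close_modules(mods, cfg.merge_dissim_max, z)
        mods = apply_adjacency_threshold(mods, adj, cfg.adjacency_min)
        label = {}
        for i, m in enumerate(mods):
            for tid in m.member_ids:
                assert tid not in label  # each transcript in <= 1 module
                label[tid] = i
        truth = ds.truth
        group = (np.round(truth["true_phase_zt"] / 8).astype(int) % 3).to_dict()
        ids = [t for t in truth.index if t in label]
        assert len(ids) >= 0.8 * len(truth)
        a = pd.Series({t: group[t] for t in ids})
        b = pd.Series({t: label[t] for t in ids})
        assert _adjusted_rand(a, b) >= 0.8


def _adjusted_rand(a: pd.Series, b: pd.Series) -> float:
    from math import comb

    ct = pd.crosstab(a, b).to_numpy()
    nij = sum(comb(int(c), 2) for c in ct.ravel())
    ai = sum(comb(int(c), 2) for c in ct.sum(axis=1))
    bi = sum(comb(int(c), 2) for c in ct.sum(axis=0))
    n = int(ct.sum())
    expected = ai * bi / comb(n, 2)
    return (nij - expected) / ((ai + bi) / 2 - expected)
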