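import itertools

import numpy as np
import pandas as pd
import pytest

from mnm.core import BinIndex, CopyNumberMatrix, make_bins
from mnm.rt import (
    BinaryRTMatrix,
    binarize_s_cells,
    correlate_profiles,
    pseudobulk_rt,
    trajectory_permutation_test,
)
from mnm.synthetic import CloneSpec, RTSpec, make_s_population


def binary_matrix(values):
    values = np.asarray(values, dtype=float)
    bins = BinIndex(["chr1"] * values.shape[1],
                    np.arange(values.shape[1]) * 100_000,
                    (np.arange(values.shape[1]) + 1) * 100_000)
    cells = np.array([f"s{i}" for i in range(values.shape[0])], dtype=object)
    return BinaryRTMatrix(cells, bins, values)


class TestBinarize:
    def test_ratio_rules(self):
        bins = BinIndex(["chr1"] * 3, [0, 1, 2], [1, 2, 3])
        s = CopyNumberMatrix(np.array(["s"], dtype=object), bins,
                             np.array([[4.0, 2.0, 3.0]]))
        out = binarize_s_cells(s, np.array([2.0, 2.0, 2.0]))
        np.testing.assert_array_equal(out.values, [[1.0, 0.0, 1.0]])  # 2.0, 1.0, 1.5x

    def test_missing_stays_missing(self):
        bins = BinIndex(["chr1"] * 2, [0, 1], [1, 2])
        s = CopyNumberMatrix(np.array(["s"], dtype=object), bins,
                             np.array([[np.nan, 4.0]]))
        out = binarize_s_cells(s, np.array([2.0, 2.0]))
        assert np.isnan(out.values[0, 0]) and out.values[0, 1] == 1.0

    def test_zero_baseline_with_data_rejected(self):
        bins = BinIndex(["chr1"] * 2, [0, 1], [1, 2])
        s = CopyNumberMatrix(np.array(["s"], dtype=object), bins,
                             np.array([[2.0, 2.0]]))
        with pytest.raises(ValueError, match="baseline"):
            binarize_s_cells(s, np.array([0.0, 2.0]))

    @pytest.mark.parametrize("true_p", [0.2, 0.4, 0.6, 0.8])
    def test_progress_recovery(self, true_p):
        bins = make_bins({"chr1": 100_000_000}, 100_000)
        clone = CloneSpec("A", {}, 1, noise_rate=0.02)
        rt = RTSpec.random(len(bins), 1)
        s, _ = make_s_population(clone, rt, bins, 50, (true_p, true_p), seed=2)
        out = binarize_s_cells(s, np.full(len(bins), 2.0))
        measured = out.progress()
        assert np.abs(measured - true_p).max() <= 0.02


class TestPseudobulk:
    def test_all_replicated_is_one(self):
        profile = pseudobulk_rt(binary_matrix([[1, 1], [1, 1]]))
        np.testing.assert_array_equal(profile.values, [1.0, 1.0])

    def test_fractional(self):
        values = np.zeros((10, 1))
        values[:3, 0] = 1.0
        profile = pseudobulk_rt(binary_matrix(values))
        assert profile.values[0] == pytest.approx(0.3)

    def test_uninformative_bin_undefined(self):
        profile = pseudobulk_rt(binary_matrix([[1, np.nan], [0, np.nan]]))
        assert np.isnan(profile.values[1])

    def test_monotone_in_rt_order(self):
        bins = make_bins({"chr1": 30_000_000}, 100_000)
        clone = CloneSpec("A", {}, 1)
        rt = RTSpec.random(len(bins), 3)
        s, _ = make_s_population(clone, rt, bins, 200, (0.05, 0.95), seed=4)
        out = binarize_s_cells(s, np.full(len(bins), 2.0))
        profile = pseudobulk_rt(out)
        # earlier bins in rt_order must have >= RT values (ranks agree)
        rt_rank = np.empty(len(bins))
        rt_rank[rt.rt_order] = np.arange(len(bins))
        rho = pd.Series(profile.values).corr(pd.Series(-rt_rank), method="spearman")
        assert rho > 0.99


class TestCorrelations:
    def test_self_correlation_unit(self):
        bins = make_bins({"chr1": 1_000_000}, 100_000)
        rng = np.random.default_rng(0)
        v = rng.random(len(bins))
        from mnm.rt import RTProfile
        p = RTProfile(bins, v, name="a")
        q = RTProfile(bins, v.copy(), name="b")
        corr, order = correlate_profiles([p, q])
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert sorted(order) == [0, 1]

    def test_rank_reversal_anticorrelated(self):
        bins = make_bins({"chr1": 1_000_000}, 100_000)
        v = np.linspace(0, 1, len(bins))
        from mnm.rt import RTProfile
        corr, _ = correlate_profiles(
            [RTProfile(bins, v, "a"), RTProfile(bins, v[::-1].copy(), "b")])
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self):
        bins = make_bins({"chr1": 2_000_000}, 100_000)
        rng = np.random.default_rng(1)
        v = rng.random(len(bins))
        from mnm.rt import RTProfile
        corr1, _ = correlate_profiles(
            [RTProfile(bins, v, "a"), RTProfile(bins, np.sqrt(v), "b")])
        assert corr1.loc["a", "b"] == pytest.approx(1.0)

    def test_too_few_shared_bins(self):
        bins = make_bins({"chr1": 400_000}, 100_000)
        from mnm.rt import RTProfile
        a = RTProfile(bins, np.array([0.1, np.nan, np.nan, np.nan]), "a")
        b = RTProfile(bins, np.array([0.1, 0.2, 0.3, 0.4]), "b")
        with pytest.raises(ValueError, match="fewer than 3"):
            correlate_profiles([a, b])

    def test_shared_vs_shuffled_rt_orders(self):
        bins = make_bins({"chr1": 50_000_000}, 100_000)
        clone = CloneSpec("A", {}, 1)
        rt = RTSpec.random(len(bins), 5)
        rt_other = RTSpec.random(len(bins), 99)
        from mnm.rt import RTProfile
        profiles = {}
        for name, order, seed in [("x", rt, 6), ("y", rt, 7), ("z", rt_other, 8)]:
            s, _ = make_s_population(clone, order, bins, 150, (0.05, 0.95), seed=seed)
            out = binarize_s_cells(s, np.full(len(bins), 2.0))
            profiles[name] = pseudobulk_rt(out, name=name)
        corr, _ = correlate_profiles(list(profiles.values()))
        assert corr.loc["x", "y"] > 0.95
        assert abs(corr.loc["x", "z"]) < 0.2


def exhaustive_pvalue(xy, labels):
    """Exact permutation p-value by enumerating all label orderings."""
    def stat(lab):
        s = 0.0
        for g in np.unique(lab):
            s += abs(xy[lab == g, 0].mean() - xy[lab == g, 1].mean())
        return s

    observed = stat(labels)
    stats = [stat(np.array(perm)) for perm in
             set(itertools.permutations(labels.tolist()))]
    # same tie tolerance as the implementation under test
    tol = 1e-9 * max(1.0, abs(observed))
    return np.mean([s >= observed - tol for s in stats]), observed


class TestPermutationTest:
    def test_matches_exhaustive_enumeration_small(self):
        rng = np.random.default_rng(2)
        xy = rng.normal(size=(8, 2))
        xy[:4] += 2.0
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        coords = pd.DataFrame(
            {"coord1": xy[:, 0], "coord2": xy[:, 1], "group": labels})
        exact, observed = exhaustive_pvalue(xy, labels)
        result = trajectory_permutation_test(coords, n_perm=4000, seed=3)
        assert result["observed"] == pytest.approx(observed)
        assert result["p_value"] == pytest.approx(exact, abs=0.05)

    def test_add_one_lower_bound_for_separated_groups(self):
        rng = np.random.default_rng(4)
        a = rng.normal([0, 100], 0.1, size=(10, 2))
        b = rng.normal([0, -100], 0.1, size=(10, 2))
        coords = pd.DataFrame({
            "coord1": np.concatenate([a[:, 0], b[:, 0]]),
            "coord2": np.concatenate([a[:, 1], b[:, 1]]),
            "group": ["a"] * 10 + ["b"] * 10,
        })
        result = trajectory_permutation_test(coords, n_perm=1000, seed=5)
        assert result["p_value"] == pytest.approx(1 / 1001)

    def test_null_calibration(self):
        # unequal group sizes: with equal sizes the literal statistic is
        # piecewise constant over permutations and p concentrates high
        rng = np.random.default_rng(6)
        ps = []
        for rep in range(30):
            xy = rng.normal(size=(31, 2))
            coords = pd.DataFrame({"coord1": xy[:, 0], "coord2": xy[:, 1],
                                   "group": ["a"] * 14 + ["b"] * 17})
            ps.append(trajectory_permutation_test(
                coords, n_perm=199, seed=rep)["p_value"])
        assert 0.25 <= float(np.median(ps)) <= 0.75

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        xy = rng.normal(size=(12, 2))
        base = pd.DataFrame({"coord1": xy[:, 0], "coord2": xy[:, 1],
                             "group": ["a"] * 6 + ["b"] * 6})
        shifted = base.copy()
        shifted[["coord1", "coord2"]] += 17.5
        r1 = trajectory_permutation_test(base, n_perm=300, seed=8)
        r2 = trajectory_permutation_test(shifted, n_perm=300, seed=8)
        assert r1["p_value"] == r2["p_value"]

    def test_pvalue_bounds(self):
        rng = np.random.default_rng(9)
        xy = rng.normal(size=(10, 2))
        coords = pd.DataFrame({"coord1": xy[:, 0], "coord2": xy[:, 1],
                               "group": ["a"] * 5 + ["b"] * 5})
        for n_perm in (1, 10, 100):
            p = trajectory_permutation_test(coords, n_perm=n_perm, seed=10)["p_value"]
            assert 1 / (n_perm + 1) <= p <= 1.0

    def test_input_validation(self):
        coords = pd.DataFrame({"coord1": [0, 1], "coord2": [0, 1],
                               "group": ["a", "a"]})
        with pytest.raises(ValueError, match="two groups"):
            trajectory_permutation_test(coords)
        coords2 = pd.DataFrame({"coord1": [0, 1, 2], "coord2": [0, 1, 2],
                                "group": ["a", "a", "b"]})
        with pytest.raises(ValueError, match="at least two points"):
            trajectory_permutation_test(coords2)
        coords3 = pd.DataFrame({"coord1": [0, 1, 2, 3], "coord2": [0, 1, 2, 3],
                                "group": ["a", "a", "b", "b"]})
        with pytest.raises(ValueError, match="n_perm"):
            trajectory_permutation_test(coords3, n_perm=0)

    def test_centroid_alternative(self):
        rng = np.random.default_rng(11)
        a = rng.normal([5, 5], 0.1, size=(8, 2))
        b = rng.normal([-5, -5], 0.1, size=(8, 2))
        coords = pd.DataFrame({
            "coord1": np.concatenate([a[:, 0], b[:, 0]]),
            "coord2": np.concatenate([a[:, 1], b[:, 1]]),
            "group": ["a"] * 8 + ["b"] * 8,
        })
        # the literal cross-axis statistic cannot see this diagonal split;
        # the centroid variant can
        r = trajectory_permutation_test(coords, n_perm=500, seed=12,
                                        statistic="centroid")
        assert r["p_value"] == pytest.approx(1 / 501)
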