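import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as sk_permanova
from skbio.stats.distance import permdisp as sk_permdisp

from metaport.beta_diversity import (
    bray_curtis,
    compare_mean_dissimilarity,
    membership_patterns,
    membership_summary,
    nmds,
    permanova,
    permdisp,
    presence_by_locality,
    sorensen_between_localities,
    temporal_turnover,
    _centroid_distances,
    _pseudo_f,
)

from conftest import make_samples


def dm_from_points(x: np.ndarray) -> DistanceMatrix:
    return DistanceMatrix(
        squareform(pdist(x)), ids=[f"s{i}" for i in range(len(x))]
    )


class TestBrayCurtis:
    def test_hand_value(self):
        reads = pd.DataFrame(
            {"t1": [50, 25], "t2": [50, 75]}, index=["x", "y"]
        )
        dm = bray_curtis(reads)
        # x=(0.5,0.5), y=(0.25,0.75): 1 - 2*(0.25+0.5) / 2 = 0.25
        assert dm["x", "y"] == pytest.approx(0.25)

    def test_disjoint_supports_are_one(self):
        reads = pd.DataFrame({"t1": [10, 0], "t2": [0, 7]}, index=["x", "y"])
        assert bray_curtis(reads)["x", "y"] == pytest.approx(1.0)

    def test_identical_rows_are_zero(self):
        reads = pd.DataFrame({"t1": [3, 6], "t2": [5, 10]}, index=["x", "y"])
        assert bray_curtis(reads)["x", "y"] == pytest.approx(0.0)

    def test_zero_sum_row_errors(self):
        reads = pd.DataFrame({"t1": [0, 1], "t2": [0, 1]}, index=["x", "y"])
        with pytest.raises(ValueError, match="x"):
            bray_curtis(reads)

    def test_metric_axioms_on_random_data(self):
        rng = np.random.default_rng(0)
        reads = pd.DataFrame(rng.integers(0, 50, (8, 12)) + 1)
        dm = bray_curtis(reads)
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0)
        assert dm.data.max() <= 1.0 and dm.data.min() >= 0.0


class TestSorensen:
    def test_set_arithmetic(self):
        presence = pd.DataFrame(
            {"A": [1, 1, 1, 0], "B": [0, 1, 1, 1]},
            index=["m1", "m2", "m3", "m4"],
        )
        table, mean = sorensen_between_localities(presence)
        assert table["sorensen"].iloc[0] == pytest.approx(4 / 6)
        assert mean == pytest.approx(4 / 6)

    @pytest.mark.parametrize(
        "a, b, expected", [([1, 1], [1, 1], 1.0), ([1, 0], [0, 1], 0.0)]
    )
    def test_identical_and_disjoint(self, a, b, expected):
        presence = pd.DataFrame({"A": a, "B": b})
        _, mean = sorensen_between_localities(presence)
        assert mean == pytest.approx(expected)

    def test_empty_locality_errors(self):
        presence = pd.DataFrame({"A": [1, 1], "B": [0, 0]})
        with pytest.raises(ValueError, match="B"):
            sorensen_between_localities(presence)


class TestMembershipPatterns:
    def test_counts_partition_total(self):
        rng = np.random.default_rng(3)
        presence = pd.DataFrame(
            rng.integers(0, 2, (40, 4)), columns=list("ABCD")
        )
        presence = presence[presence.sum(axis=1) > 0]
        patterns = membership_patterns(presence)
        assert patterns["count"].sum() == len(presence)

    def test_everywhere_motu_in_full_cell_only(self):
        presence = pd.DataFrame(
            {"A": [1, 1], "B": [1, 0], "C": [1, 0], "D": [1, 0]},
            index=["m_all", "m_a"],
        )
        patterns = membership_patterns(presence)
        full = patterns[patterns["localities"] == "A+B+C+D"]
        assert full["count"].iloc[0] == 1
        summary = membership_summary(patterns, 4)
        assert summary["fraction_everywhere"] == pytest.approx(0.5)
        assert summary["fraction_unique"] == pytest.approx(0.5)


class TestNMDS:
    def test_equilateral_points_embed_with_near_zero_stress(self):
        dm = DistanceMatrix(
            np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
            ids=["a", "b", "c"],
        )
        res = nmds(dm, seed=0)
        assert res.stress < 0.01

    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 2))
        res = nmds(dm_from_points(pts), seed=1)
        assert res.stress < 0.02

    def test_same_seed_identical_configuration(self):
        rng = np.random.default_rng(6)
        dm = dm_from_points(rng.normal(size=(8, 4)))
        a = nmds(dm, seed=3)
        b = nmds(dm, seed=3)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress


def exhaustive_permanova_p(dm: DistanceMatrix, labels: list[str]) -> float:
    """Brute-force p over all distinct label orderings."""
    d2 = dm.data**2
    codes, uniques = pd.factorize(pd.Series(labels))
    f_obs = _pseudo_f(d2, codes, len(uniques))
    count = total = 0
    for perm in set(itertools.permutations(codes)):
        total += 1
        if _pseudo_f(d2, np.array(perm), len(uniques)) >= f_obs - 1e-12:
            count += 1
    return count / total


class TestPermanova:
    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 3))
        x[6:] += 1.5
        dm = dm_from_points(x)
        labels = ["a"] * 6 + ["b"] * 6
        mine = permanova(dm, labels, n_perm=99, seed=0)
        theirs = sk_permanova(dm, grouping=labels, permutations=9)
        assert mine.statistic == pytest.approx(
            float(theirs["test statistic"]), rel=1e-10
        )

    def test_minimal_p_for_separated_clusters(self):
        # groups big enough that no permutation recreates the split
        rng = np.random.default_rng(8)
        x = rng.normal(scale=0.05, size=(24, 2))
        x[12:] += 10
        dm = dm_from_points(x)
        res = permanova(dm, ["a"] * 12 + ["b"] * 12, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_matches_exhaustive_enumeration_at_tiny_n(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(6, 2))
        x[3:] += 1.0
        dm = dm_from_points(x)
        labels = ["a", "a", "a", "b", "b", "b"]
        exact = exhaustive_permanova_p(dm, labels)
        res = permanova(dm, labels, n_perm=4999, seed=1)
        # Monte-Carlo estimate with the +1 convention vs exact fraction
        se = math.sqrt(exact * (1 - exact) / 4999)
        assert abs(res.p_value - exact) < 3 * se + 1 / 5000

    def test_single_group_errors(self):
        dm = dm_from_points(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError):
            permanova(dm, ["a"] * 4)


class TestPermdisp:
    def test_statistic_matches_skbio_centroid(self):
        rng = np.random.default_rng(10)
        x = np.vstack([rng.normal(0, 0.5, (6, 3)), rng.normal(0, 3.0, (6, 3))])
        dm = dm_from_points(x)
        labels = ["a"] * 6 + ["b"] * 6
        mine = permdisp(dm, labels, n_perm=99, seed=0)
        theirs = sk_permdisp(dm, grouping=labels, permutations=9, test="centroid")
        assert mine.statistic == pytest.approx(
            float(theirs["test statistic"]), rel=1e-6
        )

    def test_duplicated_points_have_zero_centroid_distance(self):
        x = np.vstack([np.tile([1.0, 2.0], (3, 1)), np.random.default_rng(1).normal(size=(3, 2))])
        dm = dm_from_points(x)
        codes = np.array([0, 0, 0, 1, 1, 1])
        dists = _centroid_distances(dm, codes, 2)
        assert np.allclose(dists[:3], 0, atol=1e-9)
        assert dists[3:].min() > 0

    def test_matches_exhaustive_permutation_at_tiny_n(self):
        rng = np.random.default_rng(11)
        x = np.vstack([rng.normal(0, 0.2, (3, 2)), rng.normal(0, 2.0, (3, 2))])
        dm = dm_from_points(x)
        labels = pd.Series(["a", "a", "a", "b", "b", "b"], index=list(dm.ids))
        codes = np.array([0, 0, 0, 1, 1, 1])
        dists = _centroid_distances(dm, codes, 2)
        from scipy import stats

        f_obs = stats.f_oneway(dists[:3], dists[3:]).statistic
        count = total = 0
        for perm in set(itertools.permutations(range(6))):
            d = dists[list(perm)]
            total += 1
            if stats.f_oneway(d[:3], d[3:]).statistic >= f_obs - 1e-12:
                count += 1
        exact = count / total
        res = permdisp(dm, labels, n_perm=4999, seed=2)
        se = math.sqrt(exact * (1 - exact) / 4999)
        assert abs(res.p_value - exact) < 3 * se + 1 / 5000


class TestTemporalTurnover:
    def _setup(self, reads_by_sample):
        spec = [
            (s, "A", t, r, "true_sample")
            for s, t, r in [
                ("a1", 1, 1),
                ("a2", 1, 2),
                ("b1", 2, 1),
                ("b2", 2, 2),
            ]
        ]
        samples = make_samples(spec)
        reads = pd.DataFrame(reads_by_sample).T
        return bray_curtis(reads), samples

    def test_identical_communities_zero(self):
        dm, samples = self._setup(
            {"a1": [5, 5], "a2": [5, 5], "b1": [5, 5], "b2": [5, 5]}
        )
        out = temporal_turnover(dm, samples)
        assert out["mean_dissimilarity"].iloc[0] == pytest.approx(0.0)

    def test_complete_replacement_one(self):
        dm, samples = self._setup(
            {"a1": [5, 0], "a2": [5, 0], "b1": [0, 5], "b2": [0, 5]}
        )
        out = temporal_turnover(dm, samples)
        assert out["mean_dissimilarity"].iloc[0] == pytest.approx(1.0)

    def test_mean_of_cross_pairs(self):
        dm, samples = self._setup(
            {"a1": [10, 0], "a2": [5, 5], "b1": [0, 10], "b2": [5, 5]}
        )
        expected = np.mean(
            [dm["a1", "b1"], dm["a1", "b2"], dm["a2", "b1"], dm["a2", "b2"]]
        )
        out = temporal_turnover(dm, samples)
        assert out["mean_dissimilarity"].iloc[0] == pytest.approx(expected)


class TestCompareMeanDissimilarity:
    def test_equal_matrices_t_zero_p_one(self):
        dm = dm_from_points(np.random.default_rng(1).normal(size=(6, 2)))
        res = compare_mean_dissimilarity(dm, dm)
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_shift_highly_significant(self):
        rng = np.random.default_rng(2)
        dm1 = dm_from_points(rng.normal(size=(10, 2)))
        shifted = np.clip(dm1.data + 0.1, 0, None)
        np.fill_diagonal(shifted, 0)
        dm2 = DistanceMatrix(shifted, ids=list(dm1.ids))
        res = compare_mean_dissimilarity(dm2, dm1)
        assert res.p_value < 1e-3
        assert res.mean_1 == pytest.approx(res.mean_2 + 0.1)

    def test_mismatched_ids_error(self):
        dm1 = dm_from_points(np.random.default_rng(3).normal(size=(4, 2)))
        dm2 = DistanceMatrix(dm1.data, ids=["x0", "x1", "x2", "x3"])
        with pytest.raises(ValueError):
            compare_mean_dissimilarity(dm1, dm2)


def test_presence_by_locality_pools_over_samples(sim_cascade):
    presence = presence_by_locality(
        sim_cascade.motus.reads, sim_cascade.samples
    )
    loc = sim_cascade.samples.localities[0]
    cols = sim_cascade.samples.samples_of(loc)
    cols = [c for c in cols if c in sim_cascade.motus.reads.columns]
    manual = (sim_cascade.motus.reads[cols].sum(axis=1) > 0).astype(int)
    assert presence[loc].equals(manual)
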