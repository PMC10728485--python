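import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stimflow.change_similarity import (
    ALL_CLUSTER,
    ChangeScoreMatrix,
    ClusterTimeMeans,
    change_score,
    cluster_time_means,
    group_by_change,
    pattern_minmax,
    similarity_score,
)
from stimflow.io_core import TimepointDesign
from tests.conftest import make_dataset


def means_from_profiles(profiles: dict, timepoints=None):
    """Build a ClusterTimeMeans for one gene from {cluster: profile}."""
    clusters = [c for c in profiles if c != ALL_CLUSTER] + [ALL_CLUSTER]
    n_t = len(next(iter(profiles.values())))
    tps = timepoints or [f"t{i}" for i in range(n_t)]
    values = np.array([[profiles[c] for c in clusters]], dtype=float)
    return ClusterTimeMeans(values=values, gene_names=["g"], clusters=clusters,
                            timepoints=tps)


class TestClusterTimeMeans:
    def test_toy_fixture_matches_hand_means(self):
        # 6 cells, 2 clusters x 2 timepoints, hand-computable means
        mat = np.array([[1.0], [3.0], [5.0], [7.0], [0.0], [1.0]])
        # unit-norm rows so state l2 is honest
        mat = np.hstack([mat, np.sqrt(np.maximum(0, 64 - mat**2))]) / 8.0
        ds = make_dataset(
            mat,
            time=["t0", "t0", "t0", "t0", "t1", "t1"],
            cluster=["A", "A", "B", "B", "A", "B"],
            state="l2",
        )
        means = cluster_time_means(ds, TimepointDesign(("t0", "t1")))
        gi = 0
        ai, bi = means.clusters.index("A"), means.clusters.index("B")
        all_i = means.clusters.index(ALL_CLUSTER)
        assert means.values[gi, ai, 0] == pytest.approx((1 + 3) / 2 / 8)
        assert means.values[gi, bi, 0] == pytest.approx((5 + 7) / 2 / 8)
        assert means.values[gi, ai, 1] == pytest.approx(0.0)
        assert means.values[gi, bi, 1] == pytest.approx(1 / 8)
        assert means.values[gi, all_i, 0] == pytest.approx((1 + 3 + 5 + 7) / 4 / 8)

    def test_single_cell_groups(self):
        mat = np.array([[0.6, 0.8], [1.0, 0.0]])
        ds = make_dataset(mat, time=["t0", "t1"], cluster=["A", "A"], state="l2")
        means = cluster_time_means(ds, TimepointDesign(("t0", "t1")))
        ai = means.clusters.index("A")
        assert np.allclose(means.values[:, ai, 0], [0.6, 0.8])

    def test_empty_group_errors(self):
        mat = np.ones((2, 2)) / np.sqrt(2)
        ds = make_dataset(mat, time=["t0", "t0"], cluster=["A", "B"], state="l2")
        with pytest.raises(ValueError, match="empty"):
            cluster_time_means(ds, TimepointDesign(("t0", "t1")))

    def test_requires_l2(self):
        ds = make_dataset(np.ones((2, 2)), time=["t0", "t1"], cluster=["A", "A"])
        with pytest.raises(ValueError, match="l2"):
            cluster_time_means(ds, TimepointDesign(("t0", "t1")))


class TestChangeScore:
    def test_constant_profile_zero(self):
        m = means_from_profiles({"A": [0.3, 0.3, 0.3, 0.3], ALL_CLUSTER: [0, 1, 0, 1]})
        assert change_score(m).scores.loc["g", "A"] == 0.0

    def test_forced_example(self):
        m = means_from_profiles({"A": [0.0, 1.0, 0.0, 2.0], ALL_CLUSTER: [0, 0, 0, 0]})
        assert change_score(m).scores.loc["g", "A"] == pytest.approx(4.0)

    def test_four_timepoints_three_summands(self):
        m = means_from_profiles({"A": [1.0, 2.0, 3.0, 4.0], ALL_CLUSTER: [0, 0, 0, 0]})
        assert m.n_intervals == 3
        assert change_score(m).scores.loc["g", "A"] == pytest.approx(3.0)

    def test_shift_invariance(self):
        a = means_from_profiles({"A": [0.1, 0.7, 0.2, 0.9], ALL_CLUSTER: [0, 0, 0, 0]})
        b = means_from_profiles(
            {"A": [5.1, 5.7, 5.2, 5.9], ALL_CLUSTER: [0, 0, 0, 0]}
        )
        assert change_score(a).scores.loc["g", "A"] == pytest.approx(
            change_score(b).scores.loc["g", "A"]
        )

    def test_nonnegative_and_zero_iff_constant(self, rng):
        vals = rng.normal(size=(10, 3, 4))
        m = ClusterTimeMeans(values=vals, gene_names=[f"g{i}" for i in range(10)],
                             clusters=["A", "B", ALL_CLUSTER],
                             timepoints=["t0", "t1", "t2", "t3"])
        c = change_score(m).scores.to_numpy()
        assert (c >= 0).all()
        assert (c > 0).all()  # random profiles are almost surely non-constant


class TestGroupByChange:
    def _scores(self, rows, genes=None):
        genes = genes or [f"g{i}" for i in range(len(rows))]
        return ChangeScoreMatrix(
            scores=pd.DataFrame(np.asarray(rows, dtype=float), index=genes,
                                columns=["A", "B"])
        )

    def test_duplicate_rows_same_group(self):
        s = self._scores([[1, 2], [1, 2], [8, 9]])
        g = group_by_change(s, threshold=0.5)
        assert g["g0"] == g["g1"] != g["g2"]

    def test_cut_above_root_single_group(self):
        s = self._scores([[0, 0], [1, 1], [5, 5]])
        assert group_by_change(s, threshold=1e6).nunique() == 1

    def test_two_tight_bunches_match_single_linkage_oracle(self):
        rows = [[0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [5.0, 5.0], [5.1, 5.0]]
        s = self._scores(rows)
        g = group_by_change(s, threshold=2.0, linkage="single")
        # brute-force single-linkage: the two bunches merge internally at
        # <= 0.15 and between bunches only at ~7, so a cut at 2 gives 2 groups
        assert g.nunique() == 2
        assert g["g0"] == g["g1"] == g["g2"]
        assert g["g3"] == g["g4"]
        # size-descending ids: bunch of 3 is group 1
        assert g["g0"] == 1 and g["g3"] == 2

    def test_single_gene_errors(self):
        with pytest.raises(ValueError):
            group_by_change(self._scores([[1, 2]]))


class TestPatternMinmax:
    def test_forced_example(self):
        m = means_from_profiles({"A": [2.0, 4.0, 6.0, 4.0], ALL_CLUSTER: [0, 1, 2, 3]})
        p = pattern_minmax(m)
        ai = p.clusters.index("A")
        assert np.allclose(p.values[0, ai], [0.0, 0.5, 1.0, 0.5])
        assert not p.degenerate[0, ai]

    def test_degenerate_constant_profile(self):
        m = means_from_profiles({"A": [3.0, 3.0, 3.0], ALL_CLUSTER: [0, 1, 2]})
        p = pattern_minmax(m)
        ai = p.clusters.index("A")
        assert p.degenerate[0, ai]
        assert np.allclose(p.values[0, ai], 0.0)

    def test_attains_both_extremes(self, rng):
        for _ in range(10):
            prof = rng.normal(size=4)
            m = means_from_profiles({"A": prof.tolist(), ALL_CLUSTER: [0, 0, 0, 1]})
            p = pattern_minmax(m)
            ai = p.clusters.index("A")
            assert p.values[0, ai].min() == pytest.approx(0.0)
            assert p.values[0, ai].max() == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        prof = rng.normal(size=4)
        a = pattern_minmax(means_from_profiles(
            {"A": prof.tolist(), ALL_CLUSTER: [0, 0, 0, 1]}))
        b = pattern_minmax(means_from_profiles(
            {"A": (2.5 * prof + 7).tolist(), ALL_CLUSTER: [0, 0, 0, 1]}))
        ai = a.clusters.index("A")
        assert np.allclose(a.values[0, ai], b.values[0, ai])


class TestSimilarityScore:
    def test_identical_profiles_score_one(self):
        m = means_from_profiles({"A": [0.0, 2.0, 1.0, 3.0],
                                 ALL_CLUSTER: [0.0, 2.0, 1.0, 3.0]})
        s = similarity_score(pattern_minmax(m))
        assert s.scores.loc["g", "A"] == pytest.approx(1.0)

    def test_maximal_disagreement_scores_zero(self):
        m = means_from_profiles({"A": [1.0, 0.0, 1.0, 0.0],
                                 ALL_CLUSTER: [0.0, 1.0, 0.0, 1.0]})
        s = similarity_score(pattern_minmax(m))
        assert s.scores.loc["g", "A"] == pytest.approx(0.0)

    def test_matches_hand_evaluation(self, rng):
        prof_a = rng.random(4)
        prof_all = rng.random(4)
        m = means_from_profiles({"A": prof_a.tolist(), ALL_CLUSTER: prof_all.tolist()})
        s = similarity_score(pattern_minmax(m)).scores.loc["g", "A"]

        def mm(v):
            return (v - v.min()) / (v.max() - v.min())

        expect = 1.0 - np.abs(mm(prof_all) - mm(prof_a)).sum() / 4.0
        assert s == pytest.approx(expect)


@settings(max_examples=40, deadline=None)
@given(
    st.lists(st.floats(-10, 10), min_size=4, max_size=4),
    st.lists(st.floats(-10, 10), min_size=4, max_size=4),
)
def test_similarity_always_in_unit_interval(prof_a, prof_all):
    m = means_from_profiles({"A": prof_a, ALL_CLUSTER: prof_all})
    s = similarity_score(pattern_minmax(m)).scores.loc["g", "A"]
    assert 0.0 - 1e-12 <= s <= 1.0 + 1e-12
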