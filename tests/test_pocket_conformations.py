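"""State classification, PCA reduction, density clustering, representatives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lovspec as lv
from lovspec.errors import DefinitionError, DegenerateInputError, UsageError
from lovspec.pocket_conformations import cluster_density, label_clusters


def _table(values, cols=("d1",)):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape[0] == 1 and len(cols) == 1:
        arr = arr.T
    return pd.DataFrame(arr, columns=list(cols))


class TestClassifyStates:
    def test_threshold_rules(self):
        table = _table([3.5, 6.0, 4.5])
        s = lv.classify_states(table, {"Q489": "d1"})
        assert list(s.states["Q489"]) == ["in", "out", "intermediate"]
        assert list(s.frame_class) == ["IN", "OUT", "unassigned"]

    def test_intermediate_with_in_partner_is_unassigned(self):
        table = pd.DataFrame({"d1": [3.0], "d2": [4.5]})
        s = lv.classify_states(table, {"Q489": "d1", "N468": "d2"})
        assert s.frame_class.iloc[0] == "unassigned"

    def test_out_dominates_frame_class(self):
        table = pd.DataFrame({"d1": [4.5], "d2": [6.0]})
        s = lv.classify_states(table, {"Q489": "d1", "N468": "d2"})
        assert s.frame_class.iloc[0] == "OUT"

    def test_unknown_column_rejected(self):
        with pytest.raises(DefinitionError):
            lv.classify_states(_table([3.0]), {"Q489": "nope"})

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        d=st.floats(min_value=1.5, max_value=12.0),
        delta=st.floats(min_value=0.0, max_value=6.0),
    )
    def test_monotone_in_distance(self, d, delta):
        # increasing a distance can never move the state toward 'in'
        order = {"in": 0, "intermediate": 1, "out": 2}
        s1 = lv.classify_states(_table([d]), {"r": "d1"}).states["r"].iloc[0]
        s2 = lv.classify_states(_table([d + delta]), {"r": "d1"}).states["r"].iloc[0]
        assert order[s2] >= order[s1]


class TestPCA:
    def test_single_varying_feature(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"d1": rng.normal(3, 0.5, 200), "d2": np.full(200, 4.0)})
        model = lv.fit_pca(table, ["d1", "d2"], 0.9)
        assert model.n_components == 1
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)
        assert abs(model.components[0, 0]) == pytest.approx(1.0)

    def test_known_covariance_eigenstructure(self):
        # cov [[2,1],[1,2]] has eigenvalues 3 and 1: explained fractions 3/4, 1/4
        rng = np.random.default_rng(1)
        x = rng.multivariate_normal([0, 0], [[2, 1], [1, 2]], size=200_00)
        table = pd.DataFrame(x, columns=["d1", "d2"])
        model = lv.fit_pca(table, ["d1", "d2"], 1.0)
        assert model.explained_variance_ratio[0] == pytest.approx(0.75, abs=0.01)
        assert model.explained_variance_ratio[1] == pytest.approx(0.25, abs=0.01)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        model = lv.fit_pca(table, list("abcd"), 1.0)
        x = table.to_numpy()
        back = model.inverse_transform(model.transform(table))
        assert np.abs(back - x).max() < 1e-8

    def test_components_orthonormal(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.normal(size=(300, 5)), columns=list("abcde"))
        model = lv.fit_pca(table, list("abcde"), 1.0)
        gram = model.components @ model.components.T
        assert np.abs(gram - np.eye(len(gram))).max() < 1e-10

    def test_zero_variance_rejected(self):
        table = pd.DataFrame({"d1": np.full(50, 2.9)})
        with pytest.raises(DegenerateInputError):
            lv.fit_pca(table, ["d1"], 0.9)


class TestClusterDensity:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, size=(500, 2))
        b = rng.normal(10.0, 1.0, size=(500, 2))  # 10 sigma separation
        data = np.vstack([a, b])
        truth = np.repeat([0, 1], 500)
        labels, summaries = cluster_density(data, min_cluster_size=25)
        assert len(summaries) == 2
        # match recovered ids to planted blobs by majority vote
        correct = 0
        for planted in (0, 1):
            ids, counts = np.unique(labels[truth == planted], return_counts=True)
            correct += counts.max()
        assert correct / len(truth) >= 0.99

    def test_identical_points_form_single_cluster(self):
        labels, summaries = cluster_density(np.zeros((100, 2)), min_cluster_size=5)
        assert len(summaries) == 1
        assert (labels == 0).all()
        assert summaries[0].population == 1.0

    def test_population_floor_removes_small_blob(self):
        rng = np.random.default_rng(8)
        big = rng.normal(0.0, 1.0, size=(995, 2))
        blob = rng.normal(20.0, 0.1, size=(5, 2))  # 0.5% of frames
        labels, summaries = cluster_density(
            np.vstack([big, blob]), min_cluster_size=3, min_population=0.01
        )
        assert all(s.population >= 0.01 for s in summaries)
        assert (labels[995:] == -1).all()

    def test_populations_and_noise_sum_to_one(self):
        rng = np.random.default_rng(9)
        data = np.vstack([rng.normal(0, 1, (300, 2)), rng.normal(8, 1, (200, 2))])
        labels, summaries = cluster_density(data, min_cluster_size=20)
        total = sum(s.population for s in summaries) + np.mean(labels == -1)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_min_cluster_size_validated(self):
        with pytest.raises(UsageError):
            cluster_density(np.zeros((10, 2)), min_cluster_size=1)


class TestLabelClusters:
    def _states(self, frame_classes):
        n = len(frame_classes)
        df = pd.DataFrame({"Q489": ["in"] * n})
        return lv.StateSeries(df, pd.Series(frame_classes), 4.0, 5.0)

    def test_majority_in(self):
        fc = ["IN"] * 95 + ["OUT"] * 5
        labels = np.zeros(100, dtype=int)
        summ = [lv.ClusterSummary(0, 1.0, n_frames=100)]
        assert label_clusters(summ, labels, self._states(fc))[0].label == "IN"

    def test_all_out(self):
        fc = ["OUT"] * 40
        summ = [lv.ClusterSummary(0, 1.0, n_frames=40)]
        assert label_clusters(summ, np.zeros(40, int), self._states(fc))[0].label == "OUT"

    def test_tie_is_unassigned(self):
        fc = ["IN"] * 20 + ["OUT"] * 20
        summ = [lv.ClusterSummary(0, 1.0, n_frames=40)]
        assert label_clusters(summ, np.zeros(40, int), self._states(fc))[0].label == "unassigned"


class TestRepresentatives:
    def test_small_cluster_returns_all_frames(self):
        labels = np.array([0] * 7 + [-1] * 3)
        summ = [lv.ClusterSummary(0, 0.7, n_frames=7)]
        out = lv.sample_representatives(summ, labels, n_per_cluster=10, seed=0)
        assert out[0].representatives == list(range(7))

    def test_same_seed_reproducible(self):
        labels = np.arange(200) % 2
        summ = [lv.ClusterSummary(0, 0.5, n_frames=100), lv.ClusterSummary(1, 0.5, n_frames=100)]
        a = lv.sample_representatives(summ, labels, 10, seed=4)
        b = lv.sample_representatives(summ, labels, 10, seed=4)
        assert [s.representatives for s in a] == [s.representatives for s in b]

    def test_sampling_is_uniform(self):
        # each of 100 frames should be picked with frequency 10/100 = 10% +- 1%
        labels = np.zeros(100, dtype=int)
        summ = [lv.ClusterSummary(0, 1.0, n_frames=100)]
        counts = np.zeros(100)
        n_resample = 10_000
        for seed in range(n_resample):
            out = lv.sample_representatives(summ, labels, 10, seed=seed)
            counts[out[0].representatives] += 1
        freqs = counts / n_resample
        assert np.all(np.abs(freqs - 0.10) < 0.01)


class TestParameterRecovery:
    def test_planted_populations_recovered(self, planted_config):
        """Three planted classes at 78/17/5% are recovered within 5 points and
        the 0.5% decoy blob is removed by the 1% population filter."""
        frames, table, truth = lv.generate_pocket_trajectory(planted_config)
        model = lv.fit_pca(table, list(table.columns), 0.99)
        labels, summaries = cluster_density(
            model.transform(table), min_cluster_size=10, features=table
        )
        assert len(summaries) == 3
        expected = sorted([0.775, 0.17, 0.05], reverse=True)
        got = sorted([s.population for s in summaries], reverse=True)
        for e, g in zip(expected, got):
            assert g == pytest.approx(e, abs=0.05)
        # the decoy blob is found by HDBSCAN but removed by the 1% filter,
        # so its frames end up labeled noise
        blob_frames = truth.class_labels == "C_blob"
        assert np.mean(labels[blob_frames] == -1) > 0.5
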