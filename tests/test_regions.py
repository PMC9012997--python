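"""Ward regionalization: imputation, clustering, k selection, representatives."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from otevents import regions, simulate


def ward_bruteforce(X):
    """O(n^3) agglomeration oracle: repeatedly merge the cluster pair with
    the smallest within-cluster variance increase.

    Returns the list of partitions (as frozensets of member tuples) after
    each merge, plus the scipy-convention merge heights sqrt(2 * dSSE).
    """
    clusters = {i: [i] for i in range(len(X))}
    partitions = []
    heights = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                ca = X[clusters[a]].mean(axis=0)
                cb = X[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                d_sse = na * nb / (na + nb) * float(((ca - cb) ** 2).sum())
                if best is None or d_sse < best[0]:
                    best = (d_sse, a, b)
        d_sse, a, b = best
        clusters[a] = clusters[a] + clusters.pop(b)
        heights.append(np.sqrt(2 * d_sse))
        partitions.append(
            frozenset(frozenset(m) for m in (tuple(v) for v in clusters.values()))
        )
    return partitions, heights


def _feature_matrix(X, ids=None):
    ids = ids or [f"S{i:02d}" for i in range(len(X))]
    return regions.FeatureMatrix(ids, np.asarray(X, float),
                                 pd.DataFrame(columns=["station_id", "date", "value"]))


class TestImputation:
    def test_network_mean_fill(self):
        dates = pd.date_range("2010-04-01", periods=3, freq="D")
        wide = pd.DataFrame(
            {"A": [np.nan, 5.0, 6.0], "B": [10.0, 5.0, 6.0], "C": [20.0, 5.0, 6.0]},
            index=dates,
        )
        out, log = regions.impute_daily_means(wide)
        assert out.loc[dates[0], "A"] == pytest.approx(15.0)
        assert len(log) == 1

    def test_identity_when_complete(self):
        dates = pd.date_range("2010-04-01", periods=4, freq="D")
        wide = pd.DataFrame({"A": [1.0, 2, 3, 4], "B": [4.0, 3, 2, 1]}, index=dates)
        out, log = regions.impute_daily_means(wide)
        pd.testing.assert_frame_equal(out, wide)
        assert log.empty

    def test_all_missing_date_raises(self):
        dates = pd.date_range("2010-04-01", periods=2, freq="D")
        wide = pd.DataFrame({"A": [np.nan, 1.0], "B": [np.nan, 2.0]}, index=dates)
        with pytest.raises(ValueError, match="all stations missing"):
            regions.impute_daily_means(wide)

    def test_imputed_count_equals_missing_count(self):
        rng = np.random.default_rng(0)
        dates = pd.date_range("2010-04-01", periods=50, freq="D")
        wide = pd.DataFrame(rng.normal(size=(50, 4)), index=dates,
                            columns=list("ABCD"))
        mask = rng.uniform(size=wide.shape) < 0.1
        mask[mask.all(axis=1)] = False
        wide = wide.mask(mask)
        out, log = regions.impute_daily_means(wide)
        assert len(log) == int(mask.sum())
        assert not out.isna().any().any()


class TestFeatureMatrix:
    def test_blocks_standardized_and_concatenated(self):
        rng = np.random.default_rng(1)
        dates = pd.date_range("2010-04-01", periods=100, freq="D")
        tx = pd.DataFrame(rng.normal(15, 5, (100, 3)), index=dates,
                          columns=["A", "B", "C"])
        o3 = pd.DataFrame(rng.normal(90, 20, (100, 3)), index=dates,
                          columns=["A", "B", "C"])
        fm = regions.build_feature_matrix(tx, o3)
        assert fm.X.shape == (3, 200)
        for block in (fm.X[:, :100], fm.X[:, 100:]):
            np.testing.assert_allclose(block.mean(axis=1), 0.0, atol=1e-12)
            np.testing.assert_allclose(block.std(axis=1), 1.0, atol=1e-12)

    def test_identical_stations_identical_rows(self):
        dates = pd.date_range("2010-04-01", periods=50, freq="D")
        v = np.random.default_rng(2).normal(size=50)
        tx = pd.DataFrame({"A": v, "B": v}, index=dates)
        o3 = pd.DataFrame({"A": v + 1, "B": v + 1}, index=dates)
        fm = regions.build_feature_matrix(tx, o3)
        np.testing.assert_allclose(fm.X[0], fm.X[1])

    def test_zero_variance_station_named(self):
        dates = pd.date_range("2010-04-01", periods=50, freq="D")
        tx = pd.DataFrame({"A": np.arange(50.0), "B": 5.0}, index=dates)
        o3 = pd.DataFrame({"A": np.arange(50.0), "B": np.arange(50.0)}, index=dates)
        with pytest.raises(ValueError, match="B"):
            regions.build_feature_matrix(tx, o3)


class TestWardCluster:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.5, (5, 4)), rng.normal(10, 0.5, (5, 4))])
        sol = regions.ward_cluster(_feature_matrix(X), 2)
        assert len(set(sol.labels[:5])) == 1
        assert len(set(sol.labels[5:])) == 1
        assert sol.labels[0] != sol.labels[5]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        sol = regions.ward_cluster(_feature_matrix(X), 1)
        oracle_partitions, oracle_heights = ward_bruteforce(X)
        np.testing.assert_allclose(sol.linkage[:, 2], oracle_heights, rtol=1e-10)
        from scipy.cluster.hierarchy import fcluster

        for k in range(2, 12):
            labels = fcluster(sol.linkage, t=k, criterion="maxclust")
            part = frozenset(
                frozenset(np.flatnonzero(labels == c)) for c in set(labels)
            )
            assert part == oracle_partitions[12 - k - 1], f"k={k}"

    def test_duplicate_ids_rejected(self):
        X = np.random.default_rng(5).normal(size=(4, 3))
        fm = _feature_matrix(X, ids=["A", "A", "B", "C"])
        with pytest.raises(ValueError, match="duplicate"):
            regions.ward_cluster(fm, 2)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(i * 8, 0.5, (4, 3)) for i in range(3)])
        sol = regions.ward_cluster(_feature_matrix(X), 3)
        perm = rng.permutation(len(X))
        sol_p = regions.ward_cluster(_feature_matrix(X[perm]), 3)
        assert adjusted_rand_score(sol.labels[perm], sol_p.labels) == 1.0


class TestSelectK:
    def test_four_blobs(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(i * 10, 0.5, (6, 4)) for i in range(4)])
        sol = regions.ward_cluster(_feature_matrix(X), 4)
        assert regions.select_k(sol.linkage, k_min=4) == 4

    def test_featureless_data_falls_back_to_k_min(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 4))
        sol = regions.ward_cluster(_feature_matrix(X), 4)
        assert regions.select_k(sol.linkage, k_min=4) == 4

    def test_bad_range_rejected(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 3))
        sol = regions.ward_cluster(_feature_matrix(X), 2)
        with pytest.raises(ValueError):
            regions.select_k(sol.linkage, k_min=4, k_max=3)


class TestAssignNewStation:
    def test_centroid_returns_own_cluster(self):
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(0, 0.5, (5, 3)), rng.normal(8, 0.5, (5, 3))])
        sol = regions.ward_cluster(_feature_matrix(X), 2)
        for c in range(1, 3):
            assert regions.assign_new_station(sol.centroids[c - 1], sol) == c

    def test_equidistant_tie_goes_to_smaller_label(self):
        X = np.array([[0.0, 0], [0, 1], [10, 0], [10, 1]])
        sol = regions.ward_cluster(_feature_matrix(X), 2)
        mid = (sol.centroids[0] + sol.centroids[1]) / 2
        assert regions.assign_new_station(mid, sol) == 1

    def test_dimension_mismatch(self):
        X = np.random.default_rng(11).normal(size=(6, 4))
        sol = regions.ward_cluster(_feature_matrix(X), 2)
        with pytest.raises(ValueError, match="dimension"):
            regions.assign_new_station(np.zeros(3), sol)

    def test_training_stations_reassigned_to_own_region(self):
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(i * 10, 0.5, (5, 4)) for i in range(3)])
        sol = regions.ward_cluster(_feature_matrix(X), 3)
        for i in range(len(X)):
            assert regions.assign_new_station(X[i], sol) == sol.labels[i]


class TestRepresentatives:
    def _solution_and_meta(self):
        rng = np.random.default_rng(13)
        X = np.vstack([rng.normal(0, 1.0, (6, 4)), rng.normal(10, 1.0, (6, 4))])
        ids = [f"S{i:02d}" for i in range(12)]
        types = ["urban", "suburban", "rural"] * 4
        meta = pd.DataFrame({"station_id": ids, "station_type": types})
        sol = regions.ward_cluster(_feature_matrix(X, ids), 2)
        return sol, meta

    def test_one_per_type_ranked_by_distance(self):
        sol, meta = self._solution_and_meta()
        reps = regions.representative_stations(sol, meta)
        for c in (1, 2):
            rs = [r for r in reps if r.region == c]
            assert {r.station_type for r in rs} == {"urban", "suburban", "rural"}
            dists = [r.distance for r in sorted(rs, key=lambda r: r.rank)]
            assert dists == sorted(dists)

    def test_minimal_within_type_against_bruteforce(self):
        sol, meta = self._solution_and_meta()
        reps = regions.representative_stations(sol, meta)
        types = meta.set_index("station_id")["station_type"]
        for r in reps:
            centroid = sol.centroids[r.region - 1]
            members = [
                (float(np.linalg.norm(sol.X[i] - centroid)), sid)
                for i, sid in enumerate(sol.station_ids)
                if sol.labels[i] == r.region and types[sid] == r.station_type
            ]
            assert r.station_id == min(members)[1]

    def test_single_type_region(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(4, 3))
        ids = [f"S{i}" for i in range(4)]
        meta = pd.DataFrame({"station_id": ids, "station_type": ["urban"] * 4})
        sol = regions.ward_cluster(_feature_matrix(X, ids), 1)
        reps = regions.representative_stations(sol, meta)
        assert len(reps) == 1 and reps[0].station_type == "urban"


class TestPlantedRecovery:
    def test_planted_regions_recovered(self):
        cfg = simulate.SyntheticConfig(n_regions=6, stations_per_region=10, seed=42,
                                       years=tuple(range(2010, 2015)))
        net, truth = simulate.generate_network(cfg)
        series = simulate.generate_daily_series(cfg, net)
        season = [4, 5, 6, 7, 8, 9]
        tx = pd.DataFrame({s: df.set_index("date")["tx"] for s, df in series.items()})
        o3 = pd.DataFrame({s: df.set_index("date")["mda8o3"] for s, df in series.items()})
        tx = tx[tx.index.month.isin(season)]
        o3 = o3[o3.index.month.isin(season)]
        tx, _ = regions.impute_daily_means(tx)
        o3, _ = regions.impute_daily_means(o3)
        fm = regions.build_feature_matrix(tx, o3)
        sol = regions.ward_cluster(fm, 6)
        truth_labels = [truth.region_labels[s] for s in fm.station_ids]
        assert adjusted_rand_score(truth_labels, sol.labels) >= 0.9
        assert regions.select_k(sol.linkage, k_min=4, k_max=10) == 6
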