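"""Bray-Curtis, Ward.D2 (vs a from-scratch Lance-Williams oracle),
silhouette model selection, cluster validation, interpolation, provinces and
the random-forest explanation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from oceanmg import biogeo, profiles


def ward_d2_oracle(dist: np.ndarray):
    """Naive Ward.D2: Lance-Williams recursion on squared dissimilarities,
    recomputed over the full active set at every merge (no nearest-neighbour
    chain shortcuts). Returns merge heights and the partition trace."""
    n = dist.shape[0]
    d2 = dist.astype(float) ** 2
    active = {i: [i] for i in range(n)}
    pair_d2 = {
        (i, j): d2[i, j] for i, j in itertools.combinations(range(n), 2)
    }
    heights = []
    partitions = {n: [frozenset([i]) for i in range(n)]}
    next_id = n
    while len(active) > 1:
        (a, b), best = min(pair_d2.items(), key=lambda kv: kv[1])
        heights.append(np.sqrt(best))
        merged = active[a] + active[b]
        na, nb = len(active[a]), len(active[b])
        new = {}
        for c in active:
            if c in (a, b):
                continue
            nc = len(active[c])
            dac = pair_d2[tuple(sorted((a, c)))]
            dbc = pair_d2[tuple(sorted((b, c)))]
            dab = pair_d2[(a, b)]
            new[c] = (
                (na + nc) * dac + (nb + nc) * dbc - nc * dab
            ) / (na + nb + nc)
        del active[a], active[b]
        pair_d2 = {
            k: v for k, v in pair_d2.items() if a not in k and b not in k
        }
        for c, v in new.items():
            pair_d2[tuple(sorted((c, next_id)))] = v
        active[next_id] = merged
        next_id += 1
        partitions[len(active)] = [frozenset(m) for m in active.values()]
    return np.array(heights), partitions


class TestBrayCurtis:
    def test_hand_values(self):
        data = pd.DataFrame({"u": [2.0, 2.0], "v": [1.0, 1.0], "w": [2.0, 2.0]})
        d = biogeo.bray_curtis(profiles.Profile("gene", data))
        np.testing.assert_allclose(d.loc["u", "v"], 1 / 3)
        np.testing.assert_allclose(d.loc["u", "w"], 0.0)

    def test_disjoint_supports(self):
        data = pd.DataFrame({"u": [5.0, 0.0], "v": [0.0, 3.0]})
        d = biogeo.bray_curtis(profiles.Profile("gene", data))
        np.testing.assert_allclose(d.loc["u", "v"], 1.0)

    def test_zero_column_excluded_with_warning(self):
        data = pd.DataFrame({"u": [1.0, 2.0], "v": [0.0, 0.0], "w": [2.0, 1.0]})
        with pytest.warns(UserWarning, match="all-zero"):
            d = biogeo.bray_curtis(profiles.Profile("gene", data))
        assert list(d.index) == ["u", "w"]

    @settings(max_examples=30, deadline=None)
    @given(
        hnp.arrays(
            float,
            (5, 4),
            elements=st.floats(0, 100, allow_nan=False),
        )
    )
    def test_metric_properties_on_random_matrices(self, arr):
        arr = arr + 0.01  # keep columns nonzero
        data = pd.DataFrame(arr, columns=list("abcd"))
        d = biogeo.bray_curtis(profiles.Profile("gene", data)).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()


class TestWardCluster:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 3))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(6)]
        ddf = pd.DataFrame(dist, index=ids, columns=ids)
        z = biogeo.ward_linkage(ddf)
        heights, partitions = ward_d2_oracle(dist)
        np.testing.assert_allclose(np.sort(z[:, 2]), np.sort(heights), rtol=1e-9)
        for k in (2, 3, 4):
            labels = biogeo.ward_cluster(ddf, k)
            got = {
                frozenset(np.flatnonzero(labels.to_numpy() == c))
                for c in np.unique(labels)
            }
            assert got == set(partitions[k])

    def test_first_merge_is_closest_pair(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 2))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(7)]
        labels = biogeo.ward_cluster(pd.DataFrame(dist, index=ids, columns=ids), 6)
        iu = np.triu_indices(7, 1)
        i, j = iu[0][dist[iu].argmin()], iu[1][dist[iu].argmin()]
        assert labels.iloc[i] == labels.iloc[j]

    def test_two_tight_groups_recovered(self):
        ids = [f"s{i}" for i in range(6)]
        dist = np.full((6, 6), 10.0)
        dist[:3, :3] = 0.1
        dist[3:, 3:] = 0.1
        np.fill_diagonal(dist, 0)
        labels = biogeo.ward_cluster(pd.DataFrame(dist, index=ids, columns=ids), 2)
        assert labels.iloc[:3].nunique() == 1
        assert labels.iloc[3:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[5]

    def test_k_out_of_range(self):
        dist = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            biogeo.ward_cluster(dist, 3)


class TestOptimalK:
    def test_three_planted_groups_selected(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        pts = np.vstack([c + rng.normal(0, 0.3, (5, 2)) for c in centers])
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(15)]
        res = biogeo.optimal_k(pd.DataFrame(dist, index=ids, columns=ids))
        assert res.k == 3
        assert res.mean_silhouette > 0.7
        # grid oracle: no other k does better
        assert res.silhouette_by_k[3] == max(res.silhouette_by_k.values())

    def test_all_equal_distances_ties_to_kmin(self):
        n = 6
        dist = np.full((n, n), 1.0)
        np.fill_diagonal(dist, 0)
        ids = [f"s{i}" for i in range(n)]
        res = biogeo.optimal_k(pd.DataFrame(dist, index=ids, columns=ids))
        assert res.k == 2


class TestValidateClusters:
    def test_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        pts = np.vstack(
            [c + rng.normal(0, 0.2, (6, 2)) for c in ([0, 0], [8, 0], [0, 8])]
        )
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(18)]
        ddf = pd.DataFrame(dist, index=ids, columns=ids)
        labels = biogeo.ward_cluster(ddf, 3)
        out = biogeo.validate_clusters(ddf, labels)
        assert len(out) == 3
        assert all(p <= 0.01 for _, p in out.values())

    def test_random_labels_not_systematically_significant(self):
        """Pairwise dissimilarities are mutually dependent, so the rank test
        is only approximately calibrated under label permutation; the honest
        requirement is no systematic significance for random labels."""
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(14, 3))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(14)]
        ddf = pd.DataFrame(dist, index=ids, columns=ids)
        pvals = []
        for _ in range(100):
            labels = pd.Series(rng.permutation([1] * 7 + [2] * 7), index=ids)
            out = biogeo.validate_clusters(ddf, labels)
            pvals.extend(p for _, p in out.values())
        pvals = np.array(pvals)
        assert (pvals <= 0.01).mean() <= 0.08
        assert np.median(pvals) > 0.15

    def test_identical_dissimilarities_h_zero(self):
        n = 6
        dist = np.full((n, n), 0.5)
        np.fill_diagonal(dist, 0)
        ids = [f"s{i}" for i in range(n)]
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=ids)
        out = biogeo.validate_clusters(
            pd.DataFrame(dist, index=ids, columns=ids), labels
        )
        for h, p in out.values():
            assert h == 0.0 and p == 1.0

    def test_hand_computed_kruskal(self):
        """Two-sample tie-free case cross-checked against the rank formula."""
        within = np.array([1.0, 2.0, 3.0])
        between = np.array([4.0, 5.0, 6.0, 7.0])
        h_ours, _ = stats.kruskal(within, between)
        # ranks: within 1..3 (R1=6), between 4..7 (R2=22); n=7
        h_hand = 12 / (7 * 8) * (6**2 / 3 + 22**2 / 4) - 3 * 8
        np.testing.assert_allclose(h_ours, h_hand)

    def test_singleton_cluster_skipped(self):
        n = 5
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(n, 2))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(n)]
        labels = pd.Series([1, 1, 1, 1, 2], index=ids)
        with pytest.warns(UserWarning, match="single member"):
            out = biogeo.validate_clusters(
                pd.DataFrame(dist, index=ids, columns=ids), labels
            )
        assert 2 not in out


class TestInterpolateMissing:
    def _stations(self, values):
        return pd.DataFrame(
            {
                "station_id": [f"s{i}" for i in range(len(values))],
                "chla": values,
            }
        )

    def test_midpoint(self):
        out = biogeo.interpolate_missing(self._stations([1.0, np.nan, 3.0]))
        np.testing.assert_allclose(out["chla"], [1, 2, 3])

    def test_identity_when_complete(self):
        st_ = self._stations([1.0, 2.0, 3.0])
        out = biogeo.interpolate_missing(st_)
        pd.testing.assert_frame_equal(out, st_)

    def test_edge_fill(self):
        out = biogeo.interpolate_missing(self._stations([np.nan, 2.0, 4.0]))
        np.testing.assert_allclose(out["chla"], [2, 2, 4])

    def test_entirely_missing_rejected(self):
        with pytest.raises(ValueError, match="chla"):
            biogeo.interpolate_missing(self._stations([np.nan, np.nan, np.nan]))


class TestDefineProvinces:
    def _blocks(self):
        rng = np.random.default_rng(0)
        lat = np.concatenate([rng.uniform(-60, -40, 3), rng.uniform(30, 50, 3)])
        return pd.DataFrame(
            {
                "station_id": [f"s{i}" for i in range(6)],
                "latitude": lat,
                "longitude": rng.uniform(-30, -10, 6),
                "temperature": np.concatenate(
                    [rng.uniform(1, 4, 3), rng.uniform(20, 25, 3)]
                ),
                "salinity": rng.uniform(34, 35, 6),
                "chla": rng.uniform(0.1, 1.0, 6),
            }
        )

    def test_two_latitude_blocks(self):
        st_ = self._blocks()
        labels = biogeo.define_provinces(st_, 2)
        assert labels.iloc[:3].nunique() == 1
        assert labels.iloc[0] != labels.iloc[5]

    def test_k_equals_n_rejected(self):
        with pytest.raises(ValueError):
            biogeo.define_provinces(self._blocks(), 6)

    def test_matches_ward_oracle_on_standardised_matrix(self):
        st_ = self._blocks()
        z = stats.zscore(
            st_[list(biogeo.PROVINCE_VARIABLES)].to_numpy(float), axis=0, ddof=0
        )
        dist = np.sqrt(((z[:, None] - z[None]) ** 2).sum(-1))
        _, partitions = ward_d2_oracle(dist)
        labels = biogeo.define_provinces(st_, 3)
        got = {
            frozenset(np.flatnonzero(labels.to_numpy() == c))
            for c in np.unique(labels)
        }
        assert got == set(partitions[3])


class TestExplainClustersRF:
    def _noise_stations(self, n, rng, temps):
        return pd.DataFrame(
            {
                "station_id": [f"s{i}" for i in range(n)],
                "temperature": temps,
                "salinity": rng.normal(35, 0.5, n),
                "chla": rng.uniform(0.05, 1.0, n),
                "poc": rng.uniform(2, 10, n),
                "nitrate": rng.uniform(0.1, 20, n),
                "phosphate": rng.uniform(0.05, 1.5, n),
            }
        )

    def test_planted_temperature_threshold_recovered(self):
        rng = np.random.default_rng(0)
        temps = rng.uniform(0, 28, 30)
        st_ = self._noise_stations(30, rng, temps)
        labels = pd.Series((temps > 15).astype(int), index=st_["station_id"])
        rf = biogeo.explain_clusters_rf(st_, labels, n_trees=500, seed=0)
        assert rf.importances.idxmax() == "temperature"
        assert rf.oob_score >= 0.9
        np.testing.assert_allclose(rf.importances.sum(), 1.0)

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(1)
        scores = []
        for rep in range(10):
            temps = rng.uniform(0, 28, 24)
            st_ = self._noise_stations(24, rng, temps)
            labels = pd.Series(
                rng.permutation([0] * 12 + [1] * 12), index=st_["station_id"]
            )
            rf = biogeo.explain_clusters_rf(st_, labels, n_trees=120, seed=rep)
            scores.append(rf.oob_score)
        assert abs(np.mean(scores) - 0.5) < 0.18

    def test_single_cluster_rejected(self):
        rng = np.random.default_rng(0)
        st_ = self._noise_stations(8, rng, rng.uniform(0, 28, 8))
        labels = pd.Series([1] * 8, index=st_["station_id"])
        with pytest.raises(ValueError):
            biogeo.explain_clusters_rf(st_, labels)
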