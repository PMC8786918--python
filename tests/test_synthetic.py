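"""Generator contracts: determinism, preconditions, planted structure."""

import numpy as np
import pandas as pd
import pytest

from oceanmg import synthetic


class TestMakeStations:
    def test_shape_and_temperature_envelope(self):
        st = synthetic.make_stations(22, (-62, 47), seed=1)
        assert len(st) == 22
        assert st["station_id"].is_unique
        assert st["latitude"].is_monotonic_increasing
        assert st["temperature"].min() >= 0
        assert st["temperature"].max() <= 30
        peak_lat = st.loc[st["temperature"].idxmax(), "latitude"]
        assert -15 <= peak_lat <= 15

    def test_seeded_determinism(self):
        a = synthetic.make_stations(22, (-62, 47), seed=3)
        b = synthetic.make_stations(22, (-62, 47), seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_stations_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_stations(3, (-62, 47), seed=0)

    def test_nitrate_anticorrelated_with_temperature(self):
        st = synthetic.make_stations(22, (-62, 47), seed=0, missing={})
        r = np.corrcoef(st["temperature"], st["nitrate"])[0, 1]
        assert r < -0.5

    def test_missing_pattern_applied(self):
        st = synthetic.make_stations(22, (-62, 47), seed=0)
        for cov, n in synthetic.DEFAULT_MISSING.items():
            assert st[cov].isna().sum() == n


class TestMakeCatalog:
    def test_catalog_size_and_ko_redundancy(self):
        catalog, truth = synthetic.make_catalog(
            n_taxa=50, n_kos=40, variants_per_pair=8, seed=7
        )
        assert len(catalog) <= 50 * 40 * 8
        assert catalog["gene_id"].is_unique
        assert catalog["length_bp"].between(210, 4500).all()
        carriers = truth.variants.groupby("ko_id")["taxon_id"].nunique()
        assert (carriers >= 5).all()
        # every regime contributes carriers to every KO
        regime_of = truth.taxa.set_index("taxon_id")["regime"]
        for _, grp in truth.variants.groupby("ko_id"):
            assert regime_of.loc[grp["taxon_id"].unique()].nunique() == 3

    def test_variant_niches_nested_in_taxon_niche(self):
        _, truth = synthetic.make_catalog(seed=2)
        taxa = truth.taxa.set_index("taxon_id")
        v = truth.variants
        mu_t = taxa.loc[v["taxon_id"], "mu"].to_numpy()
        sig_t = taxa.loc[v["taxon_id"], "sigma"].to_numpy()
        assert (v["mu"].to_numpy() >= mu_t - 2 * sig_t - 1e-9).all()
        assert (v["mu"].to_numpy() <= mu_t + 2 * sig_t + 1e-9).all()
        np.testing.assert_allclose(
            v["sigma"].to_numpy() / sig_t, truth.sub_niche_ratio
        )

    def test_unclassified_fraction(self):
        catalog, _ = synthetic.make_catalog(unclassified_fraction=0.2, seed=0)
        blanked = catalog["taxon_id"].isna() | catalog["ko_id"].isna()
        assert abs(blanked.mean() - 0.2) < 0.03

    def test_zero_variants_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_catalog(variants_per_pair=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_catalog(cazy_fraction=1.5)

    def test_truth_json_roundtrip(self, tmp_path):
        _, truth = synthetic.make_catalog(n_taxa=9, n_kos=4, seed=5)
        truth.to_json(tmp_path / "truth.json")
        back = synthetic.NicheTruth.from_json(tmp_path / "truth.json")
        pd.testing.assert_frame_equal(truth.taxa, back.taxa)
        pd.testing.assert_frame_equal(truth.variants, back.variants)
        assert back.regime_centers == truth.regime_centers


class TestSimulateCounts:
    def test_column_sums_and_determinism(self, transect):
        stations, catalog, counts, truth = transect
        assert (counts.sum(axis=0) == 200_000).all()
        again = synthetic.make_transect(seed=1)[2]
        pd.testing.assert_frame_equal(counts, again)

    def test_warm_variant_prefers_warm_station(self):
        stations = synthetic.make_stations(22, (-62, 47), seed=0, missing={})
        catalog, truth = synthetic.make_catalog(n_taxa=6, n_kos=3, seed=0)
        exp = synthetic.expected_counts(catalog, truth, stations, 100_000)
        temps = stations.set_index("station_id")["temperature"]
        warm = (temps - 24).abs().idxmin()
        cold = (temps - 5).abs().idxmin()
        v = truth.variants
        pick = v[(v["mu"] > 24) & (v["mu"] < 26)].iloc[0]["gene_id"]
        assert exp.loc[pick, warm] > exp.loc[pick, cold]

    def test_low_depth_rejected(self, transect):
        stations, catalog, _, truth = transect
        with pytest.raises(ValueError):
            synthetic.simulate_counts(catalog, truth, stations, reads_per_station=100)

    def test_catalog_truth_mismatch_rejected(self, transect):
        stations, catalog, _, truth = transect
        with pytest.raises(ValueError):
            synthetic.simulate_counts(catalog.iloc[:10], truth, stations)


class TestPlantedStructure:
    def test_abundant_variant_maxima_recoverable(self, transect):
        """Empirical abundance maxima of well-sampled variants sit at (or one
        local temperature gap from) the expected-count maximum."""
        stations, catalog, counts, truth = transect
        exp = synthetic.expected_counts(catalog, truth, stations, 200_000)
        temps = stations.set_index("station_id")["temperature"]
        strong = exp.max(axis=1) >= 100
        assert strong.sum() > 50
        gap = float(np.abs(np.diff(np.sort(temps.to_numpy()))).max())
        n_bad = 0
        for gid in exp.index[strong]:
            t_emp = temps[counts.loc[gid].idxmax()]
            t_exp = temps[exp.loc[gid].idxmax()]
            if abs(t_emp - t_exp) > gap:
                n_bad += 1
        assert n_bad / strong.sum() <= 0.05

    def test_ko_redundancy_flattens_marginals(self, transect):
        """KO marginal abundance varies less across stations than taxon
        marginal abundance (the planted functional redundancy)."""
        stations, catalog, counts, truth = transect
        v = truth.variants.set_index("gene_id")
        by_ko = counts.groupby(v.loc[counts.index, "ko_id"].to_numpy()).sum()
        by_taxon = counts.groupby(v.loc[counts.index, "taxon_id"].to_numpy()).sum()

        def mean_cv(df):
            m = df.mean(axis=1)
            return float((df.std(axis=1) / m[m > 0]).mean())

        assert mean_cv(by_ko) < mean_cv(by_taxon)

    def test_station_regimes_cover_three_regimes(self, transect):
        stations, _, _, truth = transect
        regimes = truth.station_regimes(stations)
        assert set(regimes.unique()) == {0, 1, 2}


def test_write_transect_files(tmp_path, transect):
    stations, catalog, counts, truth = transect
    synthetic.write_transect(tmp_path, stations, catalog, counts, truth)
    for name in ("stations.tsv", "catalog.tsv", "counts.tsv", "truth.json"):
        assert (tmp_path / name).exists()
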