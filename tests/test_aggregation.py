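import numpy as np
import pandas as pd
import pytest
from scipy import stats

from treedom import aggregation as agg
from treedom import dominance as dom
from treedom import io as tdio


class TestStandardizeCounts:
    def _table(self, areas, counts):
        plots = pd.DataFrame(
            {"plot_id": [f"p{i}" for i in range(len(areas))], "habitat": "swamp",
             "lat": -4.0, "lon": -73.0, "area_ha": areas}
        ).set_index("plot_id")
        recs = []
        for i, row in enumerate(counts):
            for j, c in enumerate(row):
                if c:
                    recs.append({"plot_id": f"p{i}", "species": f"s{j}",
                                 "id_status": "species", "count": c})
        return tdio.InventoryTable(plots=plots, records=pd.DataFrame(recs))

    def test_min_area_plot_unchanged(self):
        t = self._table([0.1, 0.2], [[10, 4], [6, 2]])
        std = agg.standardize_counts(t, "swamp")
        i = std.plot_ids.index("p0")
        assert std.counts[i].tolist() == [10, 4]

    def test_halving(self):
        t = self._table([0.1, 0.2], [[1, 1], [10, 0]])
        std = agg.standardize_counts(t, "swamp")
        i = std.plot_ids.index("p1")
        j = std.species.index("s0")
        assert std.counts[i, j] == 5

    def test_round_to_zero_boundary(self):
        t = self._table([0.05, 0.2], [[1, 1], [1, 0]])
        std = agg.standardize_counts(t, "swamp")
        i = std.plot_ids.index("p1")
        j = std.species.index("s0")
        assert std.counts[i, j] == 0  # 1 * 0.05/0.2 = 0.25 rounds down


class TestEstimateK:
    def test_poisson_counts_hit_the_cap(self):
        rng = np.random.default_rng(8)
        x = rng.poisson(5.0, 2000)
        est = agg.estimate_k(x)
        assert est.k >= 100

    @pytest.mark.parametrize("k_true", [0.2, 0.5, 1.0])
    def test_nb_recovery(self, k_true):
        rng = np.random.default_rng(int(k_true * 100))
        x = rng.negative_binomial(k_true, k_true / (k_true + 5.0), 2000)
        est = agg.estimate_k(x)
        assert est.k == pytest.approx(k_true, rel=0.2)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            agg.estimate_k(np.zeros(10, dtype=int))

    def test_merging_samples_with_same_k_is_consistent(self):
        rng = np.random.default_rng(9)
        k = 0.5
        a = rng.negative_binomial(k, k / (k + 5.0), 3000)
        b = rng.negative_binomial(k, k / (k + 5.0), 3000)
        ka = agg.estimate_k(a).k
        kab = agg.estimate_k(np.concatenate([a, b])).k
        assert kab == pytest.approx(ka, rel=0.3)

    def test_dominants_in_realistic_communities_are_clumped(self, community):
        """A substantial share of dominant species shows k at or below 1
        (strong aggregation), and the planted rank ordering holds: local
        dominants are more clumped than widespread dominants."""
        table, truth = community["table"], community["truth"]
        ks_frames, locals_, widespreads = [], [], []
        for h in ["terra_firme", "floodplain", "swamp", "white_sand"]:
            m = dom.relative_abundances(table, h)
            r = dom.dominance_result(m)
            ks = agg.k_for_dominants(table, h, species=r.dominants)
            ks_frames.append(ks)
            arch = truth[truth["habitat"] == h].set_index("species")["archetype"]
            planted = ks.join(arch, on="species")
            locals_ += planted.loc[planted["archetype"] == "local", "k"].tolist()
            widespreads += planted.loc[planted["archetype"] == "widespread", "k"].tolist()
        ks = pd.concat(ks_frames, ignore_index=True)
        share_low = ((ks["k"] > 0) & (ks["k"] <= 1.0)).mean()
        assert share_low > 0.25
        if locals_ and widespreads:
            assert np.median(locals_) < np.median(widespreads)


class TestCodominanceF:
    def test_absent_species_gives_zero(self):
        assert agg.codominance_F(0, 5, 10, 20) == 0.0

    def test_monodominant_pair_gives_one(self):
        assert agg.codominance_F(10, 20, 10, 20) == 1.0

    def test_hand_value(self):
        assert agg.codominance_F(2, 5, 10, 20) == pytest.approx(0.05)

    def test_symmetry_in_plots(self):
        assert agg.codominance_F(3, 7, 12, 15) == agg.codominance_F(7, 3, 15, 12)

    def test_counts_exceeding_totals_rejected(self):
        with pytest.raises(ValueError):
            agg.codominance_F(11, 5, 10, 20)

    def test_matches_pair_sampling_simulation(self):
        rng = np.random.default_rng(10)
        n_draws = 200_000
        f = agg.codominance_F(2, 5, 10, 20)
        hits = (rng.random(n_draws) < 2 / 10) & (rng.random(n_draws) < 5 / 20)
        se = np.sqrt(f * (1 - f) / n_draws)
        assert abs(hits.mean() - f) < 4 * se


class TestPairwiseDistances:
    def test_identical_coordinates_zero(self):
        plots = pd.DataFrame({"lat": [1.0, 1.0], "lon": [2.0, 2.0]})
        d = agg.pairwise_distances(plots)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_one_degree_longitude_at_equator(self):
        plots = pd.DataFrame({"lat": [0.0, 0.0], "lon": [0.0, 1.0]})
        d = agg.pairwise_distances(plots)
        # closed form: R * pi / 180
        assert d[0, 1] == pytest.approx(6371.0088 * np.pi / 180, rel=1e-6)

    def test_triangle_inequality(self, rng):
        plots = pd.DataFrame({"lat": rng.uniform(-10, 5, 12), "lon": rng.uniform(-78, -65, 12)})
        d = agg.pairwise_distances(plots)
        for _ in range(50):
            i, j, k = rng.choice(12, 3, replace=False)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


def _toy_matrix(counts, habitat="swamp"):
    counts = np.asarray(counts)
    rel = counts / counts.sum(axis=1, keepdims=True)
    return dom.AbundanceMatrix(
        habitat, [f"p{i}" for i in range(counts.shape[0])],
        [f"s{i}" for i in range(counts.shape[1])], counts, rel
    )


class TestAggregationCurves:
    def test_constant_F_preserved(self, rng):
        # identical composition everywhere: F constant across all pairs
        n_plots = 16
        counts = np.tile([5, 5], (n_plots, 1))
        m = _toy_matrix(counts)
        lat = rng.uniform(-6, -2, n_plots)
        lon = rng.uniform(-75, -70, n_plots)
        dmat = agg.pairwise_km(lat, lon)
        curves = agg.aggregation_curves(m, dmat, seed=0)
        assert np.allclose(curves.F_abs["s0"], 0.25)

    def test_clumped_species_decays_with_distance(self, community):
        table = community["table"]
        truth = community["truth"]
        m = dom.relative_abundances(table, "floodplain")
        # most clumped planted local dominant: short-range occupancy
        local = truth[(truth["habitat"] == "floodplain") & (truth["archetype"] == "local")]
        sp = [s for s in local["species"] if s in m.species][0]
        dmat = agg.pairwise_distances(table.plots.loc[m.plot_ids])
        curves = agg.aggregation_curves(m, dmat, species=[sp], seed=1)
        rho, _ = stats.spearmanr(curves.distance_km, curves.F_abs[sp])
        assert rho < 0

    def test_few_pairs_warn_and_bin(self, rng):
        counts = np.array([[3, 1], [2, 2], [1, 3]])
        m = _toy_matrix(counts)
        dmat = agg.pairwise_km(np.array([-4.0, -4.5, -5.0]), np.array([-73.0, -73.5, -74.0]))
        with pytest.warns(UserWarning, match="binned"):
            curves = agg.aggregation_curves(m, dmat, seed=2)
        assert np.all(np.isfinite(curves.F_abs.to_numpy()))

    def test_smoothed_values_within_local_range(self, rng):
        n_plots = 40
        counts = rng.integers(1, 30, size=(n_plots, 2))
        m = _toy_matrix(counts)
        lat = rng.uniform(-6, -2, n_plots)
        lon = rng.uniform(-75, -70, n_plots)
        dmat = agg.pairwise_km(lat, lon)
        curves = agg.aggregation_curves(m, dmat, seed=3)
        iu, ju = np.triu_indices(n_plots, k=1)
        totals = counts.sum(axis=1)
        F = agg.codominance_F(counts[iu, 0], counts[ju, 0], totals[iu], totals[ju])
        # smoother stays inside the global envelope of raw pair values
        assert curves.F_abs["s0"].max() <= F.max() + 1e-9
        assert curves.F_abs["s0"].min() >= 0.0


class TestRelativizeCurves:
    def test_two_identical_species_split_evenly(self):
        grid = np.linspace(0, 100, 10)
        F = pd.DataFrame({"a": np.full(10, 0.2), "b": np.full(10, 0.2)}, index=grid)
        c = agg.CodominanceCurves("swamp", grid, F)
        rel = agg.relativize_curves(c)
        assert np.allclose(rel.F_rel, 0.5)

    def test_rows_sum_to_one_exactly(self, rng):
        grid = np.linspace(0, 100, 25)
        F = pd.DataFrame(rng.uniform(0, 1, (25, 6)), index=grid,
                         columns=[f"s{i}" for i in range(6)])
        rel = agg.relativize_curves(agg.CodominanceCurves("swamp", grid, F))
        assert np.allclose(rel.F_rel.sum(axis=1), 1.0, atol=1e-9)

    def test_all_zero_distance_masked(self):
        grid = np.array([0.0, 1.0])
        F = pd.DataFrame({"a": [0.0, 0.3], "b": [0.0, 0.1]}, index=grid)
        rel = agg.relativize_curves(agg.CodominanceCurves("swamp", grid, F))
        assert rel.F_rel.iloc[0].isna().all()
        assert rel.F_rel.iloc[1].sum() == pytest.approx(1.0)

    def test_local_dominant_peaks_at_short_range(self, community):
        """Planted local dominants have relatively higher F at short distance."""
        table, truth = community["table"], community["truth"]
        m = dom.relative_abundances(table, "terra_firme")
        r = dom.dominance_result(m)
        dmat = agg.pairwise_distances(table.plots.loc[m.plot_ids])
        local = truth[(truth["habitat"] == "terra_firme") & (truth["archetype"] == "local")]
        sp_local = [s for s in local["species"] if s in r.dominants]
        species = list(dict.fromkeys(r.dominants[:12] + sp_local))
        curves = agg.relativize_curves(
            agg.aggregation_curves(m, dmat, species=species, seed=4)
        )
        rel = curves.F_rel[sp_local[0]].dropna()
        short = rel.iloc[: len(rel) // 4].mean()
        long = rel.iloc[-len(rel) // 4 :].mean()
        assert short > long


class TestKRegressions:
    def test_constant_k_gains_no_support(self):
        rng = np.random.default_rng(12)
        results = []
        for h in ["terra_firme", "floodplain"]:
            n = 25
            table = pd.DataFrame(
                {"species": [f"{h}_{i}" for i in range(n)], "d": 1.0,
                 "rank": np.arange(1, n + 1), "cum_share": np.linspace(0, 1, n),
                 "dominant": True,
                 "mean_local_abundance": rng.uniform(0.02, 0.3, n),
                 "regional_frequency": rng.uniform(0.1, 0.9, n)}
            )
            results.append(dom.DominanceResult(habitat=h, table=table, D=float(n)))
        ks = pd.concat(
            [r.table.assign(habitat=r.habitat)[["habitat", "species"]] for r in results],
            ignore_index=True,
        ).assign(k=0.5, mean=5.0, estimator="ml", converged=True)
        out = agg.k_regressions(results, ks)
        for label in ["abundance", "frequency"]:
            rank = out[label]["ranking"].set_index("model")
            # the pure-k model cannot beat the intercept by more than chance
            assert rank.loc["x", "aic"] >= rank.loc["intercept", "aic"] - 2.5

    def test_planted_k_relationships_recovered(self, community):
        """Clumped local dominants: abundance falls and frequency rises with k."""
        table = community["table"]
        results, ks_frames = [], []
        for h in ["terra_firme", "floodplain", "swamp", "white_sand"]:
            m = dom.relative_abundances(table, h)
            r = dom.dominance_result(m)
            results.append(r)
            ks_frames.append(agg.k_for_dominants(table, h, species=r.dominants))
        ks = pd.concat(ks_frames, ignore_index=True)
        ks = ks[ks["k"] < 1e5]
        out = agg.k_regressions(results, ks)
        ab = out["abundance"]["fits"]["x"].slope("k")
        fr = out["frequency"]["fits"]["x"].slope("k")
        assert ab < 0
        assert fr > 0

    def test_shuffling_k_destroys_relationships(self, community):
        table = community["table"]
        results, ks_frames = [], []
        for h in ["terra_firme", "floodplain"]:
            m = dom.relative_abundances(table, h)
            r = dom.dominance_result(m)
            results.append(r)
            ks_frames.append(agg.k_for_dominants(table, h, species=r.dominants))
        ks = pd.concat(ks_frames, ignore_index=True)
        ks = ks[ks["k"] < 1e5].reset_index(drop=True)
        out_true = agg.k_regressions(results, ks)
        rng = np.random.default_rng(13)
        shuffled = ks.copy()
        shuffled["k"] = rng.permutation(shuffled["k"].to_numpy())
        out_perm = agg.k_regressions(results, shuffled)
        for label in ["abundance", "frequency"]:
            z_true = abs(out_true[label]["fits"]["x"].slope("k")) / out_true[label]["fits"]["x"].slope_se("k")
            z_perm = abs(out_perm[label]["fits"]["x"].slope("k")) / out_perm[label]["fits"]["x"].slope_se("k")
            assert z_perm < z_true
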