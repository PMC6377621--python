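import numpy as np
import pandas as pd
import pytest

from polarscape.arisa import GROUP_WINDOWS, call_true_peaks, richness
from polarscape.community import nestedness_temperature
from polarscape.synth import (
    MULTI_TAXA,
    GroundTruth,
    default_exog_corr,
    default_truth,
    generate_community_matrix,
    generate_dem,
    generate_electropherogram,
    generate_sample_table,
)

from oracles import semivariogram


class TestGenerateDEM:
    def test_coast_edge_has_zero(self):
        dem = generate_dem(32, 32, 100.0, 800.0, smoothness=5.0, seed=1)
        assert dem.values[:, -1].min() == 0.0
        assert dem.values.min() >= 0.0

    def test_deterministic(self):
        a = generate_dem(16, 20, 50.0, 500.0, seed=7)
        b = generate_dem(16, 20, 50.0, 500.0, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_different_seed_differs(self):
        a = generate_dem(16, 20, 50.0, 500.0, seed=7)
        b = generate_dem(16, 20, 50.0, 500.0, seed=8)
        assert not np.array_equal(a.values, b.values)

    def test_semivariogram_increases_with_lag(self):
        dem = generate_dem(64, 64, 50.0, 1500.0, smoothness=2.0, seed=3)
        gamma = semivariogram(dem.values, dem.cellsize, max_lag_cells=6)
        assert np.all(np.diff(gamma) > 0)

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            generate_dem(4, 32, 100.0, 800.0)
        with pytest.raises(ValueError):
            generate_dem(32, 32, 100.0, -5.0)


class TestGroundTruth:
    def test_default_truth_valid(self, truth):
        sigma = truth.implied_covariance()
        w = np.linalg.eigvalsh(sigma.to_numpy())
        assert w.min() > 0
        # unit implied variances throughout
        np.testing.assert_allclose(np.diag(sigma), 1.0, atol=1e-10)

    def test_negative_disturbance_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            default_truth(disturbance_sds={"soil_water": -1.0, "cyano_s": 0.5,
                                           "fungal_s": 0.5, "multi_s": 0.5})

    def test_overexplained_variance_rejected(self):
        coeffs = dict(default_truth().path_coefficients)
        for k in list(coeffs):
            if k[1] == "cyano_s":
                coeffs[k] = np.sign(coeffs[k]) * 0.9
        with pytest.raises(ValueError, match="shrink"):
            GroundTruth(coeffs, default_exog_corr())

    def test_net_effects_ordering_matches_design(self, truth):
        net = truth.net_effects()
        assert net.loc["cyano_s", "biotic"] == 0.0
        assert (net.loc["cyano_s", "abiotic"] > net.loc["cyano_s", "spatial"])
        assert ((net >= 0) & (net <= 1)).all().all()


class TestSampleTable:
    def test_sites_inside_dem(self, small_dem, truth):
        t = generate_sample_table(small_dem, 80, truth, seed=2)
        assert len(t) == 80
        assert all(small_dem.contains(x, y) for x, y in zip(t.x, t.y))

    def test_deterministic(self, small_dem, truth):
        a = generate_sample_table(small_dem, 40, truth, seed=5)
        b = generate_sample_table(small_dem, 40, truth, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_too_many_sites_rejected(self, small_dem, truth):
        with pytest.raises(ValueError, match="exceeds"):
            generate_sample_table(small_dem, 10_000, truth)

    def test_atp_independent(self, small_dem, truth):
        t = generate_sample_table(small_dem, 500, truth, seed=3)
        others = [c for c in t.columns
                  if c not in ("atp",) and t[c].dtype.kind == "f" and t[c].std() > 0]
        band = 2.0 / np.sqrt(500)  # ~95% sampling band around 0
        rs = [abs(np.corrcoef(np.log(t.atp), t[c])[0, 1]) for c in others]
        # allow one marginal excursion among ~15 correlations
        assert sum(r > band for r in rs) <= 1

    def test_richness_ranges(self, small_dem, truth):
        t = generate_sample_table(small_dem, 200, truth, seed=4)
        assert t.multi_s.between(0, 9).all()
        assert t.cyano_s.between(0, 120).all()
        assert t.fungal_s.between(0, 120).all()

    def test_discretization_is_monotone(self, small_dem, truth):
        t = generate_sample_table(small_dem, 150, truth, seed=6)
        for v in ("cyano_s", "fungal_s", "multi_s"):
            order = np.argsort(t[f"{v}_latent"].to_numpy())
            assert np.all(np.diff(t[v].to_numpy()[order]) >= 0)

    def test_noise_free_limit_exact_linear(self, small_dem):
        truth = default_truth(
            disturbance_sds={"soil_water": 0.0, "cyano_s": 0.0,
                             "fungal_s": 0.0, "multi_s": 0.0},
            spatial_sd=0.0,
        )
        t = generate_sample_table(small_dem, 120, truth, seed=8, discretize=False)
        # reconstruct the generator's internal z-scores by exact inversion of
        # the emission transforms, then refit each equation by OLS:
        # coefficients come back to machine precision with zero residuals
        z = {}
        for v in ("elevation", "slope", "aspect", "distance", "wetness"):
            col = t[v].to_numpy()
            z[v] = (col - col.mean()) / col.std()
        z["temperature"] = (t.temperature.to_numpy() + 5.0) / 3.0
        z["ph"] = (t.ph.to_numpy() - 7.8) / 0.7
        z["nitrogen"] = (np.log(t.nitrogen.to_numpy()) + 2.3) / 0.5
        z["soil_water"] = (np.log(t.soil_water.to_numpy()) - 0.8) / 0.6
        z["cyano_s"] = t.cyano_s_latent.to_numpy()
        coefs = truth.path_coefficients
        for effect, target in (("soil_water", z["soil_water"]),
                               ("fungal_s", t.fungal_s_latent.to_numpy())):
            parents = [c for (c, e) in coefs if e == effect and c not in ("s1", "s2")]
            x = np.column_stack([z[c] for c in parents])
            beta, *_ = np.linalg.lstsq(x, target, rcond=None)
            np.testing.assert_allclose(
                beta, [coefs[(c, effect)] for c in parents], atol=1e-9
            )
            np.testing.assert_allclose(target - x @ beta, 0.0, atol=1e-9)

    def test_mvn_mode_covariance_converges_to_truth(self, small_dem, truth):
        # mean sample covariance over seeds approaches the path-tracing
        # implied covariance computed analytically from the truth
        target = truth.implied_covariance()
        cols = target.columns
        acc = np.zeros((len(cols), len(cols)))
        reps = 60
        for s in range(reps):
            t = generate_sample_table(small_dem, 500, truth, seed=s, mode="mvn",
                                      discretize=False)
            acc += np.cov(t[cols].to_numpy(), rowvar=False)
        acc /= reps
        err = np.abs(acc - target.to_numpy()).max()
        assert err < 4.0 / np.sqrt(500 * reps) * 3


class TestParameterRecovery:
    def test_ci_coverage_of_path_parameters(self, small_dem, truth):
        # 95% normal-theory CIs from the inverse information should cover the
        # true free parameters in ~95 of 100 replicates at n = 490
        from polarscape.sem import fit_ml

        values = truth.param_values()
        path_params = [q.name for q in truth.model.parameters
                       if q.kind in ("path", "weight")]
        cover = {name: 0 for name in path_params}
        reps = 100
        for rep in range(reps):
            t = generate_sample_table(small_dem, 490, truth, seed=50_000 + rep,
                                      mode="mvn", discretize=False)
            fit = fit_ml(truth.model, t, compute_se=True)
            for name in path_params:
                est, se = fit.estimates[name], fit.se[name]
                if np.isfinite(se) and abs(est - values[name]) <= 1.96 * se:
                    cover[name] += 1
        rates = np.array(list(cover.values())) / reps
        assert rates.mean() >= 0.93
        assert rates.min() >= 0.88, dict(zip(path_params, rates))


class TestCommunityMatrix:
    def test_perfect_nesting_rows(self):
        m = generate_community_matrix(np.array([3, 2, 1]), 5, 1.0)
        np.testing.assert_array_equal(
            m.to_numpy(),
            [[1, 1, 1, 0, 0], [1, 1, 0, 0, 0], [1, 0, 0, 0, 0]],
        )
        assert nestedness_temperature(m.to_numpy()[:, :3]) == 0.0

    def test_row_sums_conserved(self, rng):
        rich = rng.integers(0, 15, size=25)
        m = generate_community_matrix(rich, 20, 0.5, seed=1)
        np.testing.assert_array_equal(m.sum(axis=1).to_numpy(), rich)

    def test_overflow_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            generate_community_matrix(np.array([10]), 5)

    def test_strength_orders_temperature(self):
        # monotonicity by simulation: nested >> random in >= 95/100 seeds
        rng = np.random.default_rng(0)
        wins = 0
        for s in range(100):
            rich = rng.integers(1, 18, size=25)
            hot = generate_community_matrix(rich, 20, 0.0, seed=s)
            cold = generate_community_matrix(rich, 20, 1.0, seed=s)
            t_cold = nestedness_temperature(cold, n_pack=3)
            t_hot = nestedness_temperature(hot, n_pack=3)
            wins += t_cold < t_hot
        assert wins >= 95

    def test_taxon_names(self):
        m = generate_community_matrix(np.array([2, 1]), 9, 1.0, taxon_names=MULTI_TAXA)
        assert list(m.columns) == MULTI_TAXA


class TestElectropherogram:
    def test_zero_richness_calls_zero(self):
        prof = generate_electropherogram(0, (100, 1200), seed=1, noise_peaks=10)
        assert richness(call_true_peaks(prof, "cyanobacteria")) == 0

    def test_round_trip_exact(self):
        prof = generate_electropherogram(25, (100, 1200), seed=2, noise_peaks=12)
        assert richness(call_true_peaks(prof, "cyanobacteria")) == 25

    def test_deterministic(self):
        a = generate_electropherogram(10, (100, 1400), seed=3)
        b = generate_electropherogram(10, (100, 1400), seed=3)
        np.testing.assert_array_equal(a.sizes, b.sizes)
        np.testing.assert_array_equal(a.rfu, b.rfu)

    def test_too_narrow_range_rejected(self):
        with pytest.raises(ValueError, match="narrow"):
            generate_electropherogram(100, (100, 150))

    @pytest.mark.parametrize("group,window", sorted(GROUP_WINDOWS.items()))
    def test_round_trip_over_many_profiles(self, group, window, rng):
        for _ in range(100):
            r = int(rng.integers(0, 60))
            prof = generate_electropherogram(
                r, window, seed=int(rng.integers(2**31)), noise_peaks=int(rng.integers(0, 20))
            )
            assert richness(call_true_peaks(prof, group)) == r


class TestBundle:
    def test_richness_equals_incidence_row_sums(self, bundle):
        for var, m in bundle.communities.items():
            np.testing.assert_array_equal(
                m.sum(axis=1).to_numpy(), bundle.samples[var].to_numpy()
            )

    def test_multicellular_in_range(self, bundle):
        assert bundle.samples.multi_s.between(0, 9).all()
        assert list(bundle.communities["multi_s"].columns) == MULTI_TAXA

    def test_arisa_round_trip_whole_bundle(self, bundle):
        group_var = {"cyanobacteria": "cyano_s", "fungi": "fungal_s"}
        for (group, sid), prof in bundle.electropherograms.items():
            site = int(sid.replace("site", ""))
            expected = int(bundle.samples.loc[site, group_var[group]])
            assert richness(call_true_peaks(prof, group)) == expected

    def test_sites_inside_dem(self, bundle):
        dem = bundle.dem
        assert all(dem.contains(x, y) for x, y in zip(bundle.samples.x, bundle.samples.y))
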