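"""Generator tests: known moments, planted signals, invariants, determinism."""

import numpy as np
import pandas as pd
import pytest

import envgxe as ex
from envgxe.errors import DataError, InvalidConfigError


class TestSites:
    def test_default_network_matches_published_coordinates(self):
        sites = {s.site_id: s for s in ex.simulate_programs(10, seed=0)}
        assert sites["WI"].latitude == pytest.approx(44.12)
        assert sites["WI"].longitude == pytest.approx(-89.54)
        assert sum(s.is_selection for s in sites.values()) >= 1
        assert sum(s.is_trial for s in sites.values()) >= 2

    def test_same_seed_reproduces_sites(self):
        assert ex.simulate_programs(15, seed=4) == ex.simulate_programs(15, seed=4)

    def test_single_site_rejected(self):
        with pytest.raises(InvalidConfigError):
            ex.simulate_programs(1, seed=0)

    @pytest.mark.parametrize("lat,lon", [(95.0, 0.0), (0.0, 200.0)])
    def test_coordinate_bounds_enforced(self, lat, lon):
        with pytest.raises(InvalidConfigError):
            ex.SiteDef("X", True, True, lat, lon)


class TestGenotypes:
    def test_binomial_dosage_moment(self, default_sites):
        # 2000 clones at a fixed frequency: mean dosage must match 4p
        dm, _, _ = ex.simulate_genotypes(
            2000, 3, default_sites, [ex.EnvQtl(0, "minTemp", 0.0, base_freq=0.3)],
            seed=1)
        mean = dm.dosages[0].mean()
        sd = np.sqrt(4 * 0.3 * 0.7)
        assert abs(mean - 1.2) < 3 * sd / np.sqrt(2000)

    def test_cline_shifts_program_frequencies(self):
        # two programs at z = -1, +1: frequency gap approximately 2c
        sites = [
            ex.SiteDef("LO", True, True, 30.0, -90.0,
                       climate=ex.ClimateParams(38, 4, 25, 4, 0.2)),
            ex.SiteDef("HI", True, True, 48.0, -90.0,
                       climate=ex.ClimateParams(30, 4, 17, 4, 0.2)),
        ]
        dm, _, prog = ex.simulate_genotypes(
            3000, 2, sites, [ex.EnvQtl(0, "minTemp", 0.1, base_freq=0.5)], seed=2)
        freq = {}
        for p in ("LO", "HI"):
            cols = prog[prog == p].index
            sub = dm.subset_clones(list(cols))
            freq[p] = sub.dosages[0].mean() / 4
        gap = abs(freq["HI"] - freq["LO"])
        assert gap == pytest.approx(0.2, abs=0.03)

    def test_determinism_and_frequency_band(self, default_sites):
        a, _, _ = ex.simulate_genotypes(50, 100, default_sites, seed=9)
        b, _, _ = ex.simulate_genotypes(50, 100, default_sites, seed=9)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.markers == b.markers

    def test_more_qtl_than_markers_rejected(self, default_sites):
        qtl = [ex.EnvQtl(i, "minTemp", 0.1) for i in range(3)]
        with pytest.raises(InvalidConfigError):
            ex.simulate_genotypes(10, 2, default_sites, qtl, seed=0)

    def test_dosage_csv_roundtrip(self, small_panel, tmp_path):
        dm, _, _ = small_panel
        path = tmp_path / "geno.csv"
        dm.to_csv(path)
        back = ex.DosageMatrix.from_csv(path)
        assert back.markers == dm.markers
        assert np.array_equal(back.dosages, dm.dosages)
        assert np.array_equal(back.pos, dm.pos)


class TestWeather:
    def test_zero_variance_series_is_flat(self):
        site = ex.SiteDef("X", True, True, 44.0, -90.0,
                          climate=ex.ClimateParams(30, 0, 15, 0, 0.1,
                                                   wet_day_prob=0.0,
                                                   seasonal_amp=0.0))
        w = ex.simulate_weather([site], [2020], seed=0)
        assert (w["tmax_c"] == 30).all()
        assert (w["tmin_c"] == 15).all()
        assert (w["precip_cm"] == 0).all()

    def test_physical_invariants_and_masking(self, default_sites):
        w = ex.simulate_weather(default_sites, [2019, 2020], seed=1,
                                missing_fraction=0.1)
        present = w.dropna()
        assert (present["tmax_c"] >= present["tmin_c"]).all()
        assert (present["precip_cm"] >= 0).all()
        frac = w["tmax_c"].isna().mean()
        assert frac == pytest.approx(0.1, abs=0.02)

    def test_inverted_temperature_means_clipped(self):
        site = ex.SiteDef("X", True, True, 44.0, -90.0,
                          climate=ex.ClimateParams(10, 2, 20, 2, 0.1))
        w = ex.simulate_weather([site], [2020], seed=3)
        assert (w["tmax_c"] >= w["tmin_c"]).all()

    def test_empty_inputs_rejected(self, default_sites):
        with pytest.raises(InvalidConfigError):
            ex.simulate_weather([], [2020], seed=0)
        with pytest.raises(InvalidConfigError):
            ex.simulate_weather(default_sites, [], seed=0)


class TestYields:
    def test_noise_free_limit_equals_fixed_effects(self, default_sites):
        dm, truth, _ = ex.simulate_genotypes(20, 10, default_sites, seed=0)
        truth.variance_components = {"g": 0, "gY": 0, "gL": 0, "gYL": 0, "e": 0}
        truth.year_effects = {2020: 1.0, 2021: -2.0}
        truth.loc_effects = {"A": 3.0, "B": 0.0}
        truth.yl_effects = {("A", 2020): 0.5}
        lay = ex.make_trial_layout(dm.clones, ["A", "B"], [2020, 2021], 1)
        y = ex.simulate_yields(dm, truth, lay, seed=0)
        expected = (truth.mu
                    + y["year"].map(truth.year_effects)
                    + y["location"].map(truth.loc_effects)
                    + [truth.yl_effects.get((l, t), 0.0)
                       for l, t in zip(y["location"], y["year"])])
        assert np.allclose(y["plot_yield_kg"], expected)

    def test_clone_variance_moment(self, default_sites):
        dm, truth, _ = ex.simulate_genotypes(1000, 5, default_sites, seed=1)
        truth.variance_components = {"g": 1.0, "gY": 0, "gL": 0, "gYL": 0, "e": 0}
        lay = ex.make_trial_layout(dm.clones, ["A", "B"], [2020], 1)
        y = ex.simulate_yields(dm, truth, lay, seed=2)
        clone_means = y.groupby("clone")["plot_yield_kg"].mean()
        assert clone_means.var() == pytest.approx(1.0, rel=0.10)

    def test_raw_slope_qtl_recovered_per_dosage_class(self, default_sites):
        # regression of yield on E within a dosage class has slope beta * d
        dm, truth, _ = ex.simulate_genotypes(
            600, 5, default_sites, [ex.EnvQtl(0, "minTemp", 0.0, base_freq=0.5)],
            seed=3)
        truth.slope_qtl = [ex.SlopeQtl(0, "maxTemp", 0.05, scale="raw")]
        truth.variance_components = {"g": 0, "gY": 0, "gL": 0, "gYL": 0, "e": 1e-4}
        te = pd.DataFrame({"location": ["A", "B", "A", "B"],
                           "year": [1, 1, 2, 2],
                           "maxTemp": [20.0, 24.0, 28.0, 32.0]})
        lay = ex.make_trial_layout(dm.clones, ["A", "B"], [1, 2], 1)
        y = ex.simulate_yields(dm, truth, lay, trial_env=te, seed=4)
        env = te.set_index(["location", "year"])["maxTemp"]
        y["E"] = env.loc[list(zip(y["location"], y["year"]))].to_numpy()
        dos = pd.Series(dm.dosages[0], index=dm.clones)
        y["d"] = y["clone"].map(dos)
        for d in (0, 2, 4):
            sub = y[y["d"] == d]
            if len(sub) < 20:
                continue
            slope = np.polyfit(sub["E"], sub["plot_yield_kg"], 1)[0]
            assert slope == pytest.approx(0.05 * d, abs=0.01)

    def test_negative_variance_component_rejected(self, default_sites):
        dm, truth, _ = ex.simulate_genotypes(20, 5, default_sites, seed=0)
        truth.variance_components["g"] = 0.1
        lay = ex.make_trial_layout(dm.clones, ["A", "B"], [2020], 1)
        truth.variance_components = dict(truth.variance_components)
        truth.variance_components["e"] = -1.0
        with pytest.raises(InvalidConfigError):
            ex.simulate_yields(dm, truth, lay, seed=0)

    def test_yields_always_positive(self, default_sites):
        dm, truth, _ = ex.simulate_genotypes(100, 5, default_sites, seed=5)
        truth.variance_components = {"g": 50.0, "gY": 0, "gL": 0, "gYL": 0, "e": 50.0}
        lay = ex.make_trial_layout(dm.clones, ["A", "B"], [2020, 2021], 2)
        y = ex.simulate_yields(dm, truth, lay, seed=6)
        assert (y["plot_yield_kg"] > 0).all()
        assert y["floored"].any()  # large noise must have hit the floor


class TestSubmissionYears:
    def test_null_trend_for_neutral_markers(self, small_panel):
        dm, _, _ = small_panel
        years, dm2 = ex.simulate_submission_years(dm, [], seed=1)
        slopes = []
        yv = years.to_numpy(dtype=float)
        for i in range(0, 100):
            slopes.append(np.polyfit(yv, dm2.dosages[i].astype(float), 1)[0])
        assert abs(np.mean(slopes)) < 0.01

    def test_planted_trend_shifts_frequency(self, default_sites):
        dm, _, _ = ex.simulate_genotypes(3000, 5, default_sites, seed=8)
        years, dm2 = ex.simulate_submission_years(
            dm, [ex.GpsmQtl(0, 0.02, base_freq=0.3)], (2010, 2022), seed=8)
        f_first = dm2.dosages[0][years <= 2012].mean() / 4
        f_last = dm2.dosages[0][years >= 2020].mean() / 4
        # expected gap: 0.02/yr x ~9 years between window centers
        assert f_last - f_first == pytest.approx(0.02 * 9, abs=0.04)

    def test_single_year_design_refused_downstream(self, small_panel):
        dm, _, _ = small_panel
        years = pd.Series(2015, index=dm.clones)
        with pytest.raises(DataError):
            ex.run_gpsm(dm, years, ex.AnalysisConfig())
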