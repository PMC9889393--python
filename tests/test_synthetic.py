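import numpy as np
import pytest

from fluxgap import (
    ForcingConfig,
    TruthModel,
    default_noise_model,
    fit_noise_model,
    fit_truth_surrogate,
    generate_forcing,
    inject_noise,
    make_synthetic_year,
    swr_skewness,
    truth_nee,
)
from fluxgap.synthetic import NoiseModel

from conftest import make_series


class TestForcing:
    def test_non_leap_year_has_17520_records(self):
        s = generate_forcing(ForcingConfig(year=2015))
        assert len(s) == 17520

    def test_leap_year_has_17568_records(self):
        s = generate_forcing(ForcingConfig(year=2020))
        assert len(s) == 17568

    def test_fixed_seed_reproducible(self):
        a = generate_forcing(ForcingConfig(), seed=7)
        b = generate_forcing(ForcingConfig(), seed=7)
        assert a.equals(b)

    def test_swr_nonnegative_and_dark_below_horizon(self):
        s = generate_forcing(ForcingConfig(latitude=67.99), seed=0)
        assert np.all(s.swr >= 0)
        # winter-solstice day at a polar-night latitude stays dark
        solstice = s.day_of_year == 355
        assert np.all(s.swr[solstice] == 0.0)

    def test_daytime_skewness_rises_with_latitude(self):
        # medians over 20 seeds, 35°N → 65°N, strictly increasing
        medians = []
        for lat in (35.0, 45.0, 55.0, 65.0):
            vals = [
                swr_skewness(
                    generate_forcing(ForcingConfig(latitude=lat), seed=s), "daytime"
                )
                for s in range(20)
            ]
            medians.append(np.median(vals))
        assert all(a < b for a, b in zip(medians, medians[1:]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            generate_forcing(ForcingConfig(clear_sky_transmittance=1.5))
        with pytest.raises(ValueError):
            generate_forcing(ForcingConfig(cloud_persistence=1.0))
        with pytest.raises(ValueError):
            generate_forcing(ForcingConfig(tair_annual_amplitude=-1.0))


class TestTruthModel:
    def test_dark_nee_equals_respiration(self):
        m = TruthModel()
        for t in (-10.0, 0.0, 10.0, 20.0):
            expected = m.r10 * m.q10 ** ((t - 10.0) / 10.0)
            assert truth_nee(m, 0.0, t, 5.0, 180) == pytest.approx(expected)

    def test_half_saturation_by_construction(self):
        m = TruthModel(vpd_sensitivity=0.0, season_start=-500.0, season_end=5000.0)
        dark = truth_nee(m, 0.0, 10.0, 0.0, 180)
        half = truth_nee(m, m.k_half, 10.0, 0.0, 180)
        season = m.season(180)
        assert dark - half == pytest.approx(season * m.pmax / 2.0, rel=1e-6)

    def test_saturating_limit(self):
        m = TruthModel(vpd_sensitivity=0.0)
        lo = truth_nee(m, 1e7, 10.0, 0.0, 180)
        asymptote = m.r10 - m.season(180) * m.pmax
        assert lo == pytest.approx(asymptote, rel=1e-4)

    def test_monotone_nonincreasing_in_swr(self):
        m = TruthModel()
        swr = np.linspace(0.0, 1200.0, 400)
        for t, v, d in ((0.0, 1.0, 60), (10.0, 5.0, 180), (20.0, 10.0, 240)):
            nee = truth_nee(m, swr, np.full_like(swr, t), np.full_like(swr, v), d)
            assert np.all(np.diff(nee) <= 1e-12)

    def test_negative_swr_rejected(self):
        with pytest.raises(ValueError):
            truth_nee(TruthModel(), -1.0, 10.0, 1.0, 100)


class TestNoiseModel:
    def test_number_of_bins(self):
        assert NoiseModel.N_BINS == 2 * 2 * 5

    def test_winter_night_bin_assignment(self):
        # month 3 with swr 10 W m⁻² is winter/night whatever the quintile
        model = NoiseModel(tair_edges=np.array([-5.0, 0.0, 5.0, 10.0]))
        idx = model.bin_index(np.array([3]), np.array([10.0]), np.array([2.0]))
        assert 0 <= idx[0] < 5  # winter block, night sub-block

    def test_swr_exactly_20_is_night(self):
        model = NoiseModel(tair_edges=np.array([-5.0, 0.0, 5.0, 10.0]))
        night = model.bin_index(np.array([6]), np.array([20.0]), np.array([2.0]))
        day = model.bin_index(np.array([6]), np.array([20.0 + 1e-9]), np.array([2.0]))
        assert 10 <= night[0] < 15  # summer/night
        assert 15 <= day[0] < 20  # summer/day

    def test_every_record_maps_to_exactly_one_bin(self, year_pair):
        clean, _ = year_pair
        model = default_noise_model(clean, seed=0)
        idx = model.bin_index(clean.month, clean.swr, clean.tair)
        assert idx.min() >= 0 and idx.max() < 20
        assert idx.shape == (len(clean),)

    def test_tair_quintiles_equal_count(self, year_pair):
        clean, _ = year_pair
        model = default_noise_model(clean, seed=0)
        q = np.searchsorted(model.tair_edges, clean.tair, side="right")
        counts = np.bincount(q, minlength=5)
        assert counts.max() - counts.min() <= len(clean) // 20

    def test_strict_mode_names_the_empty_bin(self, year_pair):
        clean, _ = year_pair
        residuals = np.random.default_rng(0).normal(size=len(clean))
        with pytest.raises(ValueError, match="winter/night"):
            fit_noise_model(clean, residuals, require_all_bins=True)

    def test_misaligned_residuals_rejected(self, year_pair):
        clean, _ = year_pair
        with pytest.raises(ValueError):
            fit_noise_model(clean, np.zeros(10))


class TestInjectNoise:
    def test_zero_pools_return_input(self, year_pair):
        clean, _ = year_pair
        model = fit_noise_model(clean, np.zeros(len(clean)))
        out = inject_noise(clean, model, seed=3)
        np.testing.assert_array_equal(out.nee, clean.nee)

    def test_single_bin_resampling_is_centred(self):
        # one ±1 pool, 10,000 records: mean perturbation ≈ 0 within 3 SE
        n = 10000
        s = make_series(n, nee=np.zeros(n), swr=np.zeros(n), tair=np.full(n, 10.0))
        model = NoiseModel(tair_edges=np.array([1.0, 2.0, 3.0, 4.0]))
        model.pools = [np.array([1.0, -1.0])] * 20
        out = inject_noise(s, model, seed=5)
        se = 1.0 / np.sqrt(n)
        assert abs(np.mean(out.nee - s.nee)) < 3 * se

    def test_fixed_seed_identical(self, year_pair):
        clean, _ = year_pair
        model = default_noise_model(clean, seed=0)
        a = inject_noise(clean, model, seed=9)
        b = inject_noise(clean, model, seed=9)
        np.testing.assert_array_equal(a.nee, b.nee)

    def test_record_mapping_to_empty_pool_errors(self, year_pair):
        clean, _ = year_pair
        model = default_noise_model(clean, seed=0)
        model.pools = [np.array([])] * 20
        with pytest.raises(ValueError, match="empty residual bin"):
            inject_noise(clean, model, seed=0)

    def test_preserves_count_and_timestamps(self, year_pair):
        clean, noisy = year_pair
        assert len(noisy) == len(clean)
        assert noisy.time.equals(clean.time)


class TestMakeSyntheticYear:
    def test_pair_is_gap_free_and_seeded(self):
        a_clean, a_noisy = make_synthetic_year(seed=11)
        b_clean, b_noisy = make_synthetic_year(seed=11)
        assert a_noisy.measured.all()
        assert a_clean.equals(b_clean) and a_noisy.equals(b_noisy)

    def test_distinct_seeds_distinct_noise(self):
        _, a = make_synthetic_year(seed=1)
        _, b = make_synthetic_year(seed=2)
        assert not np.array_equal(a.nee, b.nee)


class TestSurrogate:
    def test_recovers_driver_only_generating_function(self):
        # with the seasonal switch flat, NEE is an exact smooth function of
        # the four predictors and the network should recover it closely
        truth = TruthModel(season_start=-200.0, season_end=2000.0)
        clean, _ = make_synthetic_year(truth=truth, seed=3)
        rng = np.random.default_rng(0)
        hold = rng.random(len(clean)) < 0.3
        train = clean.copy()
        train.nee[hold] = np.nan
        train.qc[hold] = 1
        model = fit_truth_surrogate(train, epochs=150, learning_rate=3e-3, seed=0)
        pred = model.predict_series(clean)
        resid = pred[hold] - clean.nee[hold]
        assert np.all(np.isfinite(pred))
        assert np.sqrt(np.mean(resid**2)) < 0.05 * np.std(clean.nee)

    def test_insufficient_data_rejected(self):
        n = 200
        s = make_series(n, tsoil=np.full(n, 5.0))
        with pytest.raises(ValueError):
            fit_truth_surrogate(s)

    def test_requires_tsoil(self, year_pair):
        clean, _ = year_pair
        s = clean.copy()
        s.tsoil = None
        with pytest.raises(ValueError, match="tsoil"):
            fit_truth_surrogate(s)

    def test_repeated_generation_yields_distinct_noisy_sets(self, year_pair):
        clean, _ = year_pair
        noise = default_noise_model(clean, seed=0)
        sets = [inject_noise(clean, noise, seed=k) for k in range(5)]
        for i in range(5):
            for j in range(i + 1, 5):
                assert not np.array_equal(sets[i].nee, sets[j].nee)
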