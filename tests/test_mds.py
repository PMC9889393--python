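import numpy as np
import pytest

from fluxgap import (
    GapPlan,
    MDSConfig,
    fill_gap,
    fill_gap_subsample_variant,
    fill_loo,
    fill_series,
    sample_candidates,
    swr_tolerance,
)
from fluxgap.mds import UNFILLED, KIND_ALL, KIND_MDC, KIND_SWR, default_window_schedule

from conftest import make_series
from oracle_mds import brute_force_fill


class TestTolerances:
    def test_two_band_rule(self):
        cfg = MDSConfig.preset("standard")
        assert swr_tolerance(cfg, 30.0) == 20.0
        assert swr_tolerance(cfg, 55.0) == 50.0
        assert swr_tolerance(cfg, 50.0) == 20.0  # tie takes the low band

    def test_single_tolerance_variant(self):
        cfg = MDSConfig.preset("single_tol")
        for target in (0.0, 30.0, 55.0, 500.0):
            assert swr_tolerance(cfg, target) == 25.0

    def test_narrowed_preset(self):
        cfg = MDSConfig.preset("narrowed")
        assert (cfg.swr_tol_low, cfg.swr_tol_high) == (10.0, 25.0)

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            swr_tolerance(MDSConfig.preset("standard"), -1.0)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            MDSConfig(swr_tol_low=0.0)
        with pytest.raises(ValueError):
            MDSConfig(min_sample=0)
        with pytest.raises(ValueError):
            MDSConfig(variant="bogus")


class TestSampleCandidates:
    def _series(self):
        # index 1 is the gap (swr 55, tair 10, vpd 3)
        nee = np.array([1.0, np.nan, 2.0, 3.0])
        swr = np.array([10.0, 55.0, 55.0, 55.0])
        tair = np.array([11.0, 10.0, 13.0, 10.0])
        vpd = np.array([5.0, 3.0, 3.0, 3.0])
        qc = np.array([0, 1, 0, 0])
        return make_series(4, nee=nee, qc=qc, swr=swr, tair=tair, vpd=vpd)

    def test_tolerance_predicates(self):
        s = self._series()
        cfg = MDSConfig.preset("standard")
        got = sample_candidates(s, 1, 7, cfg, use_all_drivers=True)
        # record 0: |Δswr|=45≤50, |Δtair|=1≤2.5, |Δvpd|=2≤5 → included
        # record 2: |Δtair|=3>2.5 → excluded; record 3: all match
        assert got == [(1.0, 10.0), (3.0, 55.0)]

    def test_swr_only_mode_readmits_tair_violations(self):
        s = self._series()
        got = sample_candidates(s, 1, 7, MDSConfig.preset("standard"), use_all_drivers=False)
        assert got == [(1.0, 10.0), (2.0, 55.0), (3.0, 55.0)]

    def test_empty_window(self):
        s = self._series()
        cfg = MDSConfig(swr_tol_low=1.0, swr_tol_high=1.0, tair_tol=0.1, vpd_tol=0.1)
        assert sample_candidates(s, 0, 7, cfg) == []


class TestFillGap:
    def test_mean_of_constant_candidates(self):
        n = 96
        nee = np.full(n, 5.0)
        nee[40] = np.nan
        qc = np.zeros(n, dtype=int)
        qc[40] = 1
        s = make_series(n, nee=nee, qc=qc, swr=np.full(n, 100.0))
        value, tier, size = fill_gap(s, 40, MDSConfig.preset("standard"))
        assert value == 5.0
        assert tier == "all±7d"
        assert size == n - 1

    def test_arithmetic_mean_of_three_candidates(self):
        n = 48
        nee = np.full(n, np.nan)
        qc = np.ones(n, dtype=int)
        for i, v in zip((10, 20, 30), (-2.0, -4.0, -8.0)):
            nee[i] = v
            qc[i] = 0
        s = make_series(n, nee=nee, qc=qc, swr=np.full(n, 100.0))
        value, tier, size = fill_gap(s, 15, MDSConfig.preset("standard"))
        assert value == pytest.approx(-14.0 / 3.0)
        assert size == 3

    def test_no_drivers_falls_to_mdc(self):
        n = 48 * 5
        nee = np.full(n, 1.5)
        swr = np.full(n, 50.0)
        target = 2 * 48 + 24
        nee[target] = np.nan
        qc = np.zeros(n, dtype=int)
        qc[target] = 1
        swr[target] = np.nan
        s = make_series(n, nee=nee, qc=qc, swr=swr)
        s.tair[target] = np.nan
        s.vpd[target] = np.nan
        value, tier, size = fill_gap(s, target, MDSConfig.preset("standard"))
        assert value == 1.5
        assert tier.startswith("mdc")

    def test_unfillable_gap_flagged_not_zeroed(self):
        n = 48
        nee = np.full(n, np.nan)
        qc = np.ones(n, dtype=int)
        nee[5] = 2.0  # a single candidate < min_sample of 2
        qc[5] = 0
        s = make_series(n, nee=nee, qc=qc, swr=np.full(n, 100.0))
        value, tier, size = fill_gap(s, 20, MDSConfig.preset("standard"))
        assert np.isnan(value) and tier is None and size == 0

    def test_filling_a_measured_record_is_an_error(self):
        s = make_series(48, nee=np.ones(48))
        with pytest.raises(ValueError):
            fill_gap(s, 3, MDSConfig.preset("standard"))


class TestSubsampleVariant:
    def test_two_sided_average(self):
        cands = [(-2.0, 80.0), (-4.0, 90.0), (-8.0, 120.0)]
        got = fill_gap_subsample_variant(cands, target_swr=100.0, daytime=True)
        assert got == pytest.approx(-5.5)
        plain = np.mean([c[0] for c in cands])
        assert got != pytest.approx(plain)

    def test_symmetric_candidates_match_plain_mean(self):
        cands = [(-2.0, 80.0), (-6.0, 120.0), (-3.0, 90.0), (-5.0, 110.0)]
        got = fill_gap_subsample_variant(cands, 100.0, daytime=True)
        assert got == pytest.approx(-4.0)

    def test_night_uses_plain_mean(self):
        cands = [(-2.0, 1.0), (-4.0, 2.0), (-8.0, 10.0)]
        got = fill_gap_subsample_variant(cands, 5.0, daytime=False)
        assert got == pytest.approx(-14.0 / 3.0)

    def test_single_sided_falls_back(self):
        cands = [(-2.0, 80.0), (-4.0, 90.0)]
        got = fill_gap_subsample_variant(cands, 100.0, daytime=True)
        assert got == pytest.approx(-3.0)

    def test_exact_target_swr_excluded_from_subsamples(self):
        cands = [(-2.0, 80.0), (-100.0, 100.0), (-8.0, 120.0)]
        got = fill_gap_subsample_variant(cands, 100.0, daytime=True)
        assert got == pytest.approx(0.5 * (-2.0 + -8.0))

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            fill_gap_subsample_variant([], 100.0, daytime=True)


class TestFillSeries:
    def test_empty_mask_is_noop(self, year_pair, standard_config):
        _, noisy = year_pair
        plan = GapPlan(mask=np.zeros(len(noisy), dtype=bool))
        res = fill_series(noisy, plan, standard_config)
        np.testing.assert_array_equal(res.nee_filled, noisy.nee)
        assert not res.filled.any()

    def test_constant_series_fills_constant(self, standard_config):
        n = 48 * 10
        s = make_series(n, nee=np.full(n, 2.5), swr=np.full(n, 30.0))
        mask = np.zeros(n, dtype=bool)
        mask[100:150] = True
        res = fill_series(s, GapPlan(mask=mask), standard_config)
        assert np.all(res.nee_filled[mask] == 2.5)

    def test_masked_records_hidden_from_candidate_pool(self, standard_config):
        n = 48 * 10
        nee = np.full(n, 3.0)
        nee[200] = 1000.0  # outlier that must not contaminate once masked
        s = make_series(n, nee=nee, swr=np.full(n, 30.0))
        mask = np.zeros(n, dtype=bool)
        mask[200] = True
        res = fill_series(s, GapPlan(mask=mask), standard_config)
        assert res.nee_filled[200] == 3.0

    def test_loo_excludes_self(self, standard_config):
        n = 48 * 10
        nee = np.full(n, 3.0)
        nee[200] = 1000.0
        s = make_series(n, nee=nee, swr=np.full(n, 30.0))
        res = fill_loo(s, standard_config)
        assert res.nee_filled[200] == 3.0

    def test_deterministic(self, year_pair, catalogue, standard_config):
        from fluxgap import insert_gaps

        _, noisy = year_pair
        plan = insert_gaps(noisy, catalogue, 0.3, seed=0)
        a = fill_series(noisy, plan, standard_config)
        b = fill_series(noisy, plan, standard_config)
        np.testing.assert_array_equal(a.nee_filled, b.nee_filled)
        np.testing.assert_array_equal(a.fill_step, b.fill_step)


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "variant", ["standard", "narrowed", "single_tol", "subsample_mean"]
    )
    def test_kernel_matches_brute_force(self, variant):
        rng = np.random.default_rng(42)
        n = 400
        nee = rng.normal(0, 3, n)
        qc = (rng.random(n) < 0.15).astype(int)  # pre-existing gaps
        nee[qc != 0] = np.nan
        swr = np.abs(rng.normal(60, 80, n))
        tair = rng.normal(8, 4, n)
        vpd = np.abs(rng.normal(4, 2, n))
        # a few records with missing drivers exercise the swr-only and MDC routes
        tair[rng.integers(0, n, 8)] = np.nan
        vpd[rng.integers(0, n, 8)] = np.nan
        swr[rng.integers(0, n, 5)] = np.nan
        s = make_series(n, nee=nee, qc=qc, swr=swr, tair=tair, vpd=vpd)
        mask = s.measured & (rng.random(n) < 0.3)
        cfg = MDSConfig.preset(variant)
        res = fill_series(s, GapPlan(mask=mask), cfg)
        mismatches = 0
        for g, value, step in brute_force_fill(s, mask, cfg):
            if step is None:
                ok = res.fill_step[g] == UNFILLED
            else:
                ok = res.fill_step[g] == step and res.nee_filled[g] == value
            mismatches += not ok
        assert mismatches == 0


def test_default_schedule_shape():
    sched = default_window_schedule()
    assert sched[:6] == [
        (KIND_ALL, 7),
        (KIND_ALL, 14),
        (KIND_SWR, 7),
        (KIND_MDC, 0),
        (KIND_MDC, 1),
        (KIND_MDC, 2),
    ]
    assert sched[-1] == (KIND_MDC, 210)
    kinds = {k for k, _ in sched}
    assert kinds == {KIND_ALL, KIND_SWR, KIND_MDC}
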