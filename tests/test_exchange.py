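import numpy as np
import pytest

from mitotrace.calibration import endpoint_calibration
from mitotrace.errors import (
    ConfigurationError,
    DomainError,
    InsufficientDataError,
    UndefinedRatioError,
)
from mitotrace.exchange import (
    ExchangeResult,
    SpeciationSystem,
    _total_mg,
    atp_from_free_mg,
    exchange_pipeline,
    exchange_rate,
    free_mg_given_atp,
    inhibition_summary,
    reconstruct_atp_timecourse,
)
from mitotrace.synthetic import gen_mgg_run
from mitotrace.trace_io import Trace


def _default_sys(**kw):
    base = dict(Mg_total=1.0, adenine_total=2.0, dye_total=0.002)
    base.update(kw)
    return SpeciationSystem(**base)


def _random_system(rng):
    kd_atp = rng.uniform(0.01, 0.2)
    return SpeciationSystem(
        Mg_total=rng.uniform(0.2, 5.0),
        adenine_total=rng.uniform(0.1, 5.0),
        dye_total=rng.uniform(0.0, 0.01),
        Kd_ATP=kd_atp,
        Kd_ADP=kd_atp + rng.uniform(0.05, 1.0),
        Kd_MgG=rng.uniform(0.3, 3.0),
    )


class TestSpeciationOracle:
    def test_no_ligands_gives_total(self):
        sys = SpeciationSystem(Mg_total=1.0, adenine_total=0.0, dye_total=0.0)
        assert free_mg_given_atp(sys, 0.0) == 1.0

    def test_root_bracket_and_residual(self):
        sys = _default_sys()
        mg = free_mg_given_atp(sys, 0.0)
        assert 0.0 < mg < 1.0
        assert abs(_total_mg(sys, mg, 0.0) - sys.Mg_total) < 1e-11

    def test_more_atp_lowers_free_mg(self):
        """ATP binds Mg tighter than ADP, so converting ADP to ATP frees less Mg."""
        sys = _default_sys()
        mgs = [free_mg_given_atp(sys, a) for a in np.linspace(0.0, 2.0, 9)]
        assert np.all(np.diff(mgs) < 0)

    def test_atp_outside_total_rejected(self):
        with pytest.raises(DomainError):
            free_mg_given_atp(_default_sys(), 2.5)

    def test_equal_kds_unidentifiable(self):
        with pytest.raises(ConfigurationError):
            SpeciationSystem(Mg_total=1.0, adenine_total=2.0, Kd_ATP=0.35, Kd_ADP=0.35)


class TestClosedFormInversion:
    def test_oracle_round_trip(self):
        sys = _default_sys()
        mg = free_mg_given_atp(sys, 0.5)
        assert atp_from_free_mg(sys, mg) == pytest.approx(0.5, abs=1e-9)

    def test_all_adp_endpoint(self):
        sys = _default_sys()
        assert atp_from_free_mg(sys, free_mg_given_atp(sys, 0.0)) == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_oracle_over_random_systems(self):
        """Closed form inverts the bisection oracle to 1e-9 mM over 1000 random
        valid systems."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(1000):
            sys = _random_system(rng)
            atp = rng.uniform(0.0, sys.adenine_total)
            mg = free_mg_given_atp(sys, atp)
            worst = max(worst, abs(atp_from_free_mg(sys, mg) - atp))
        assert worst < 1e-9

    def test_conservation_at_reconstructed_point(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            sys = _random_system(rng)
            atp = rng.uniform(0.0, sys.adenine_total)
            mg = free_mg_given_atp(sys, atp)
            assert _total_mg(sys, mg, atp_from_free_mg(sys, mg)) == pytest.approx(
                sys.Mg_total, abs=1e-9
            )

    def test_free_mg_out_of_range(self):
        with pytest.raises(DomainError):
            atp_from_free_mg(_default_sys(), 1.5)


class TestReconstruction:
    def test_noiseless_run_matches_generator_truth(self):
        trace, events, cfg, truth = gen_mgg_run("crangon", "control", seed=1, noise_frac=0.0)
        sys = SpeciationSystem.from_config(cfg, adenine_total=truth["adenine_total_mM"])
        cal = endpoint_calibration(trace, events)
        atp = reconstruct_atp_timecourse(trace, events, cal, sys)
        adp_t = events.first("ADP").time
        m = (atp.time >= adp_t) & (atp.time < 239.0)
        expected = np.minimum(truth["rate_mM_per_min"] * (atp.time[m] - adp_t) / 60.0, 1.0)
        np.testing.assert_allclose(atp.signal[m], expected, atol=1e-6)
        assert np.all(atp.signal[atp.time < adp_t] == 0.0)

    def test_saturated_samples_flagged_rest_reconstructed(self):
        trace, events, cfg, truth = gen_mgg_run("crangon", "control", seed=1, noise_frac=0.0)
        sig = trace.signal.copy()
        burst = (trace.time >= 100.0) & (trace.time < 102.0)  # detector railed briefly
        sig[burst] = truth["F_max"]
        spiked = Trace(trace.time, sig, trace.units, trace.channel)
        sys = SpeciationSystem.from_config(cfg, adenine_total=truth["adenine_total_mM"])
        cal = endpoint_calibration(spiked, events)
        atp = reconstruct_atp_timecourse(spiked, events, cal, sys)
        railed = (atp.time >= 100.0) & (atp.time < 102.0)
        assert np.all(np.isnan(atp.signal[railed]))
        good = (atp.time >= 65.0) & (atp.time < 100.0)
        expected = truth["rate_mM_per_min"] * (atp.time[good] - 60.0) / 60.0
        np.testing.assert_allclose(atp.signal[good], expected, atol=1e-6)

    def test_flat_trace_reconstructs_zero(self):
        trace, events, cfg, truth = gen_mgg_run("crangon", "control", seed=1,
                                                rate=0.0, noise_frac=0.0)
        res = exchange_pipeline(trace, events, cfg)
        assert res.rate == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.atp_timecourse.signal, 0.0, atol=1e-9)


class TestExchangeRate:
    def test_noiseless_linear_slope(self):
        t = np.arange(0.0, 60.0, 0.2)
        atp = Trace(t, 0.1 / 60.0 * t, units="mM", channel="ATP")
        res = exchange_rate(atp, window=(0.0, 60.0))
        assert res.rate == pytest.approx(0.1, abs=1e-12)
        assert res.rate_se == pytest.approx(0.0, abs=1e-9)

    def test_flat_input_zero_rate(self):
        t = np.arange(0.0, 60.0, 0.2)
        res = exchange_rate(Trace(t, np.full_like(t, 0.3), "mM"), window=(0.0, 60.0))
        assert res.rate == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_within_three_se(self):
        rng = np.random.default_rng(9)
        t = np.arange(0.0, 60.0, 0.2)  # 300 samples
        truth = 0.1
        atp = Trace(t, truth / 60.0 * t + rng.normal(0, 0.002, t.size), "mM")
        res = exchange_rate(atp, window=(0.0, 60.0))
        assert abs(res.rate - truth) < 3 * res.rate_se

    def test_too_few_samples(self):
        t = np.arange(0.0, 1.2, 0.2)
        with pytest.raises(InsufficientDataError):
            exchange_rate(Trace(t, t, "mM"), window=(0.0, 1.2))

    def test_auto_window_stops_at_quarter_consumed(self):
        t = np.arange(0.0, 120.0, 0.2)
        atp = Trace(t, np.minimum(0.05 * t, 2.0), "mM")  # fast: 0.5 mM (25% of 2) at t=10
        res = exchange_rate(atp, window="auto", t_adp=0.0, A_total=2.0)
        assert res.window[1] <= 10.5


class TestInhibition:
    def _res(self, rate):
        return ExchangeResult(rate=rate, rate_se=0.0, window=(0.0, 60.0))

    def test_arithmetic(self):
        assert inhibition_summary(self._res(0.1), self._res(0.01)) == pytest.approx(90.0)

    def test_identity_is_zero(self):
        assert inhibition_summary(self._res(0.1), self._res(0.1)) == 0.0

    def test_faster_than_control_clamped(self):
        assert inhibition_summary(self._res(0.1), self._res(0.2)) == 0.0

    def test_zero_control_undefined(self):
        with pytest.raises(UndefinedRatioError):
            inhibition_summary(self._res(0.0), self._res(0.0))

    def test_bka_preset_pair_strongly_inhibited(self):
        ctrl = exchange_pipeline(*gen_mgg_run("crangon", "control", seed=3)[:3])
        bka = exchange_pipeline(*gen_mgg_run("crangon", "BKA", seed=3)[:3])
        assert inhibition_summary(ctrl, bka) >= 80.0


class TestRateRecovery:
    @pytest.mark.parametrize("rate", [0.02, 0.05, 0.1, 0.3])
    def test_recovery_within_five_percent(self, rate):
        """At 1% noise of the exchange-phase excursion, OLS recovers the
        generator's rate within 5% relative error."""
        for seed in range(1, 6):
            trace, events, cfg, truth = gen_mgg_run("crangon", seed=seed, rate=rate)
            res = exchange_pipeline(trace, events, cfg)
            assert abs(res.rate - rate) / rate < 0.05

    def test_mass_specific_rate_units(self):
        res = ExchangeResult(rate=0.1, rate_se=0.0, window=(0.0, 60.0))
        cfg_rate = res.rate_nmol_per_min_per_mg(
            __import__("mitotrace").AssayConfig(chamber_volume=2.0, protein_mass=1.0)
        )
        assert cfg_rate == pytest.approx(200.0)  # 0.1 mM/min x 2 ml = 0.2 µmol/min /1 mg
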