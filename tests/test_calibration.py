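import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitotrace.calibration import (
    PolarizationScale,
    adp_depolarization_percent,
    dose_response_table,
    endpoint_calibration,
    fit_ph_calibration,
    free_mg_from_fluorescence,
    normalize_scatter,
    ph_from_ratio,
    polarization_percent,
    ratio_from_ph,
)
from mitotrace.errors import (
    BelowFloorError,
    CalibrationError,
    DomainError,
    EventError,
    InsufficientDataError,
    SaturationError,
)
from mitotrace.synthetic import gen_bcecf_calibration, gen_safranine_run
from mitotrace.trace_io import CalibrationResult, Event, EventLog, Trace


def _cal(f_min=100.0, f_max=600.0):
    return CalibrationResult("MgG", {"F_min": f_min, "F_max": f_max})


class TestEndpointCalibration:
    def test_clean_plateaus(self, endpoint_trace):
        trace, events = endpoint_trace
        cal = endpoint_calibration(trace, events)
        assert cal.params["F_min"] == pytest.approx(100.0)
        assert cal.params["F_max"] == pytest.approx(600.0)

    def test_noisy_plateaus_within_median_error(self, endpoint_trace):
        trace, events = endpoint_trace
        rng = np.random.default_rng(3)
        sigma = 2.0
        noisy = Trace(trace.time, trace.signal + rng.normal(0, sigma, len(trace)), "afu")
        cal = endpoint_calibration(noisy, events)
        n = 100  # 20 s plateau at 5 Hz
        assert cal.params["F_min"] == pytest.approx(100.0, abs=3 * sigma / np.sqrt(n))
        assert cal.params["F_max"] == pytest.approx(600.0, abs=3 * sigma / np.sqrt(n))

    def test_missing_mgcl2_event(self, endpoint_trace):
        trace, _ = endpoint_trace
        events = EventLog([Event(30.0, "EDTA", 5.0, "mM")])
        with pytest.raises(CalibrationError, match="incomplete"):
            endpoint_calibration(trace, events)

    def test_inverted_plateaus(self, endpoint_trace, clock):
        t = clock(120.0)
        sig = np.where(t < 70.0, 600.0, 100.0)  # floor above ceiling
        events = EventLog([Event(30.0, "EDTA", 5.0, "mM"), Event(70.0, "MgCl2", 25.0, "mM")])
        with pytest.raises(CalibrationError, match="inverted"):
            endpoint_calibration(Trace(t, sig, "afu"), events)


class TestFreeMg:
    @pytest.mark.parametrize(
        "F, expected",
        [(100.0, 0.0), (350.0, 1.0), (200.0, 0.25)],  # floor, half-saturation=Kd, isotherm point
    )
    def test_isotherm_inversion(self, F, expected):
        assert free_mg_from_fluorescence(F, _cal(), Kd_MgG=1.0) == pytest.approx(expected)

    def test_forward_inverse_identity(self):
        mg = 0.25
        F = 100.0 + 500.0 * mg / (1.0 + mg)
        assert free_mg_from_fluorescence(F, _cal(), 1.0) == pytest.approx(mg, abs=1e-9)

    def test_saturation_and_floor_errors(self):
        with pytest.raises(SaturationError):
            free_mg_from_fluorescence(595.0, _cal(), 1.0)  # within 2% band of F_max
        with pytest.raises(BelowFloorError):
            free_mg_from_fluorescence(85.0, _cal(), 1.0)

    def test_floor_band_clamped_to_zero(self):
        assert free_mg_from_fluorescence(95.0, _cal(), 1.0) == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(min_value=100.0, max_value=589.0), st.floats(min_value=100.0, max_value=589.0))
    def test_strictly_increasing_in_fluorescence(self, f1, f2):
        if f1 == f2:
            return
        lo, hi = sorted((f1, f2))
        assert free_mg_from_fluorescence(lo, _cal(), 1.0) < free_mg_from_fluorescence(hi, _cal(), 1.0)


class TestPHCalibration:
    def test_noiseless_recovery_over_random_truths(self):
        """Exact model recovery to 1e-6 relative across 100 random parameter sets."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            truth = (rng.uniform(8.0, 11.0), rng.uniform(-1.5, -0.2), rng.uniform(0.05, 0.8))
            pts = gen_bcecf_calibration(truth, n_points=11, noise_sd=0.0)
            cal = fit_ph_calibration(pts)
            np.testing.assert_allclose((cal.a, cal.b, cal.c), truth, rtol=1e-6)
            assert cal.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_fit_quality(self):
        pts = gen_bcecf_calibration(noise_sd=0.005, seed=1)
        cal = fit_ph_calibration(pts)
        assert cal.r_squared > 0.99
        assert all(np.isfinite([cal.se_a, cal.se_b, cal.se_c]))

    def test_too_few_points(self):
        pts = gen_bcecf_calibration(n_points=4)[:3]
        with pytest.raises(InsufficientDataError):
            fit_ph_calibration(pts)

    def test_narrow_ph_span(self):
        pts = gen_bcecf_calibration(n_points=6, ph_range=(7.0, 7.3))
        with pytest.raises(InsufficientDataError, match="span"):
            fit_ph_calibration(pts)

    def test_interpolation_identity_and_inverse(self):
        truth = (9.0, -0.5, 0.1)
        pts = gen_bcecf_calibration(truth, n_points=11)
        cal = fit_ph_calibration(pts)
        x0, ph0 = pts[4]
        assert ph_from_ratio(x0, cal) == pytest.approx(ph0, abs=1e-6)
        assert ratio_from_ph(ph_from_ratio(x0, cal), cal) == pytest.approx(x0, abs=1e-9)

    def test_pole_domain_error(self):
        cal = fit_ph_calibration(gen_bcecf_calibration())
        with pytest.raises(DomainError):
            ph_from_ratio(-cal.c - 0.1, cal)


class TestPolarization:
    scale = PolarizationScale(F_baseline=100.0, F_uncoupled=600.0)

    @pytest.mark.parametrize("F, expected", [(100.0, 100.0), (600.0, 0.0), (350.0, 50.0)])
    def test_percent_scale(self, F, expected):
        tr = Trace([0.0, 1.0], [F, F], "afu")
        assert polarization_percent(tr, self.scale).signal == pytest.approx(expected)

    def test_degenerate_scale(self):
        with pytest.raises(CalibrationError):
            PolarizationScale(F_baseline=100.0, F_uncoupled=100.0)

    @settings(max_examples=25, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=10.0), st.floats(min_value=-50.0, max_value=50.0))
    def test_affine_invariance(self, gain, offset):
        """Gain/offset changes of the raw signal leave percentages unchanged."""
        rng = np.random.default_rng(5)
        sig = rng.uniform(100.0, 600.0, 20)
        t = np.arange(20.0)
        p1 = polarization_percent(Trace(t, sig, "afu"), self.scale)
        p2 = polarization_percent(
            Trace(t, gain * sig + offset, "afu"),
            PolarizationScale(gain * 100.0 + offset, gain * 600.0 + offset),
        )
        np.testing.assert_allclose(p1.signal, p2.signal, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("depth", [30.0, 0.0, 100.0])
    def test_adp_depolarization_depth(self, clock, depth):
        t = clock(300.0)
        sig = np.full_like(t, 100.0)
        sig[t >= 120.0] = 100.0 + depth / 100.0 * 500.0
        events = EventLog([Event(120.0, "ADP", 2.0, "mM")])
        d = adp_depolarization_percent(Trace(t, sig, "afu"), events, self.scale)
        assert d == pytest.approx(depth, abs=1e-9)

    def test_missing_adp_event(self, clock):
        tr = Trace(clock(100.0), np.full(501, 100.0), "afu")
        with pytest.raises(EventError):
            adp_depolarization_percent(tr, EventLog([]), self.scale)


class TestDoseResponse:
    def test_bka_sensitive_rows_monotone(self):
        runs = []
        for dose in [0, 1.25, 2.5, 5, 10, 20]:
            tr, ev, scale, _ = gen_safranine_run("mouse-liver", 7.3, dose, seed=2)
            runs.append((tr, ev, scale, 7.3, dose))
        out = dose_response_table(runs)
        assert out.monotone_nonincreasing[7.3] is True
        row = out.table.loc[7.3]
        assert row[0] > row[20]  # inhibitor clearly dampens depolarization

    def test_insensitive_preset_flat_row(self):
        runs = []
        for dose in [0, 5, 20]:
            tr, ev, scale, _ = gen_safranine_run("artemia", 7.3, dose, seed=2)
            runs.append((tr, ev, scale, 7.3, dose))
        out = dose_response_table(runs)
        assert out.monotone_nonincreasing[7.3] is True
        row = out.table.loc[7.3]
        assert abs(row[20] - row[0]) < 3.0  # flat within noise

    def test_empty_runs(self):
        out = dose_response_table([])
        assert out.table.empty and out.monotone_nonincreasing == {}


class TestNormalizeScatter:
    def _trace(self, clock, drop_to=None):
        t = clock(400.0)
        sig = np.full_like(t, 1000.0)
        if drop_to is not None:
            sig[t >= 150.0] = drop_to
        sig[t >= 300.0] = 300.0
        events = EventLog(
            [Event(60.0, "CaCl2", 0.2, "mM"), Event(300.0, "alamethicin", 40.0, "ug")]
        )
        return Trace(t, sig, "afu_scatter"), events

    def test_endpoints(self, clock):
        tr, ev = self._trace(clock)
        s = normalize_scatter(tr, ev)
        assert s.signal[0] == pytest.approx(100.0)
        assert s.signal[-1] == pytest.approx(0.0)

    def test_no_swelling_stays_high(self, clock):
        tr, ev = self._trace(clock)
        s = normalize_scatter(tr, ev)
        pre = s.signal[s.time < 300.0]
        assert np.all(pre >= 90.0)

    def test_inverted_scatter_error(self, clock):
        t = clock(400.0)
        sig = np.where(t < 300.0, 300.0, 1000.0)
        ev = EventLog([Event(60.0, "CaCl2", 0.2, "mM"), Event(300.0, "alamethicin", 40.0, "ug")])
        with pytest.raises(CalibrationError, match="inverted"):
            normalize_scatter(Trace(t, sig, "afu_scatter"), ev)

    def test_missing_alamethicin(self, clock):
        tr, _ = self._trace(clock)
        with pytest.raises(CalibrationError):
            normalize_scatter(tr, EventLog([Event(60.0, "CaCl2", 0.2, "mM")]))
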