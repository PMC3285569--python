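"""Threshold-crossing detection, APD/DI arithmetic, CV fitting,
restitution curves and wavelength estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atriasim import (detect_crossings, compute_apd_di, measure_cv,
                      estimate_wavelength, RestitutionCurve,
                      select_recording_sites, make_sheet)
from atriasim.measure import _pava, CrossingSeries


def brute_force_crossings(t, v, thr):
    ups, downs = [], []
    for i in range(len(v) - 1):
        if v[i] < thr <= v[i + 1]:
            ups.append(t[i] + (thr - v[i]) / (v[i + 1] - v[i]) * (t[i + 1] - t[i]))
        elif v[i] >= thr > v[i + 1]:
            downs.append(t[i] + (thr - v[i]) / (v[i + 1] - v[i]) * (t[i + 1] - t[i]))
    return np.array(ups), np.array(downs)


class TestCrossings:
    def test_trapezoid_apd_200ms(self):
        t = np.arange(0.0, 400.0, 0.5)
        v = np.full_like(t, -80.0)
        v[(t >= 10) & (t < 210)] = 20.0
        v[t >= 210] = -80.0
        # linear ramps of one sample each give interpolable crossings
        s = detect_crossings(t, v)
        apd, di = compute_apd_di(s)
        assert apd[0] == pytest.approx(200.0, abs=0.5)

    def test_flat_trace_yields_empty_series(self):
        t = np.arange(0, 100.0, 1.0)
        s = detect_crossings(t, np.full_like(t, -81.0))
        assert s.ups.size == 0 and s.downs.size == 0

    def test_matches_brute_force_scan_on_noisy_ap(self, rng):
        t = np.arange(0.0, 1000.0, 0.5)
        v = -80 + 100 * np.exp(-((t % 330 - 80) / 60.0) ** 2) \
            + rng.normal(0, 2.0, t.size)
        s = detect_crossings(t, v)
        bu, bd = brute_force_crossings(t, v, -70.0)
        np.testing.assert_allclose(s.ups, bu, atol=1e-12)
        np.testing.assert_allclose(s.downs, bd, atol=1e-12)

    def test_coarse_sampling_rejected(self):
        t = np.arange(0, 100, 2.0)
        with pytest.raises(ValueError):
            detect_crossings(t, np.zeros_like(t))


class TestApdDi:
    def test_spec_arithmetic(self):
        s = CrossingSeries(ups=np.array([0.0, 500.0]),
                           downs=np.array([220.0, 720.0]))
        apd, di = compute_apd_di(s)
        np.testing.assert_allclose(apd, [220.0, 220.0])
        np.testing.assert_allclose(di, [280.0])

    def test_single_ap(self):
        s = CrossingSeries(ups=np.array([10.0]), downs=np.array([180.0]))
        apd, di = compute_apd_di(s)
        assert apd.tolist() == [170.0] and di.size == 0

    def test_trailing_incomplete_ap_dropped(self):
        s = CrossingSeries(ups=np.array([0.0, 500.0, 900.0]),
                           downs=np.array([220.0, 700.0]))
        apd, _ = compute_apd_di(s)
        assert apd.size == 2


class TestCV:
    def test_exact_linear_fit(self):
        x = np.linspace(1.0, 3.0, 9)
        t = x / 0.065
        assert measure_cv(t, x) == pytest.approx(0.065, rel=1e-12)

    def test_nonplanar_wave_rejected(self):
        x = np.linspace(0, 2, 6)
        t = np.array([0.0, 1.0, 0.5, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="planar"):
            measure_cv(t, x)

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError):
            measure_cv(np.array([0, 1, 2.0]), np.array([0, 1, 2.0]))


class TestRestitutionCurve:
    def _curve(self):
        return RestitutionCurve(di=np.array([50.0, 100.0, 200.0, 400.0]),
                                cv=np.array([0.05, 0.060, 0.064, 0.065]),
                                apd=np.array([120.0, 170.0, 210.0, 230.0]))

    def test_interpolation_and_range_flag(self):
        c = self._curve()
        assert c.cv_at(150.0) == pytest.approx(0.062)
        assert c.in_range(150.0) and not c.in_range(10.0)
        # flat extrapolation at the short end
        assert c.cv_at(10.0) == pytest.approx(0.05)

    def test_max_apd_slope(self):
        c = self._curve()
        assert c.max_apd_slope() == pytest.approx(1.0)   # (170-120)/50

    def test_duplicate_di_rejected(self):
        with pytest.raises(ValueError):
            RestitutionCurve(di=np.array([50.0, 50.0]),
                             cv=np.array([0.05, 0.06]),
                             apd=np.array([100.0, 120.0]))

    def test_noisy_samples_get_monotone_fit(self, rng):
        di = np.linspace(40, 400, 20)
        apd = 230 - 150 * np.exp(-di / 80.0) + rng.normal(0, 1.0, 20)
        c = RestitutionCurve(di=di, cv=np.full(20, 0.065), apd=apd)
        assert np.all(np.diff(c.apd_fit) >= 0)
        assert np.all(np.diff(c.cv_fit) >= 0)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_pava_is_monotone_and_idempotent_on_sorted(self, ys):
        fit = _pava(np.array(ys))
        assert np.all(np.diff(fit) >= -1e-9)
        srt = np.sort(np.array(ys))
        np.testing.assert_allclose(_pava(srt), srt, atol=1e-12)


class TestWavelength:
    def test_arithmetic(self):
        c = RestitutionCurve(di=np.array([50.0, 400.0]),
                             cv=np.array([0.05, 0.05]),
                             apd=np.array([150.0, 150.0]))
        w = estimate_wavelength(200.0, 100.0, c)
        assert w.wl == pytest.approx(200.0 * 0.05)       # 10 cm
        assert not w.extrapolated

    def test_degenerate_zero_apd(self):
        c = RestitutionCurve(di=np.array([50.0, 400.0]),
                             cv=np.array([0.05, 0.06]),
                             apd=np.array([150.0, 210.0]))
        assert estimate_wavelength(0.0, 100.0, c).wl == 0.0

    def test_out_of_range_di_flagged_not_dropped(self):
        c = RestitutionCurve(di=np.array([50.0, 400.0]),
                             cv=np.array([0.05, 0.06]),
                             apd=np.array([150.0, 210.0]))
        w = estimate_wavelength(180.0, 20.0, c)
        assert w.extrapolated and np.isfinite(w.wl)


class TestRecordingSites:
    def test_farthest_point_sampling_spreads_sites(self):
        dom = make_sheet(50, 50, "bulk")
        sites = select_recording_sites(dom, 16, seed=0)
        assert sites.size == 16 and np.unique(sites).size == 16
        coords = np.argwhere(dom.active)[sites] * dom.dx
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 0.15     # cm; no two sites collapse together

    def test_deterministic_for_seed(self):
        dom = make_sheet(40, 40, "bulk")
        a = select_recording_sites(dom, 8, seed=3)
        b = select_recording_sites(dom, 8, seed=3)
        assert np.array_equal(a, b)
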