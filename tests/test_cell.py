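"""Single-cell model: parameter construction, remodeling transforms,
fixed-concentration contract, integration accuracy and rate dependence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atriasim import (make_baseline_params, apply_electrical_remodeling,
                      derivatives, step_cell, rest_state, IntegrationFailure)
from atriasim.cell import (NSTATE, RATE_TABLES, K1_SCALE, _integrate_single,
                           _integrate_fixed_exact, DV_MAX, DT_SUB_MIN,
                           DT_SUB_MAX)


def _paced_apd(params, cl, n_beats, dt_max=DT_SUB_MAX, dv_max=DV_MAX):
    """Steady single-cell APD at -70 mV under periodic 80 A/F, 1 ms pacing."""
    y = rest_state(params)
    n = int(n_beats * cl / 0.01)
    rec = np.empty(n // 25 + 10)
    nrec = _integrate_single(y, params.to_array(), n, 0.01, 0.0, 1.0, 80.0,
                             cl, 25, rec, dv_max, DT_SUB_MIN, dt_max,
                             RATE_TABLES)
    v = rec[:nrec]
    t = np.arange(1, nrec + 1) * 0.25
    up = np.flatnonzero((v[:-1] < -70) & (v[1:] >= -70))
    dn = np.flatnonzero((v[:-1] >= -70) & (v[1:] < -70))
    tu = t[up] + (-70 - v[up]) / (v[up + 1] - v[up]) * 0.25
    td = t[dn] + (-70 - v[dn]) / (v[dn + 1] - v[dn]) * 0.25
    apds = [td[td > u][0] - u for u in tu if np.any(td > u)]
    return apds[-1]


class TestParams:
    def test_baseline_carries_the_standing_modifications(self, baseline):
        assert baseline.g_K1 == pytest.approx(0.09 * 1.75)
        assert K1_SCALE == 1.75
        assert baseline.K_i == 139.0
        assert baseline.Na_i == 11.2
        assert baseline.f_E == 0.0
        # unscaled source-model conductances at f_E = 0
        assert baseline.g_CaL == pytest.approx(0.12375)
        assert baseline.g_to == pytest.approx(0.1652)
        assert baseline.g_Kur == pytest.approx(1.0)

    @pytest.mark.parametrize("f_E, caL, to, kur", [
        (1.0, 0.30, 0.50, 0.50),
        (0.0, 1.00, 1.00, 1.00),
        (0.5, 0.65, 0.75, 0.75),
    ])
    def test_electrical_remodeling_scalings(self, baseline, f_E, caL, to, kur):
        p = apply_electrical_remodeling(baseline, f_E)
        assert p.g_CaL == pytest.approx(baseline.g_CaL * caL)
        assert p.g_to == pytest.approx(baseline.g_to * to)
        assert p.g_Kur == pytest.approx(baseline.g_Kur * kur)
        assert p.g_Na == baseline.g_Na and p.g_K1 == baseline.g_K1
        assert p.f_E == f_E

    @pytest.mark.parametrize("bad", [-0.1, 1.2, np.nan])
    def test_remodeling_fraction_validated(self, baseline, bad):
        with pytest.raises(ValueError):
            apply_electrical_remodeling(baseline, bad)

    @given(f=st.floats(0.0, 1.0), g=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_remodeled_conductances_nonnegative_and_monotone(self, f, g):
        base = make_baseline_params()
        pf, pg = (apply_electrical_remodeling(base, x) for x in (f, g))
        assert min(pf.g_CaL, pf.g_to, pf.g_Kur) >= 0.0
        if f <= g:
            assert pf.g_CaL >= pg.g_CaL and pf.g_to >= pg.g_to


class TestDerivatives:
    def test_rest_is_a_fixed_point(self, baseline, rest):
        dy = derivatives(rest, baseline, i_stim=0.0)
        assert abs(dy[0]) < 1e-3       # mV/ms

    def test_fixed_concentration_derivatives_are_zero(self, baseline, rest):
        dy = derivatives(rest, baseline)
        assert dy[16] == 0.0 and dy[17] == 0.0

    def test_suprathreshold_stimulus_fires_fast_upstroke(self, baseline, rest):
        y = rest.copy()
        max_dvdt = 0.0
        for k in range(3000):                      # 30 ms
            i_stim = 80.0 if k < 100 else 0.0
            dv = derivatives(y, baseline, i_stim)[0] - i_stim
            max_dvdt = max(max_dvdt, dv)
            y = step_cell(y, baseline, 0.01, i_stim)
        assert max_dvdt > 100.0                    # mV/ms, AP upstroke

    def test_nonfinite_state_rejected(self, baseline, rest):
        bad = rest.copy()
        bad[0] = np.nan
        with pytest.raises(ValueError):
            derivatives(bad, baseline)


class TestIntegration:
    def test_resting_cell_stays_put_over_one_step(self, baseline, rest):
        out = step_cell(rest, baseline, 0.01)
        assert abs(out[0] - rest[0]) < 1e-6

    def test_long_unstimulated_integration_holds_rest(self, baseline, rest):
        y = rest.copy()
        n = int(2000 / 0.01)                      # 2 s
        rec = np.empty(0)
        _integrate_single(y, baseline.to_array(), n, 0.01, 0.0, 0.0, 0.0,
                          0.0, 0, rec, DV_MAX, DT_SUB_MIN, DT_SUB_MAX,
                          RATE_TABLES)
        assert abs(y[0] - rest[0]) < 1.0

    def test_fixed_concentrations_bit_exact_after_pacing(self, baseline, rest):
        y = rest.copy()
        n = int(2 * 500 / 0.01)
        rec = np.empty(0)
        _integrate_single(y, baseline.to_array(), n, 0.01, 0.0, 1.0, 80.0,
                          500.0, 0, rec, DV_MAX, DT_SUB_MIN, DT_SUB_MAX,
                          RATE_TABLES)
        assert y[16] == rest[16] and y[17] == rest[17]

    def test_gates_stay_in_unit_interval_through_an_ap(self, baseline, rest):
        y = rest.copy()
        for k in range(40000):                     # 400 ms
            y = step_cell(y, baseline, 0.01, 80.0 if k < 100 else 0.0)
            assert np.all(y[1:16] >= 0.0) and np.all(y[1:16] <= 1.0)

    def test_blowup_is_flagged(self, baseline, rest):
        broken = rest.copy()
        broken[0] = 95.0
        broken[1:4] = 1.0
        with pytest.raises(IntegrationFailure):
            for _ in range(200):
                broken = step_cell(broken, baseline, 0.01, i_stim=5000.0)

    def test_adaptive_matches_fine_fixed_step_reference(self, baseline, rest):
        """One AP: adaptive sub-stepping vs forward Euler at dt = 1 us on
        the exact (non-tabulated) right-hand side."""
        n_ms = 400
        y = rest.copy()
        ref = np.empty(n_ms * 4 + 8)
        nr = _integrate_fixed_exact(y, baseline.to_array(),
                                    int(n_ms / 0.001), 0.001,
                                    10.0, 11.0, 80.0, 250, ref)
        y = rest.copy()
        adapt = np.empty(n_ms * 4 + 8)
        na = _integrate_single(y, baseline.to_array(), int(n_ms / 0.01),
                               0.01, 10.0, 11.0, 80.0, 1e9, 25, adapt,
                               DV_MAX, DT_SUB_MIN, DT_SUB_MAX, RATE_TABLES)
        m = min(nr, na)
        assert m >= n_ms * 4 - 4
        assert np.max(np.abs(ref[:m] - adapt[:m])) < 0.1

    def test_apd_converges_when_substep_cap_halves(self, baseline):
        a1 = _paced_apd(baseline, 1000.0, 4, dt_max=0.01)
        a2 = _paced_apd(baseline, 1000.0, 4, dt_max=0.005, dv_max=0.1)
        assert abs(a1 - a2) < 1.0

    def test_single_cell_apd_strictly_decreases_with_remodeling(self, baseline):
        apds = [
            _paced_apd(apply_electrical_remodeling(baseline, f), 1000.0, 4)
            for f in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert np.all(np.diff(apds) < 0.0)
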