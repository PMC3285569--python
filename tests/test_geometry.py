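"""Synthetic domains: constructors, invariants, remodeling transforms."""

import numpy as np
import pytest

from atriasim import (make_cable, make_sheet, make_atrial_surrogate,
                      apply_structural_remodeling, apply_random_fibrosis,
                      SurrogateConfig, REGION_D)
from atriasim.geometry import BULK, FAST, SLOW


class TestCable:
    def test_constructor_contract(self):
        dom = make_cable(400, "bulk")
        assert dom.shape == (400,)
        assert dom.n_active == 400
        assert np.all(dom.labels == BULK)
        assert dom.dx == 0.025                      # 10 cm cable

    def test_slow_cable_gets_slow_calibration(self):
        dom = make_cable(400, "slow")
        assert np.allclose(dom.D, REGION_D[SLOW])

    def test_too_short_cable_rejected(self):
        with pytest.raises(ValueError):
            make_cable(10, "bulk")

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError):
            make_cable(100, "epicardium")


class TestSheet:
    def test_uniform_bulk_sheet(self):
        dom = make_sheet(40, 30, "bulk")
        assert dom.shape == (40, 30)
        assert np.allclose(dom.D[dom.active], REGION_D[BULK])

    def test_interface_weights_are_harmonic_means(self):
        labels = np.full((40, 40), BULK, dtype=np.int8)
        labels[:, 18:22] = SLOW
        dom = make_sheet(40, 40, labels)
        nbr, w = dom.connectivity()
        Db, Ds = REGION_D[BULK], REGION_D[SLOW]
        expected = 2 * Db * Ds / (Db + Ds) / dom.dx ** 2
        g2n = dom.grid_to_node().reshape(dom.shape)
        i = g2n[20, 17]                  # bulk node facing the slow strip
        j = g2n[20, 18]
        col = np.flatnonzero(nbr[i] == j)[0]
        assert w[i, col] == pytest.approx(expected, rel=1e-12)
        # interior bulk face for contrast
        k = g2n[20, 5]
        m = g2n[20, 6]
        col2 = np.flatnonzero(nbr[k] == m)[0]
        assert w[k, col2] == pytest.approx(Db / dom.dx ** 2, rel=1e-12)

    def test_disconnected_active_set_rejected(self):
        act = np.ones((30, 30), dtype=bool)
        act[:, 15] = False                # split into two components
        with pytest.raises(ValueError):
            make_sheet(30, 30, "bulk", active=act)

    def test_unlabeled_active_node_rejected(self):
        labels = np.full((20, 20), -1, dtype=np.int8)
        with pytest.raises(ValueError):
            make_sheet(20, 20, labels)


class TestSurrogate:
    CFG = SurrogateConfig(nx=150, ny=150, large_hole_radius=0.45,
                          small_hole_radius=0.12, n_small_holes=2,
                          fast_strip_width=0.3, isthmus_half_width=0.25,
                          jitter=0.05)

    def test_constructor_contract(self):
        dom = make_atrial_surrogate(seed=1, config=self.CFG)
        assert len(dom.obstacles) >= 2
        labs = set(np.unique(dom.labels[dom.active]))
        assert {BULK, FAST, SLOW} <= labs
        assert all(o["perimeter_cm"] > 0 for o in dom.obstacles)

    def test_deterministic_for_seed(self):
        a = make_atrial_surrogate(seed=5, config=self.CFG)
        b = make_atrial_surrogate(seed=5, config=self.CFG)
        assert np.array_equal(a.active, b.active)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.D, b.D)
        c = make_atrial_surrogate(seed=6, config=self.CFG)
        assert not np.array_equal(a.active, c.active)

    def test_obstacle_minimal_period_arithmetic(self):
        """Perimeter / bulk CV bounds the period of reentry anchored to
        each obstacle; the large holes must admit periods reachable by the
        remodeled tissue (>= ~100 ms)."""
        dom = make_atrial_surrogate(seed=1, config=self.CFG)
        from atriasim import REGION_CV
        periods = [o["perimeter_cm"] / REGION_CV[BULK] for o in dom.obstacles]
        assert max(periods) > 20.0


class TestRemodeling:
    def test_structural_scaling(self):
        dom = make_cable(100, "bulk")
        out = apply_structural_remodeling(dom, 0.5)
        assert np.allclose(out.D, dom.D * 0.5)
        assert out.structural_scale == 0.5
        assert np.array_equal(out.labels, dom.labels)

    @pytest.mark.parametrize("s", [1.0, 0.83, 0.70, 0.5])
    def test_standard_remodeling_levels_accepted(self, s):
        dom = apply_structural_remodeling(make_cable(100, "bulk"), s)
        assert dom.structural_scale == s

    @pytest.mark.parametrize("s", [0.0, -0.2, 1.5])
    def test_invalid_scale_rejected(self, s):
        with pytest.raises(ValueError):
            apply_structural_remodeling(make_cable(100, "bulk"), s)

    def test_scale_commutes_with_construction(self):
        cfg = TestSurrogate.CFG
        a = apply_structural_remodeling(make_atrial_surrogate(3, cfg), 0.7)
        b = make_atrial_surrogate(3, cfg)
        b = apply_structural_remodeling(b, 0.7)
        assert np.allclose(a.D, b.D)


class TestFibrosis:
    def test_identity_at_zero(self):
        dom = make_sheet(40, 40, "bulk")
        out = apply_random_fibrosis(dom, 0.0, seed=1)
        assert np.array_equal(out.active, dom.active)

    def test_reproducible_inactive_count(self):
        dom = make_sheet(60, 60, "bulk")
        a = apply_random_fibrosis(dom, 0.2, seed=11)
        b = apply_random_fibrosis(dom, 0.2, seed=11)
        fib = a.manifest["fibrosis"]
        assert fib["n_random"] == int(np.floor(0.2 * dom.n_active))
        # random kills plus pruned stranded islands
        assert dom.n_active - a.n_active == fib["n_random"] + fib["n_pruned"]
        assert np.array_equal(a.active, b.active)

    def test_fraction_bounds(self):
        dom = make_sheet(40, 40, "bulk")
        with pytest.raises(ValueError):
            apply_random_fibrosis(dom, 0.6, seed=1)

    def test_connectivity_loss_reported(self):
        # a 1D cable disconnects as soon as any interior node is removed
        dom = make_cable(100, "bulk")
        with pytest.raises(ValueError, match="disconnect"):
            apply_random_fibrosis(dom, 0.3, seed=2)
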