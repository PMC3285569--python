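"""Filament detection and counting against analytic rotating-wave
fixtures with known phase singularities, plus episode-level measures."""

import numpy as np
import pytest

from atriasim import (make_sheet, make_annulus, detect_filaments,
                      count_filaments, max_filament_count, episode_duration,
                      mean_period, classify_dominant_waves)
from atriasim.reentry import FilamentFrame, _link_tracks
from atriasim.solver import Recordings, FieldState

# rotation period 40 ms and 2 cm pitch: the -30 mV isoline advances by
# ~0.1 cm between paired snapshots, well above grid resolution
OMEGA = 2 * np.pi / 40.0        # rotation rate, rad/ms
K_SPIRAL = 2 * np.pi / 2.0      # radial pitch, rad/cm


def _coords(dom):
    return np.argwhere(dom.active) * dom.dx


def spiral_phase(dom, centers, charges):
    """Static phase field with prescribed singularities (Archimedean arms)."""
    xy = _coords(dom)
    phi = np.zeros(len(xy))
    for (cx, cy), q in zip(centers, charges):
        dx_, dy_ = xy[:, 0] - cx, xy[:, 1] - cy
        phi += q * (np.arctan2(dy_, dx_) + K_SPIRAL * np.hypot(dx_, dy_))
    return phi


def rotating_voltage(phi, t):
    return -80.0 + 55.0 * (1.0 + np.cos(phi - OMEGA * t))


def topological_charge_count(dom, phi):
    """Independent oracle: plaquette winding numbers of the phase field."""
    g = np.full(dom.shape, np.nan)
    g[dom.active] = phi
    def wrap(a):
        return np.angle(np.exp(1j * a))
    d1 = wrap(g[1:, :-1] - g[:-1, :-1])     # along x at y
    d2 = wrap(g[1:, 1:] - g[1:, :-1])       # along y at x+1
    d3 = wrap(g[:-1, 1:] - g[1:, 1:])
    d4 = wrap(g[:-1, :-1] - g[:-1, 1:])
    q = (d1 + d2 + d3 + d4) / (2 * np.pi)
    q = np.where(np.isfinite(q), np.round(q), 0.0)
    return int(np.sum(np.abs(q) > 0.5)), int(q[np.abs(q) > 0.5].sum()
                                             if np.any(np.abs(q) > 0.5) else 0)


class TestFilamentDetection:
    def setup_method(self):
        self.dom = make_sheet(100, 100, "bulk")     # 2.5 cm square

    def _frame(self, phi):
        v1 = rotating_voltage(phi, 0.0)
        v2 = rotating_voltage(phi, 2.0)
        return detect_filaments(v1, v2, self.dom, t1=100.0, t2=102.0)

    def test_plane_wave_has_no_tips(self):
        xy = _coords(self.dom)
        phi = 2 * np.pi * xy[:, 0] / 1.2            # parallel isolines
        frame = self._frame(phi)
        assert count_filaments(frame) == 0
        n_sing, _ = topological_charge_count(self.dom, phi)
        assert n_sing == 0

    def test_single_spiral_one_cluster_at_core(self):
        phi = spiral_phase(self.dom, [(1.25, 1.25)], [+1])
        frame = self._frame(phi)
        n_sing, _ = topological_charge_count(self.dom, phi)
        assert n_sing == 1
        assert count_filaments(frame) == 1
        core = frame.points.mean(axis=0)
        assert np.hypot(core[0] - 1.25, core[1] - 1.25) < 0.3

    def test_figure_of_eight_two_clusters_net_charge_zero(self):
        centers = [(0.8, 1.25), (1.7, 1.25)]
        phi = spiral_phase(self.dom, centers, [+1, -1])
        frame = self._frame(phi)
        n_sing, net = topological_charge_count(self.dom, phi)
        assert n_sing == 2 and net == 0     # singularities come in pairs
        assert count_filaments(frame) == 2

    def test_wrong_snapshot_spacing_rejected(self):
        v = rotating_voltage(spiral_phase(self.dom, [(1.2, 1.2)], [1]), 0.0)
        with pytest.raises(ValueError, match="2"):
            detect_filaments(v, v, self.dom, t1=0.0, t2=3.0)


class TestCounting:
    def test_empty_frame(self):
        f = FilamentFrame(time=0.0, points=np.empty((0, 2)))
        assert count_filaments(f) == 0

    def test_two_separated_groups(self, rng):
        a = rng.normal([1.0, 1.0], 0.05, (20, 2))
        b = rng.normal([4.0, 4.0], 0.05, (15, 2))
        f = FilamentFrame(time=0.0, points=np.vstack([a, b]))
        assert count_filaments(f) == 2
        assert f.labels is not None and np.unique(f.labels).size == 2

    def test_agrees_with_connected_component_oracle(self, rng):
        """200 random point sets: cluster count must match a graph
        connected-components oracle at the same merge radius in >= 95%."""
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components
        agree = 0
        for _ in range(200):
            n = int(rng.integers(1, 14))
            pts = rng.uniform(0, 5.0, (n, 2))
            f = FilamentFrame(time=0.0, points=pts)
            k = count_filaments(f, merge_radius=0.5)
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            adj = csr_matrix(d <= 0.5)
            k_ref, _ = connected_components(adj, directed=False)
            agree += (k == k_ref)
        assert agree >= 190

    def test_max_over_frames_and_series(self, rng):
        frames = [FilamentFrame(time=10.0 * i, points=rng.uniform(0, 1, (m, 2)))
                  for i, m in enumerate([0, 1, 3, 1, 0])]
        mx, series = max_filament_count(frames)
        assert mx == series.max()
        assert series[0] == 0 and len(series) == 5


def _recordings_from_traces(t, traces, cap_reached=False, t_end=None):
    final = FieldState(states=np.zeros((1, 21)), t=t_end if t_end else t[-1])
    return Recordings(times=t, traces=traces, sites=np.arange(traces.shape[1]),
                      snapshot_times=np.empty(0),
                      snapshots=np.empty((0, 0)), final=final,
                      terminated_at=None if cap_reached else t[-1])


class TestEpisodeMeasures:
    def test_duration_from_last_activation(self):
        t = np.arange(0.0, 1000.0, 1.0)
        v = np.full((t.size, 2), -80.0)
        for start in (50, 200, 350):                # site 0: 3 beats
            v[(t >= start) & (t < start + 100), 0] = 0.0
        dur, sustained = episode_duration(
            _recordings_from_traces(t, v), t_init=20.0, cap=2000.0)
        assert not sustained
        assert dur == pytest.approx(350.0 - 20.0, abs=1.0)

    def test_sustained_at_cap(self):
        t = np.arange(0.0, 1000.0, 1.0)
        v = np.full((t.size, 1), -80.0)
        rec = _recordings_from_traces(t, v, cap_reached=True, t_end=1000.0)
        dur, sustained = episode_duration(rec, t_init=0.0, cap=1000.0)
        assert sustained and dur == 1000.0

    def test_mean_period_strictly_periodic(self):
        t = np.arange(0.0, 2000.0, 1.0)
        v = np.full((t.size, 1), -80.0)
        for k in range(12):
            start = 100 + 150 * k
            v[(t >= start) & (t < start + 60), 0] = 0.0
        per = mean_period(_recordings_from_traces(t, v), t_init=0.0)
        assert per == pytest.approx(150.0, abs=0.5)

    def test_mean_period_undefined_when_sparse(self):
        t = np.arange(0.0, 500.0, 1.0)
        v = np.full((t.size, 1), -80.0)
        v[(t >= 100) & (t < 160), 0] = 0.0
        assert np.isnan(mean_period(_recordings_from_traces(t, v)))


class TestDominantWaves:
    def _free_spiral_frames(self, n_rot, period=100.0, frame_dt=10.0):
        frames = []
        n = int(n_rot * period / frame_dt)
        for i in range(n):
            t = i * frame_dt
            ang = 2 * np.pi * t / period
            pt = np.array([[2.0 + 0.3 * np.cos(ang), 2.0 + 0.3 * np.sin(ang)]])
            frames.append(FilamentFrame(time=t, points=pt))
        return frames

    def test_track_linking_joins_moving_tip(self):
        frames = self._free_spiral_frames(2)
        tracks = _link_tracks(frames)
        assert len(tracks) == 1
        assert len(tracks[0].times) == len(frames)

    def test_free_spiral_six_rotations_is_dominant(self):
        dom = make_sheet(40, 40, "bulk")
        rec = _recordings_from_traces(np.arange(0.0, 10.0, 1.0),
                                      np.full((10, 1), -80.0))
        out = classify_dominant_waves(self._free_spiral_frames(6), rec, dom)
        assert len(out) == 1
        assert out[0].anchor == "un-anchored"
        assert out[0].rotations >= 5
        assert out[0].chirality == "ccw"

    def test_three_rotation_transient_not_dominant(self):
        dom = make_sheet(40, 40, "bulk")
        rec = _recordings_from_traces(np.arange(0.0, 10.0, 1.0),
                                      np.full((10, 1), -80.0))
        assert classify_dominant_waves(self._free_spiral_frames(3), rec, dom) == []

    def _anchored_recordings(self, dom, n_laps, period=110.0):
        cx, cy = dom.obstacles[0]["center_cm"]
        xy = np.argwhere(dom.active) * dom.dx
        th = np.arctan2(xy[:, 1] - cy, xy[:, 0] - cx)
        t = np.arange(0.0, n_laps * period, 10.0)
        snaps = np.empty((t.size, len(th)))
        for i, ti in enumerate(t):
            phase = np.mod(th - 2 * np.pi * ti / period, 2 * np.pi)
            snaps[i] = np.where(phase < 0.6 * np.pi, 0.0, -80.0)
        final = FieldState(states=np.zeros((1, 21)), t=t[-1])
        return Recordings(times=t, traces=snaps[:, :1], sites=np.array([0]),
                          snapshot_times=t, snapshots=snaps, final=final)

    def test_anchored_wave_detected_with_obstacle_id_and_chirality(self):
        dom = make_annulus(r_outer=0.9, width=0.25)
        rec = self._anchored_recordings(dom, n_laps=6)
        out = classify_dominant_waves([], rec, dom)
        assert len(out) == 1
        assert out[0].anchor == "central"
        assert out[0].rotations >= 5
        assert out[0].chirality == "ccw"

    def test_too_few_laps_not_dominant(self):
        dom = make_annulus(r_outer=0.9, width=0.25)
        rec = self._anchored_recordings(dom, n_laps=3)
        assert classify_dominant_waves([], rec, dom) == []
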