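"""Spatiotemporal characterization of reentrant episodes.

Wave tips ("filaments" in the 2D surrogate) are located as the
intersections of the -30 mV isopotential curves of two voltage snapshots
taken 2 ms apart, restricted to points where the membrane is
depolarizing — the standard isopotential-crossing tip detector. The
number of separate filaments per frame is a spatial clustering count
(agglomerative merge at a 0.5 cm radius, refined by k-means with the
resulting k). Episode-level quantities: maximal filament count, duration
of reentrant activity (last activation after initiation; early
termination once the whole field stays below -60 mV for 200 ms), mean
activation period over the recording sites, and dominant waves — waves
persisting for at least five rotations, either free (tip track spinning
about its own centroid) or anchored (activation circulating an obstacle's
perimeter), with chirality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy import ndimage
from skimage import measure as _skmeasure
from shapely.geometry import MultiLineString
from sklearn.cluster import KMeans

from .geometry import TissueDomain
from .measure import detect_crossings
from .solver import Recordings

__all__ = [
    "FilamentFrame", "FilamentTrack", "DominantWave", "EpisodeSummary",
    "detect_filaments", "count_filaments", "max_filament_count",
    "episode_duration", "mean_period", "classify_dominant_waves",
    "summarize_episode", "filament_frames",
]

TIP_THRESHOLD = -30.0   # mV
PAIR_DT = 2.0           # ms
MERGE_RADIUS = 0.5      # cm
MIN_ROTATIONS = 5


@dataclass
class FilamentFrame:
    """Wave-tip points (cm coordinates) of one snapshot pair."""
    time: float
    points: np.ndarray          # (k, 2)
    labels: np.ndarray | None = None
    count: int | None = None


@dataclass
class FilamentTrack:
    times: list = field(default_factory=list)
    centroids: list = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.times[-1] - self.times[0] if len(self.times) > 1 else 0.0

    def rotations(self) -> tuple[float, int]:
        """Net tip-rotation count about the track's mean position and its
        sense (+1 counter-clockwise, -1 clockwise)."""
        if len(self.centroids) < 3:
            return 0.0, 0
        pts = np.asarray(self.centroids)
        rel = pts - pts.mean(axis=0)
        ang = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
        total = ang[-1] - ang[0]
        return abs(total) / (2 * np.pi), int(np.sign(total))


@dataclass
class DominantWave:
    anchor: str                 # obstacle id or "un-anchored"
    chirality: str              # "cw" | "ccw"
    rotations: float
    centroid: tuple[float, float] | None = None


@dataclass
class EpisodeSummary:
    episode_id: str
    f_E: float
    s: float
    location: str
    ci: float
    seed: int
    duration: float
    sustained: bool
    max_filaments: int
    mean_period: float
    dominant_waves: list
    filament_series: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# Filament detection
# ---------------------------------------------------------------------------

def _to_grid(v_nodes: np.ndarray, domain: TissueDomain,
             fill: float = -100.0) -> np.ndarray:
    g = np.full(domain.shape, fill)
    g[domain.active] = v_nodes
    return g


def detect_filaments(v1: np.ndarray, v2: np.ndarray, domain: TissueDomain,
                     threshold: float = TIP_THRESHOLD,
                     t1: float | None = None, t2: float | None = None,
                     time: float = np.nan) -> FilamentFrame:
    """Tips as intersections of the two snapshots' threshold isolines.

    ``v1``/``v2`` are active-node voltage vectors of snapshots separated by
    exactly 2 ms (checked when ``t1``/``t2`` are given). Only intersection
    points on the upstroke (V rising between the snapshots) are kept;
    coordinates are in cm (node-centred).
    """
    if t1 is not None and t2 is not None:
        if abs((t2 - t1) - PAIR_DT) > 1e-6:
            raise ValueError(f"snapshot spacing must be {PAIR_DT} ms, got {t2 - t1}")
        time = t2
    if domain.ndim != 2:
        raise ValueError("filament detection operates on 2D domains")
    g1 = _to_grid(np.asarray(v1, float), domain)
    g2 = _to_grid(np.asarray(v2, float), domain)
    dvg = g2 - g1
    c1 = _skmeasure.find_contours(g1, threshold)
    c2 = _skmeasure.find_contours(g2, threshold)

    def upstroke_branches(contours):
        """Contour pieces on the depolarizing branch. The wave tip itself
        is a stagnation point (dV/dt ~ 0), so a small tolerance keeps the
        vertices flanking it while the waveback (clearly repolarizing) is
        discarded."""
        segs = []
        for c in contours:
            if len(c) < 2:
                continue
            dv = ndimage.map_coordinates(dvg, c.T, order=1, mode="nearest")
            keep = dv > -1.0
            start = None
            for i, k in enumerate(np.append(keep, False)):
                if k and start is None:
                    start = i
                elif not k and start is not None:
                    if i - start >= 2:
                        segs.append(c[start:i])
                    start = None
        return segs

    s1 = upstroke_branches(c1)
    s2 = upstroke_branches(c2)
    if not s1 or not s2:
        return FilamentFrame(time=time, points=np.empty((0, 2)), count=0,
                             labels=np.empty(0, dtype=int))
    ml1 = MultiLineString([s[:, ::-1] for s in s1])
    ml2 = MultiLineString([s[:, ::-1] for s in s2])
    inter = ml1.intersection(ml2)
    pts = []
    if not inter.is_empty:
        geoms = getattr(inter, "geoms", [inter])
        for gobj in geoms:
            if gobj.geom_type == "Point":
                pts.append([gobj.y, gobj.x])   # back to (row, col)
            elif gobj.geom_type in ("MultiPoint", "LineString"):
                pts.extend([[q[1], q[0]]
                            for q in np.atleast_2d(np.asarray(gobj.coords))])
    if not pts:
        return FilamentFrame(time=time, points=np.empty((0, 2)), count=0,
                             labels=np.empty(0, dtype=int))
    pts = np.asarray(pts, dtype=float)
    return FilamentFrame(time=time, points=pts * domain.dx)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_filaments(frame: FilamentFrame,
                    merge_radius: float = MERGE_RADIUS) -> int:
    """Number of separate filaments in a frame.

    Tip points are merged agglomeratively (single linkage) at
    ``merge_radius``; the resulting group count k seeds a k-means
    refinement whose assignments are stored on the frame.
    """
    pts = frame.points
    if pts.shape[0] == 0:
        frame.count = 0
        frame.labels = np.empty(0, dtype=int)
        return 0
    if pts.shape[0] == 1:
        frame.count = 1
        frame.labels = np.zeros(1, dtype=int)
        return 1
    Z = linkage(pts, method="single")
    groups = fcluster(Z, t=merge_radius, criterion="distance")
    k = int(groups.max())
    if k == 1 or k == pts.shape[0]:
        frame.labels = groups - 1
    else:
        seeds = np.stack([pts[groups == g + 1].mean(axis=0) for g in range(k)])
        km = KMeans(n_clusters=k, init=seeds, n_init=1, max_iter=20).fit(pts)
        frame.labels = km.labels_
    frame.count = k
    return k


def max_filament_count(frames: list[FilamentFrame],
                       merge_radius: float = MERGE_RADIUS
                       ) -> tuple[int, np.ndarray]:
    """Max cluster count over an episode's frames, plus the full series."""
    series = np.array([count_filaments(f, merge_radius) for f in frames],
                      dtype=int)
    return (int(series.max()) if series.size else 0), series


def filament_frames(rec: Recordings, domain: TissueDomain,
                    threshold: float = TIP_THRESHOLD) -> list[FilamentFrame]:
    """Pair up an episode's snapshots (2 ms apart) into filament frames."""
    t = rec.snapshot_times
    frames = []
    i = 0
    while i + 1 < len(t):
        if abs((t[i + 1] - t[i]) - PAIR_DT) < 1e-6:
            frames.append(detect_filaments(rec.snapshots[i], rec.snapshots[i + 1],
                                           domain, threshold,
                                           t1=t[i], t2=t[i + 1]))
            i += 2
        else:
            i += 1
    return frames


# ---------------------------------------------------------------------------
# Episode-level measures
# ---------------------------------------------------------------------------

def episode_duration(rec: Recordings, t_init: float, cap: float
                     ) -> tuple[float, bool]:
    """Duration of reentrant activity after initiation and the sustained flag.

    Duration runs from ``t_init`` to the last -70 mV upstroke at any
    recording site; an episode still active when the run hits the cap is
    sustained (duration = cap).
    """
    if rec.terminated_at is None and rec.final is not None and \
            rec.final.t >= t_init + cap - 1e-6:
        return cap, True
    last = t_init
    for m in range(rec.traces.shape[1]):
        ups = detect_crossings(rec.times, rec.traces[:, m]).ups
        ups = ups[ups > t_init]
        if ups.size:
            last = max(last, ups[-1])
    return last - t_init, False


def mean_period(rec: Recordings, t_init: float = 0.0,
                skip: int = 2) -> float:
    """Mean inter-activation interval over the recording sites.

    The first ``skip`` activations after initiation are excluded at each
    site. Returns NaN when fewer than 3 intervals are observed in total.
    """
    ivals = []
    for m in range(rec.traces.shape[1]):
        ups = detect_crossings(rec.times, rec.traces[:, m]).ups
        ups = ups[ups > t_init][skip:]
        if ups.size >= 2:
            ivals.append(np.diff(ups))
    if not ivals:
        return np.nan
    allv = np.concatenate(ivals)
    if allv.size < 3:
        return np.nan
    return float(allv.mean())


# ---------------------------------------------------------------------------
# Dominant waves
# ---------------------------------------------------------------------------

def _link_tracks(frames: list[FilamentFrame], gate: float = 1.0
                 ) -> list[FilamentTrack]:
    """Greedy nearest-neighbour linking of per-frame cluster centroids."""
    tracks: list[FilamentTrack] = []
    open_tracks: list[FilamentTrack] = []
    for f in frames:
        if f.count is None:
            count_filaments(f)
        cents = []
        if f.count:
            for g in range(f.count):
                cents.append(f.points[f.labels == g].mean(axis=0))
        used = set()
        new_open = []
        for tr in open_tracks:
            last = np.asarray(tr.centroids[-1])
            best, bd = -1, gate
            for ci, c in enumerate(cents):
                if ci in used:
                    continue
                d = float(np.linalg.norm(c - last))
                if d < bd:
                    best, bd = ci, d
            if best >= 0:
                used.add(best)
                tr.times.append(f.time)
                tr.centroids.append(cents[best])
                new_open.append(tr)
            else:
                tracks.append(tr)
        for ci, c in enumerate(cents):
            if ci not in used:
                tr = FilamentTrack(times=[f.time], centroids=[c])
                new_open.append(tr)
        open_tracks = new_open
    tracks.extend(open_tracks)
    return tracks


def _obstacle_perimeter_probes(domain: TissueDomain, obstacle: dict,
                               n_probes: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Active-node indices just outside an obstacle rim and their angles."""
    cx, cy = obstacle["center_cm"]
    r = obstacle["radius_cm"] + 2.5 * domain.dx
    angles = np.linspace(0, 2 * np.pi, n_probes, endpoint=False)
    coords = np.argwhere(domain.active) * domain.dx
    nodes = []
    for a in angles:
        p = np.array([cx + r * np.cos(a), cy + r * np.sin(a)])
        nodes.append(int(np.argmin(((coords - p) ** 2).sum(axis=1))))
    return np.array(nodes), angles


def _obstacle_circulation(snap_t: np.ndarray, snap_v: np.ndarray,
                          domain: TissueDomain, obstacle: dict,
                          n_probes: int = 8) -> tuple[float, int]:
    """Laps of activation around an obstacle from episode snapshots.

    Activation events at rim probes are -70 mV upward crossings between
    consecutive snapshots. A circulating wave shows a monotone phase delay
    around the rim summing to about one period; a passing plane wave sums
    to about zero. Returns (lap count, chirality sign)."""
    nodes, angles = _obstacle_perimeter_probes(domain, obstacle, n_probes)
    acts = []
    for nd in nodes:
        v = snap_v[:, nd]
        ups = np.flatnonzero((v[:-1] < -70.0) & (v[1:] >= -70.0))
        acts.append(snap_t[ups + 1])
    counts = [len(a) for a in acts]
    if min(counts) < 2:
        return float(min(counts)), 0
    period = float(np.median(np.concatenate([np.diff(a) for a in acts if len(a) > 1])))
    if not np.isfinite(period) or period <= 0:
        return float(min(counts)), 0
    drift = 0.0
    for k in range(n_probes):
        a0, a1 = acts[k], acts[(k + 1) % n_probes]
        lags = []
        for ta in a0:
            j = np.argmin(np.abs(a1 - ta))
            lag = (a1[j] - ta + period / 2) % period - period / 2
            lags.append(lag)
        drift += float(np.median(lags))
    if abs(drift) < 0.6 * period:
        return 0.0, 0
    return float(min(counts)), (1 if drift > 0 else -1)


def classify_dominant_waves(frames: list[FilamentFrame], rec: Recordings,
                            domain: TissueDomain,
                            min_rotations: float = MIN_ROTATIONS,
                            gate: float = 1.0) -> list[DominantWave]:
    """Dominant waves: free tip tracks or obstacle-anchored circulation
    persisting for at least ``min_rotations`` rotations."""
    out = []
    for tr in _link_tracks(frames, gate=gate):
        rot, sense = tr.rotations()
        if rot >= min_rotations:
            cen = tuple(np.asarray(tr.centroids).mean(axis=0))
            out.append(DominantWave(anchor="un-anchored",
                                    chirality="ccw" if sense > 0 else "cw",
                                    rotations=rot, centroid=cen))
    if rec.snapshots.size:
        for obs in domain.obstacles:
            laps, sense = _obstacle_circulation(rec.snapshot_times,
                                                rec.snapshots, domain, obs)
            if laps >= min_rotations and sense != 0:
                out.append(DominantWave(anchor=obs["id"],
                                        chirality="ccw" if sense > 0 else "cw",
                                        rotations=laps,
                                        centroid=obs["center_cm"]))
    return out


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

def summarize_episode(rec: Recordings, domain: TissueDomain, t_init: float,
                      cap: float, episode_id: str = "", f_E: float = 0.0,
                      s: float = 1.0, location: str = "", ci: float = np.nan,
                      seed: int = 0) -> EpisodeSummary:
    frames = filament_frames(rec, domain) if domain.ndim == 2 else []
    maxfil, series = max_filament_count(frames)
    dur, sustained = episode_duration(rec, t_init, cap)
    per = mean_period(rec, t_init)
    dom_waves = (classify_dominant_waves(frames, rec, domain)
                 if frames else [])
    return EpisodeSummary(episode_id=episode_id, f_E=f_E, s=s,
                          location=location, ci=ci, seed=seed, duration=dur,
                          sustained=sustained, max_filaments=maxfil,
                          mean_period=per, dominant_waves=dom_waves,
                          filament_series=series)
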