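"""Stimulation protocols.

Periodic pacing (with steady-state detection), S1-S2 effective refractory
period measurement, and reentry initiation by a cross-gradient protocol: a
plane S1 wave, a premature S2 delivered to a transverse block at a chosen
coupling interval after the S1 wavefront passes that region, and an
optional brief hyperpolarizing clamp (-80 mV, 1 ms) applied to the S2
region 30 ms after S2 to shorten local refractoriness and widen the
vulnerable window. Coupling-interval scans step through candidate S2
timings in 10 ms increments and hand each induced episode to the reentry
analyses.

The standard stimulus is 80 A/F for 1 ms (the model's
current-per-capacitance convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell import CellParams, apply_electrical_remodeling
from .geometry import TissueDomain, apply_structural_remodeling
from .measure import detect_crossings, compute_apd_di, measure_cv
from .solver import (SolverConfig, StimulusEvent, ClampEvent, FieldState,
                     Recordings, run, initial_field)

__all__ = [
    "StimulusSpec", "ClampSpec", "PacingResult", "ErpResult",
    "InitiationResult", "InitiationScan",
    "periodic_pacing", "measure_erp", "cross_gradient_initiation",
    "time_s1_arrival", "ring_pulse_field", "run_episode", "scan_initiations",
    "STIM_AMPLITUDE", "STIM_DURATION",
]

STIM_AMPLITUDE = 80.0   # A/F
STIM_DURATION = 1.0     # ms
CLAMP_VOLTAGE = -80.0   # mV
CLAMP_DELAY = 30.0      # ms after S2 onset
CLAMP_DURATION = 1.0    # ms

# the protocol-facing names for the solver event types
StimulusSpec = StimulusEvent
ClampSpec = ClampEvent


def _default_stim_nodes(domain: TissueDomain) -> np.ndarray:
    """Stimulated node block: first 0.1 cm of a cable, or the left-edge
    column strip of a sheet."""
    k = max(1, int(round(0.1 / domain.dx)))
    if domain.ndim == 1:
        return np.arange(min(k, domain.n_active))
    grid2node = domain.grid_to_node().reshape(domain.shape)
    cols = grid2node[:k, :].ravel()
    return cols[cols >= 0]


def _default_site(domain: TissueDomain) -> int:
    return domain.n_active // 2


def _cable_probes(domain: TissueDomain, n: int = 11) -> np.ndarray:
    """Probe nodes spanning the middle 40-60% of a cable."""
    m = domain.n_active
    return np.unique(np.linspace(int(0.40 * m), int(0.60 * m), n).astype(int))


@dataclass
class PacingResult:
    apds: np.ndarray            # per-beat APD at the measurement site (ms)
    dis: np.ndarray             # per-beat DI at the measurement site (ms)
    steady_apd: float
    steady_di: float
    cv: float                   # cm/ms, from the last paced beat (nan if no probe)
    captured_1to1: bool
    steady: bool
    alternans: bool             # steady 2:2 (long-short) response
    n_beats: int
    recordings: Recordings
    final: FieldState
    site: int
    stim_nodes: np.ndarray
    last_s1_onset: float        # ms, absolute time of the final delivered S1


def periodic_pacing(domain: TissueDomain, params: CellParams,
                    cycle_length: float, n_beats: int | None = None,
                    until_steady: bool = False, site: int | None = None,
                    stim_nodes: np.ndarray | None = None,
                    probes: np.ndarray | None = None,
                    min_beats: int = 6, max_beats: int = 20,
                    apd_tol: float = 1.0, record_dt: float = 0.25,
                    initial: FieldState | None = None,
                    t_first: float = 10.0) -> PacingResult:
    """Pace ``stim_nodes`` at a fixed cycle length and measure APD/DI/CV.

    With ``until_steady`` the train is extended in blocks until the beat
    sequence at the measurement site is stationary: either two consecutive
    beats differ by < ``apd_tol`` ms (1:1 steady state) or the last two
    odd/even pairs each repeat within ``apd_tol`` (a steady 2:2 alternans,
    flagged through ``alternans``); at least ``min_beats``, at most
    ``max_beats`` beats. Loss of 1:1 capture is reported through
    ``captured_1to1``; the result then carries whatever beats were
    measured.
    """
    if cycle_length <= 0:
        raise ValueError("cycle length must be positive")
    if site is None:
        site = _default_site(domain)
    if stim_nodes is None:
        stim_nodes = _default_stim_nodes(domain)
    if probes is None and domain.ndim == 1:
        probes = _cable_probes(domain)
    sites = np.array([site])
    if probes is not None:
        sites = np.unique(np.concatenate([sites, probes]))
    cfg = SolverConfig(record_sites=sites, record_dt=record_dt)

    if n_beats is not None:
        until_steady = False
        max_beats = min_beats = n_beats

    state = initial if initial is not None else initial_field(domain, params)
    t0 = state.t
    all_t, all_v = [], []
    beats_done = 0
    block = max_beats if not until_steady else 4
    steady = False
    rec = None
    if max_beats == 0:
        rec = run(domain, params, [], duration=cycle_length, config=cfg,
                  initial=state)
        state = rec.final
        all_t.append(rec.times)
        all_v.append(rec.traces)
    while beats_done < max_beats:
        nb = min(block, max_beats - beats_done)
        onsets = [t0 + t_first + (beats_done + k) * cycle_length for k in range(nb)]
        events = [StimulusEvent(nodes=stim_nodes, t_on=on,
                                duration=STIM_DURATION, amplitude=STIM_AMPLITUDE)
                  for on in onsets]
        rec = run(domain, params, events, duration=nb * cycle_length,
                  config=cfg, initial=state)
        state = rec.final
        all_t.append(rec.times)
        all_v.append(rec.traces)
        beats_done += nb
        if until_steady and beats_done >= min_beats:
            apds, _ = _site_apds(all_t, all_v, sites, site)
            if _is_stationary(apds, apd_tol):
                steady = True
                break
    t = np.concatenate(all_t)
    v = np.vstack(all_v)
    apds, dis = _site_apds([t], [v], sites, site)
    if not until_steady:
        steady = _is_stationary(apds, apd_tol)
    alternans = bool(
        apds.size >= 4 and abs(apds[-1] - apds[-2]) >= apd_tol
        and abs(apds[-1] - apds[-3]) < apd_tol
        and abs(apds[-2] - apds[-4]) < apd_tol)
    # 1:1 capture judged over the final beats (a transient block while the
    # APD accommodates to a fast rate does not disqualify the steady state)
    col = int(np.flatnonzero(sites == site)[0])
    ups = detect_crossings(t, v[:, col]).ups
    k = min(4, beats_done)
    window_lo = t[-1] - k * cycle_length
    captured = bool(np.count_nonzero(ups > window_lo) == k and apds.size >= 1)
    if n_beats == 0:
        captured = True

    cv = np.nan
    if probes is not None and apds.size:
        cv = _last_beat_cv(t, v, sites, probes, domain.dx)

    last_onset = t0 + t_first + (beats_done - 1) * cycle_length
    return PacingResult(
        apds=apds, dis=dis,
        steady_apd=float(apds[-1]) if apds.size else np.nan,
        steady_di=float(dis[-1]) if dis.size else np.nan,
        cv=cv, captured_1to1=bool(captured), steady=bool(steady),
        alternans=alternans, n_beats=beats_done,
        recordings=Recordings(times=t, traces=v, sites=sites,
                              snapshot_times=np.empty(0),
                              snapshots=np.empty((0, 0)), final=state),
        final=state, site=site, stim_nodes=stim_nodes,
        last_s1_onset=last_onset)


def _is_stationary(apds: np.ndarray, tol: float) -> bool:
    """Stationary beat sequence: steady 1:1, or a repeating 2:2 pattern."""
    if apds.size >= 2 and abs(apds[-1] - apds[-2]) < tol:
        return True
    return bool(apds.size >= 4 and abs(apds[-1] - apds[-3]) < tol
                and abs(apds[-2] - apds[-4]) < tol)


def _site_apds(ts, vs, sites, site):
    t = np.concatenate(ts)
    v = np.vstack(vs)
    col = int(np.flatnonzero(sites == site)[0])
    series = detect_crossings(t, v[:, col])
    return compute_apd_di(series)


def _last_beat_cv(t, v, sites, probes, dx):
    acts = []
    for p in probes:
        col = int(np.flatnonzero(sites == p)[0])
        ups = detect_crossings(t, v[:, col]).ups
        if ups.size == 0:
            return np.nan
        acts.append(ups[-1])
    try:
        return measure_cv(np.array(acts), np.asarray(probes, float) * dx)
    except ValueError:
        return np.nan


# ---------------------------------------------------------------------------
# ERP
# ---------------------------------------------------------------------------

@dataclass
class ErpResult:
    erp: float                  # ms (S1->S2 onset interval)
    apd: float                  # ms, steady APD at the reference site
    cycle_length: float
    tested: list = field(default_factory=list)   # (interval, propagated)
    site: int = -1


def _s2_propagates(domain, params, state, s1_onset, interval,
                   stim_nodes, probe_node) -> bool:
    """Deliver S1 (already part of ``state`` history? No: S1 delivered here)
    followed by S2 at ``interval``; report whether S2 elicits a propagated
    upstroke at the probe."""
    events = [
        StimulusEvent(nodes=stim_nodes, t_on=s1_onset,
                      duration=STIM_DURATION, amplitude=STIM_AMPLITUDE),
        StimulusEvent(nodes=stim_nodes, t_on=s1_onset + interval,
                      duration=STIM_DURATION, amplitude=STIM_AMPLITUDE),
    ]
    cfg = SolverConfig(record_sites=np.array([probe_node]), record_dt=0.25)
    horizon = interval + 250.0
    rec = run(domain, params, events, duration=(s1_onset - state.t) + horizon,
              config=cfg, initial=state)
    ups = detect_crossings(rec.times, rec.traces[:, 0]).ups
    t_s2 = s1_onset + interval
    return bool(np.any((ups > t_s2 + 1.0) & (ups <= t_s2 + 200.0)))


def measure_erp(domain: TissueDomain, params: CellParams, cycle_length: float,
                site: int | None = None, stim_nodes: np.ndarray | None = None,
                resolution: float = 1.0, method: str = "bisect",
                lo: float = 40.0, pacing: PacingResult | None = None,
                **pacing_kwargs) -> ErpResult:
    """Effective refractory period by S1-S2 at ``resolution`` ms.

    The strand is paced to a stationary state at the S1 cycle length; a
    single further S1 is then delivered followed by S2 at a candidate
    interval (both onset-referenced). ERP is the shortest interval whose
    S2 elicits a propagated response at a probe 0.5 cm beyond the stimulus
    edge. ``method`` is "bisect" (default) or "scan" (exhaustive, for
    cross-checking). The reported APD is that of the final S1 beat itself,
    measured at the node adjacent to the stimulus edge in a dedicated
    S1-only run, so ERP and APD describe the same action potential even
    when pacing settles into a 2:2 alternans.
    """
    if stim_nodes is None:
        stim_nodes = _default_stim_nodes(domain)
    edge = int(np.max(stim_nodes))
    apd_site = edge + 1 if site is None else site
    probe = edge + int(round(0.5 / domain.dx))
    if pacing is None:
        pacing = periodic_pacing(domain, params, cycle_length,
                                 until_steady=True, site=apd_site,
                                 stim_nodes=stim_nodes, probes=None,
                                 **pacing_kwargs)
    if not pacing.captured_1to1:
        raise ValueError("no stable 1:1 capture at the S1 cycle length")
    state = pacing.final
    s1_onset = pacing.last_s1_onset + cycle_length

    # APD of the final S1 beat, from an S1-only probe run
    s1 = StimulusEvent(nodes=stim_nodes, t_on=s1_onset,
                       duration=STIM_DURATION, amplitude=STIM_AMPLITUDE)
    cfg1 = SolverConfig(record_sites=np.array([apd_site]), record_dt=0.25)
    rec1 = run(domain, params, [s1],
               duration=(s1_onset - state.t) + 400.0, config=cfg1,
               initial=state, keep_final=False)
    apds1, _ = compute_apd_di(detect_crossings(rec1.times, rec1.traces[:, 0]))
    if apds1.size == 0:
        raise ValueError("final S1 beat did not produce a complete AP")
    apd = float(apds1[-1])

    tested = []

    def ok(interval):
        r = _s2_propagates(domain, params, state, s1_onset, interval,
                           stim_nodes, probe)
        tested.append((interval, r))
        return r

    hi = float(cycle_length)
    if not ok(hi):
        raise ValueError("S2 fails to capture even at the full cycle length")
    if method == "scan":
        iv = lo
        while iv < hi:
            if ok(iv):
                hi = iv
                break
            iv += resolution
        erp = hi
    else:
        if ok(lo):
            erp = lo
        else:
            a, b = lo, hi          # a fails, b propagates
            while b - a > resolution:
                mid = round((a + b) / 2.0 / resolution) * resolution
                if mid <= a or mid >= b:
                    mid = (a + b) / 2.0
                if ok(mid):
                    b = mid
                else:
                    a = mid
            erp = b
    return ErpResult(erp=float(erp), apd=float(apd), cycle_length=cycle_length,
                     tested=tested, site=apd_site)


# ---------------------------------------------------------------------------
# Cross-gradient reentry initiation
# ---------------------------------------------------------------------------

def default_s2_region(domain: TissueDomain, corner: str = "sw") -> np.ndarray:
    """Quarter-domain block used as the S2 (second excitation) region."""
    if domain.ndim != 2:
        raise ValueError("S2 block regions are defined for 2D domains")
    nx, ny = domain.shape
    g2n = domain.grid_to_node().reshape(domain.shape)
    sx = slice(0, nx // 2) if "s" in corner else slice(nx // 2, nx)
    sy = slice(0, ny // 2) if "w" in corner else slice(ny // 2, ny)
    blk = g2n[sx, sy].ravel()
    return blk[blk >= 0]


@dataclass
class InitiationResult:
    field: FieldState | None
    induced: bool
    coupling_interval: float
    t_s2: float                  # ms, absolute S2 onset
    s1_activation: float         # ms, S1 activation at the S2 centroid
    recordings: Recordings | None = None


def time_s1_arrival(domain: TissueDomain, params: CellParams,
                    s1_nodes: np.ndarray, s2_nodes: np.ndarray) -> float:
    """S1 activation time (-70 mV upstroke) at the S2 region's centroid.

    Shared by every coupling interval of a scan at one location/level.
    Returns NaN if the S1 wave never reaches the centroid.
    """
    coords = np.argwhere(domain.active)
    centroid = coords[s2_nodes].mean(axis=0)
    d2 = ((coords[s2_nodes] - centroid) ** 2).sum(axis=1)
    centroid_node = int(s2_nodes[np.argmin(d2)])
    cfg = SolverConfig(record_sites=np.array([centroid_node]), record_dt=0.5)
    span = max(domain.shape) * domain.dx
    t_cross = span / 0.02 + 50.0   # generous bound: slowest plausible CV
    s1 = StimulusEvent(nodes=s1_nodes, t_on=10.0, duration=STIM_DURATION,
                       amplitude=STIM_AMPLITUDE)
    rec1 = run(domain, params, [s1], duration=t_cross, config=cfg,
               keep_final=False)
    ups = detect_crossings(rec1.times, rec1.traces[:, 0]).ups
    return float(ups[0]) if ups.size else np.nan


def cross_gradient_initiation(domain: TissueDomain, params: CellParams,
                              s1_nodes: np.ndarray | None,
                              s2_nodes: np.ndarray,
                              coupling_interval: float,
                              use_clamp: bool = True,
                              settle: float = 20.0,
                              s1_activation: float | None = None
                              ) -> InitiationResult:
    """S1 plane wave, premature S2 over a transverse block, optional clamp.

    The coupling interval is referenced to the S1 activation time at the
    S2 region's centroid (first -70 mV upstroke there). Returns the field
    shortly after the S2/clamp sequence, ready for episode running; if S2
    fails to excite anything, ``induced`` is False (a labelled no-reentry
    outcome, not an error).
    """
    if s1_nodes is None:
        s1_nodes = _default_stim_nodes(domain)
    s2_nodes = np.asarray(s2_nodes)
    coords = np.argwhere(domain.active)
    centroid = coords[s2_nodes].mean(axis=0)
    d2 = ((coords[s2_nodes] - centroid) ** 2).sum(axis=1)
    centroid_node = int(s2_nodes[np.argmin(d2)])

    # pass 1 (skipped when the caller supplies a cached value): S1 alone,
    # to time its arrival at the S2 centroid
    t_act = (s1_activation if s1_activation is not None
             else time_s1_arrival(domain, params, s1_nodes, s2_nodes))
    if not np.isfinite(t_act):
        return InitiationResult(field=None, induced=False,
                                coupling_interval=coupling_interval,
                                t_s2=np.nan, s1_activation=np.nan)
    s1 = StimulusEvent(nodes=s1_nodes, t_on=10.0, duration=STIM_DURATION,
                       amplitude=STIM_AMPLITUDE)
    # probe sites spread over the S2 block: S2 capture shows as a fresh
    # upstroke at one of them after the S2 onset
    probe_idx = s2_nodes[np.linspace(0, len(s2_nodes) - 1, 7).astype(int)]
    probe_idx = np.unique(np.append(probe_idx, centroid_node))
    cfg = SolverConfig(record_sites=probe_idx, record_dt=0.5)

    # pass 2: S1 + S2 (+ clamp), stopping shortly after the sequence
    t_s2 = t_act + coupling_interval
    events = [s1, StimulusEvent(nodes=s2_nodes, t_on=t_s2,
                                duration=STIM_DURATION,
                                amplitude=STIM_AMPLITUDE)]
    if use_clamp:
        events.append(ClampEvent(nodes=s2_nodes, t_on=t_s2 + CLAMP_DELAY,
                                 duration=CLAMP_DURATION,
                                 voltage=CLAMP_VOLTAGE))
    t_end = t_s2 + CLAMP_DELAY + CLAMP_DURATION + settle
    rec2 = run(domain, params, events, duration=t_end, config=cfg)
    # S2 capture: a fresh upstroke at an S2-region probe shortly after the
    # S2 onset and before the clamp (whose release can re-cross threshold)
    induced = False
    for m in range(rec2.traces.shape[1]):
        ups = detect_crossings(rec2.times, rec2.traces[:, m]).ups
        if np.any((ups > t_s2) & (ups < t_s2 + CLAMP_DELAY - 2.0)):
            induced = True
            break
    return InitiationResult(field=rec2.final, induced=induced,
                            coupling_interval=coupling_interval,
                            t_s2=t_s2, s1_activation=t_act,
                            recordings=rec2)


@dataclass
class RingInitResult:
    """Wrapped-pulse ring initial condition plus the rate-matched strand
    measurements taken while preconditioning (APD and CV at the ring's
    period, and their product, the local wavelength in cm)."""
    field: FieldState
    cycle_length: float
    apd: float
    cv: float

    @property
    def wavelength(self) -> float:
        return self.apd * self.cv


def ring_pulse_field(domain: TissueDomain, params: CellParams,
                     front_fraction: float = 0.75,
                     direction: int = +1, n_pre: int = 5,
                     cycle_length: float | None = None) -> RingInitResult:
    """Unidirectional traveling-pulse initial condition on an annulus.

    A plane pulse is simulated on a strand matching the annulus' diffusion
    and its state profile is wrapped onto the ring by arc length: the
    wavefront sits at azimuthal fraction ``front_fraction`` of the
    mid-channel path, the repolarizing tail fills the arc behind it, and
    the remaining sector ahead of the front starts at rest.

    The strand is preconditioned with ``n_pre`` beats at the ring's
    natural period (mid-path length / conduction velocity, overridable via
    ``cycle_length``) before the final wave is wrapped, so the tail
    carries rate-adapted action potentials rather than a first beat from
    rest. Whether the resulting anchored reentry persists is then pure
    wavelength-versus-path-length physics. ``direction`` +1 propagates
    counter-clockwise.
    """
    if not domain.obstacles:
        raise ValueError("ring initiation needs a domain with an obstacle")
    obs = domain.obstacles[0]
    cx, cy = obs["center_cm"]
    r_mid = obs.get("mid_path_cm", 2 * np.pi * obs["radius_cm"]) / (2 * np.pi)
    perimeter = 2 * np.pi * r_mid

    from .geometry import make_cable, REGION_D, BULK
    n_cab = int(round((perimeter + 2.0) / domain.dx))
    cab = make_cable(n_cab, "bulk", dx=domain.dx)
    D_here = float(np.median(domain.D[domain.active]))
    cab.D[:] = D_here
    cv_est = 0.065 * np.sqrt(D_here / REGION_D[BULK])
    if cycle_length is None:
        cycle_length = perimeter / cv_est

    # pass 1: time the final front's arrival at the wrap point, and
    # measure the rate-matched APD and CV on the way
    x_front = front_fraction * perimeter
    node_f = int(round(x_front / domain.dx))
    probes = np.arange(max(node_f - 48, 4), node_f + 1, 8)
    cv_min = 0.02  # cm/ms, conservative lower bound
    sites = np.unique(np.append(probes, node_f))
    cfg = SolverConfig(record_sites=sites, record_dt=0.5)
    events = [StimulusEvent(nodes=np.arange(4), t_on=5.0 + k * cycle_length)
              for k in range(n_pre)]
    t_last = events[-1].t_on
    rec = run(cab, params, events,
              duration=t_last + x_front / cv_min + 30.0, config=cfg,
              keep_final=False)
    col_f = int(np.flatnonzero(sites == node_f)[0])
    series = detect_crossings(rec.times, rec.traces[:, col_f])
    ups = series.ups
    if ups.size == 0:
        raise ValueError("preconditioned strand pulse failed to propagate")
    apds, _ = compute_apd_di(series)
    apd = float(apds[-1]) if apds.size else np.nan
    acts = []
    for pn in probes:
        cp = int(np.flatnonzero(sites == pn)[0])
        u = detect_crossings(rec.times, rec.traces[:, cp]).ups
        acts.append(u[-1] if u.size else np.nan)
    try:
        cv = measure_cv(np.array(acts), probes * domain.dx)
    except ValueError:
        cv = np.nan
    # wrap the last wave that crossed the wrap point (under partial
    # capture, e.g. 2:1 at an unsustainable period, that is the last
    # captured beat's front)
    t_f = float(ups[-1]) + 1.0
    # pass 2: stop exactly when that front reaches the wrap point
    rec2 = run(cab, params, events, duration=t_f, config=cfg)
    profile = rec2.final.states                    # (n_cab, NSTATE)

    rest = _cell_rest(params)
    coords = np.argwhere(domain.active) * domain.dx
    theta = np.arctan2(coords[:, 1] - cy, coords[:, 0] - cx)
    # arc position behind the front, in the direction of propagation
    delta = np.mod(direction * (-theta), 2 * np.pi) * r_mid
    x = x_front - delta
    states = np.empty((domain.n_active, profile.shape[1]))
    inside = x >= 0.0
    idx = np.clip(np.round(x[inside] / domain.dx).astype(int), 0, n_cab - 1)
    states[inside] = profile[idx]
    states[~inside] = rest
    return RingInitResult(field=FieldState(states=states, t=0.0),
                          cycle_length=float(cycle_length), apd=apd, cv=cv)


def _cell_rest(params: CellParams) -> np.ndarray:
    from .cell import rest_state
    return rest_state(params)


def run_episode(domain: TissueDomain, params: CellParams, field: FieldState,
                cap: float = 10_000.0, sites: np.ndarray | None = None,
                frame_dt: float = 10.0, pair_dt: float = 2.0,
                record_dt: float = 1.0) -> Recordings:
    """Run a post-initiation field to termination or the episode cap.

    Full-field snapshot pairs (``pair_dt`` apart, for filament detection)
    are taken every ``frame_dt``; the run stops early once all voltage
    stays below -60 mV for 200 ms.
    """
    from .measure import select_recording_sites
    if sites is None:
        sites = select_recording_sites(domain, 16, seed=0)
    dt = 0.01
    step0 = int(round(field.t / dt))
    nsteps = int(round(cap / dt))
    per = int(round(frame_dt / dt))
    off = int(round(pair_dt / dt))
    base = np.arange(step0 + per, step0 + nsteps, per)
    snap_steps = np.sort(np.concatenate([base, base + off]))
    cfg = SolverConfig(dt=dt, record_sites=sites, record_dt=record_dt,
                       snapshot_steps=snap_steps,
                       terminate_on_quiescence=True)
    return run(domain, params, [], duration=cap, config=cfg, initial=field)


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------

@dataclass
class InitiationScan:
    location: str
    coupling_intervals: np.ndarray
    outcomes: list                      # per-CI: "no-reentry" | episode summary

    def __post_init__(self):
        ci = np.asarray(self.coupling_intervals, float)
        if ci.size > 1 and not np.allclose(np.diff(ci), 10.0):
            raise ValueError("coupling intervals must increase in 10 ms steps")


def scan_initiations(domain: TissueDomain, params: CellParams,
                     locations: dict[str, tuple[np.ndarray, np.ndarray]],
                     remodeling_levels: list[tuple[float, float]] | None = None,
                     coupling_intervals: np.ndarray | None = None,
                     cap: float = 10_000.0, use_clamp: bool = True,
                     seed: int = 0, frame_dt: float = 10.0,
                     min_reentry_duration: float = 150.0) -> list:
    """Coupling-interval scans over initiation locations and remodeling.

    ``locations`` maps a name to (s1_nodes, s2_nodes); ``remodeling_levels``
    is a list of (f_E, s) pairs applied on top of ``params``/``domain``.
    Every induced episode is run to termination or ``cap`` and summarized
    (see :mod:`atriasim.reentry`); non-inducing coupling intervals are
    recorded as ``no-reentry`` rows. Fully deterministic for fixed inputs.
    """
    from .reentry import summarize_episode

    if remodeling_levels is None:
        remodeling_levels = [(0.0, 1.0)]
    if coupling_intervals is None:
        coupling_intervals = np.arange(150.0, 350.0 + 1, 10.0)
    rows = []
    for (f_E, s) in remodeling_levels:
        pars = apply_electrical_remodeling(params, f_E)
        dom = apply_structural_remodeling(domain, s) if s != 1.0 else domain
        for name, (s1_nodes, s2_nodes) in locations.items():
            t_act = time_s1_arrival(dom, pars, s1_nodes, s2_nodes)
            for ci in coupling_intervals:
                init = cross_gradient_initiation(dom, pars, s1_nodes,
                                                 s2_nodes, float(ci),
                                                 use_clamp=use_clamp,
                                                 s1_activation=t_act)
                if not init.induced:
                    rows.append({"f_E": f_E, "s": s, "location": name,
                                 "ci": float(ci), "seed": seed,
                                 "outcome": "no-reentry", "summary": None})
                    continue
                rec = run_episode(dom, pars, init.field, cap=cap,
                                  frame_dt=frame_dt)
                summ = summarize_episode(rec, dom, t_init=init.t_s2, cap=cap,
                                         episode_id=f"{name}_fE{f_E}_s{s}_ci{ci:g}",
                                         f_E=f_E, s=s, location=name,
                                         ci=float(ci), seed=seed)
                outcome = ("episode" if summ.duration >= min_reentry_duration
                           else "no-reentry")
                rows.append({"f_E": f_E, "s": s, "location": name,
                             "ci": float(ci), "seed": seed,
                             "outcome": outcome, "summary": summ})
    return rows
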