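"""Explicit monodomain reaction–diffusion solver.

Operator splitting per outer step of dt = 0.01 ms: a forward-Euler
diffusion update of the voltage field (5-point / 3-point stencil with
harmonic-mean face coefficients, sealed no-flux boundaries), followed by
the cell reaction advanced with adaptive sub-stepping. Voltage-clamp
events overwrite V in their region for their duration after the reaction
update.

The kernel records voltage traces at chosen sites at a fixed cadence,
full-field snapshots at requested step indices, and optionally stops early
when the tissue is globally quiescent (all V below a threshold for a set
time after the last protocol event).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import cell as _cell
from .cell import (NSTATE, DV_MAX, DT_SUB_MIN, DT_SUB_MAX, CellParams,
                   IntegrationFailure, RATE_TABLES,
                   _react as _cell_react, _rhs_vec as _cell_rhs_vec)
from .geometry import TissueDomain

__all__ = [
    "SolverConfig", "FieldState", "Recordings",
    "StimulusEvent", "ClampEvent",
    "diffusion_step", "step", "run", "stability_limit",
]

DT_DEFAULT = 0.01  # ms


@dataclass(frozen=True)
class StimulusEvent:
    """Depolarizing current injection: ``amplitude`` in A/F for ``duration``
    ms starting at ``t_on`` (ms), applied to active-node indices ``nodes``."""
    nodes: np.ndarray
    t_on: float
    duration: float = 1.0
    amplitude: float = 80.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if len(np.atleast_1d(self.nodes)) == 0:
            raise ValueError("stimulus node set is empty")


@dataclass(frozen=True)
class ClampEvent:
    """Voltage clamp: V is held at ``voltage`` mV over ``nodes`` for
    ``duration`` ms starting at ``t_on``."""
    nodes: np.ndarray
    t_on: float
    duration: float = 1.0
    voltage: float = -80.0


@dataclass
class SolverConfig:
    dt: float = DT_DEFAULT
    record_sites: np.ndarray | None = None     # active-node indices
    record_dt: float = 1.0                     # ms
    snapshot_steps: np.ndarray | None = None   # outer-step indices
    # early-termination detector (enabled only after the last event):
    terminate_on_quiescence: bool = False
    term_voltage: float = -60.0                # mV
    term_quiet: float = 200.0                  # ms
    reaction_first: bool = False               # operator order within a step

    def validate(self, domain: TissueDomain) -> None:
        nbr, w = domain.connectivity()
        limit = stability_limit(w)
        if self.dt > limit:
            raise ValueError(
                f"dt = {self.dt} ms violates the explicit stability bound "
                f"{limit:.4f} ms for the largest diffusion coefficient")


def stability_limit(w: np.ndarray) -> float:
    """Largest stable dt (ms) for the explicit diffusion update."""
    smax = float(w.sum(axis=1).max())
    return 1.0 / smax if smax > 0 else np.inf


@dataclass
class FieldState:
    """Per-active-node cell states plus the simulation clock."""
    states: np.ndarray       # (n_active, NSTATE)
    t: float = 0.0

    @property
    def V(self) -> np.ndarray:
        return self.states[:, 0]


@dataclass
class Recordings:
    times: np.ndarray                 # (n_rec,) ms
    traces: np.ndarray                # (n_rec, n_sites) mV
    sites: np.ndarray                 # active-node indices
    snapshot_times: np.ndarray        # (n_snap,) ms
    snapshots: np.ndarray             # (n_snap, n_active) mV
    final: FieldState | None = None
    terminated_at: float | None = None  # ms, quiescence time (None if ran out)
    events: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _diffuse(V, nbr, w, dt, out):
    n = V.shape[0]
    for i in range(n):
        acc = 0.0
        vi = V[i]
        for k in range(nbr.shape[1]):
            j = nbr[i, k]
            if j >= 0:
                acc += w[i, k] * (V[j] - vi)
        out[i] = vi + dt * acc


@njit(cache=True, fastmath=True)
def _react_all(SA, V, D, p, istim, tab, I0, FR, flag_idx, flag_state,
               dy, lk, ybuf, dt, dv_max, dt_min, dt_max):
    """Vectorized reaction step over all nodes; wavefront nodes whose
    voltage increment exceeds dv_max are re-integrated adaptively from
    their pre-update state. Returns the failing node index or -1."""
    n = SA.shape[1]
    ns = SA.shape[0]
    _cell_rhs_vec(SA, D, p, istim, tab, I0, FR)
    nflag = 0
    for i in range(n):
        dv = D[0, i] * dt
        if dv > dv_max or dv < -dv_max or not (-150.0 < V[i] < 100.0):
            flag_idx[nflag] = i
            for k in range(ns):
                flag_state[nflag, k] = SA[k, i]
            nflag += 1
    for k in range(ns):
        Dk = D[k]
        Sk = SA[k]
        for i in range(n):
            Sk[i] += dt * Dk[i]
    for k in range(1, 16):
        Sk = SA[k]
        for i in range(n):
            x = Sk[i]
            if x < 0.0:
                Sk[i] = 0.0
            elif x > 1.0:
                Sk[i] = 1.0
    for q in range(nflag):
        i = flag_idx[q]
        for k in range(ns):
            ybuf[k] = flag_state[q, k]
        if _cell_react(ybuf, p, dt, istim[i], dv_max, dt_min,
                       dt_max, tab, dy, lk) != 0:
            return i
        for k in range(ns):
            SA[k, i] = ybuf[k]
    return -1


@njit(cache=True, fastmath=True)
def _writeback(states, SA):
    for i in range(states.shape[0]):
        for k in range(states.shape[1]):
            states[i, k] = SA[k, i]


@njit(cache=True, fastmath=True)
def _advance(states, nbr, w, p, dt, n_steps, step0,
             ev_kind, ev_s0, ev_s1, ev_val, ev_off, ev_nodes,
             rec_sites, rec_every, rec_t, rec_v,
             snap_steps, snap_t, snap_v,
             term_on, term_v, term_quiet_steps, term_enable_step,
             dv_max, dt_min, dt_max, tab, reaction_first):
    """Advance the field ``n_steps`` outer steps from global step ``step0``.

    Events are encoded as parallel arrays: kind (0 stimulus, 1 clamp),
    start/end step, value (A/F or mV), and node-index slices
    ev_nodes[ev_off[e]:ev_off[e+1]]. Returns (status, steps_done, n_rec,
    n_snap, term_step); status -1 flags an integration failure and the
    failing node is reported in term_step.
    """
    n = states.shape[0]
    ns = states.shape[1]
    # struct-of-arrays layout for the vectorized reaction step
    SA = np.empty((ns, n))
    for i in range(n):
        for k in range(ns):
            SA[k, i] = states[i, k]
    V = SA[0]
    D = np.empty((ns, n))
    I0 = np.empty(n, dtype=np.int64)
    FR = np.empty(n)
    flag_idx = np.empty(n, dtype=np.int64)
    flag_state = np.empty((n, ns))
    tmp = np.empty(n)
    istim = np.zeros(n)
    dy = np.empty(ns)
    lk = np.empty(tab.shape[1])
    ybuf = np.empty(ns)
    n_ev = ev_kind.shape[0]
    n_rec = 0
    n_snap = 0
    i_snap = 0
    last_active_step = step0
    for s in range(n_steps):
        gstep = step0 + s
        # toggle stimulus currents at event boundaries
        for e in range(n_ev):
            if ev_kind[e] == 0:
                if gstep == ev_s0[e]:
                    for q in range(ev_off[e], ev_off[e + 1]):
                        istim[ev_nodes[q]] = ev_val[e]
                elif gstep == ev_s1[e]:
                    for q in range(ev_off[e], ev_off[e + 1]):
                        istim[ev_nodes[q]] = 0.0
        # one split step; either operator order is supported (their APD
        # difference is a tested self-consistency bound)
        if not reaction_first:
            _diffuse(V, nbr, w, dt, tmp)
            for i in range(n):
                V[i] = tmp[i]
        bad = _react_all(SA, V, D, p, istim, tab, I0, FR, flag_idx,
                         flag_state, dy, lk, ybuf, dt, dv_max, dt_min, dt_max)
        if bad >= 0:
            _writeback(states, SA)
            return -1, s, n_rec, n_snap, bad
        if reaction_first:
            _diffuse(V, nbr, w, dt, tmp)
            for i in range(n):
                V[i] = tmp[i]
        # clamps overwrite
        for e in range(n_ev):
            if ev_kind[e] == 1 and ev_s0[e] <= gstep < ev_s1[e]:
                for q in range(ev_off[e], ev_off[e + 1]):
                    V[ev_nodes[q]] = ev_val[e]
        # recordings
        if rec_every > 0 and (gstep + 1) % rec_every == 0:
            rec_t[n_rec] = (gstep + 1) * dt
            for m in range(rec_sites.shape[0]):
                rec_v[n_rec, m] = V[rec_sites[m]]
            n_rec += 1
        if i_snap < snap_steps.shape[0] and gstep + 1 == snap_steps[i_snap]:
            snap_t[n_snap] = (gstep + 1) * dt
            for i in range(n):
                snap_v[n_snap, i] = V[i]
            n_snap += 1
            i_snap += 1
        # quiescence detection
        if term_on and gstep >= term_enable_step and (gstep % 25) == 0:
            vmax = -1e9
            for i in range(n):
                if V[i] > vmax:
                    vmax = V[i]
            if vmax >= term_v:
                last_active_step = gstep
            elif gstep - last_active_step >= term_quiet_steps:
                _writeback(states, SA)
                return 1, s + 1, n_rec, n_snap, last_active_step
        elif term_on and gstep < term_enable_step:
            last_active_step = gstep
    _writeback(states, SA)
    return 0, n_steps, n_rec, n_snap, last_active_step


# ---------------------------------------------------------------------------
# Python-level API
# ---------------------------------------------------------------------------

def _pack_events(events, dt, n_active) -> tuple[np.ndarray, ...]:
    ev_kind = np.empty(len(events), dtype=np.int64)
    ev_s0 = np.empty(len(events), dtype=np.int64)
    ev_s1 = np.empty(len(events), dtype=np.int64)
    ev_val = np.empty(len(events))
    offs = [0]
    nodes = []
    for k, ev in enumerate(events):
        idx = np.atleast_1d(np.asarray(ev.nodes, dtype=np.int64))
        if idx.size and (idx.min() < 0 or idx.max() >= n_active):
            raise ValueError("event node index outside the active node set")
        if isinstance(ev, StimulusEvent):
            ev_kind[k] = 0
            ev_val[k] = ev.amplitude
        elif isinstance(ev, ClampEvent):
            ev_kind[k] = 1
            ev_val[k] = ev.voltage
        else:
            raise TypeError(f"unknown event type {type(ev)!r}")
        ev_s0[k] = int(round(ev.t_on / dt))
        ev_s1[k] = int(round((ev.t_on + ev.duration) / dt))
        nodes.append(idx)
        offs.append(offs[-1] + idx.size)
    ev_off = np.asarray(offs, dtype=np.int64)
    ev_nodes = (np.concatenate(nodes) if nodes else np.empty(0, dtype=np.int64))
    return ev_kind, ev_s0, ev_s1, ev_val, ev_off, ev_nodes


def initial_field(domain: TissueDomain, params: CellParams) -> FieldState:
    """All nodes at the single-cell rest state of ``params``."""
    y0 = _cell.rest_state(params)
    states = np.tile(y0, (domain.n_active, 1))
    return FieldState(states=states, t=0.0)


def diffusion_step(V: np.ndarray, domain: TissueDomain,
                   dt: float = DT_DEFAULT) -> np.ndarray:
    """One explicit diffusion update of an active-node voltage vector."""
    nbr, w = domain.connectivity()
    if dt > stability_limit(w):
        raise ValueError("dt violates the explicit stability bound")
    out = np.empty_like(np.asarray(V, dtype=float))
    _diffuse(np.asarray(V, dtype=float), nbr, w, dt, out)
    return out


def step(field: FieldState, domain: TissueDomain, params: CellParams,
         events: list | None = None, dt: float = DT_DEFAULT) -> FieldState:
    """One split step (diffusion then reaction) with any active events."""
    rec = run(domain, params, events or [], duration=dt,
              config=SolverConfig(dt=dt, record_dt=0.0), initial=field)
    return rec.final


def run(domain: TissueDomain, params: CellParams, events: list,
        duration: float, config: SolverConfig | None = None,
        initial: FieldState | None = None,
        keep_final: bool = True) -> Recordings:
    """Integrate the monodomain system for ``duration`` ms.

    Returns site traces (cadence ``config.record_dt``), snapshots at
    ``config.snapshot_steps`` (global outer-step indices), and the final
    field. With ``terminate_on_quiescence`` the run stops once every node
    has stayed below ``term_voltage`` for ``term_quiet`` ms after the last
    event; ``terminated_at`` then reports the time of last activity.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    cfg = config or SolverConfig()
    nbr, w = domain.connectivity()
    if cfg.dt > stability_limit(w):
        raise ValueError(
            f"dt = {cfg.dt} violates stability bound {stability_limit(w):.4f} ms")
    if initial is None:
        initial = initial_field(domain, params)
    states = initial.states.copy()
    step0 = int(round(initial.t / cfg.dt))
    n_steps = int(round(duration / cfg.dt))

    ev_pack = _pack_events(events, cfg.dt, domain.n_active)
    sites = (np.asarray(cfg.record_sites, dtype=np.int64)
             if cfg.record_sites is not None else np.empty(0, dtype=np.int64))
    rec_every = int(round(cfg.record_dt / cfg.dt)) if cfg.record_dt > 0 else 0
    max_rec = (n_steps // rec_every + 2) if rec_every else 1
    rec_t = np.zeros(max_rec)
    rec_v = np.zeros((max_rec, sites.size))
    snap_steps = (np.asarray(cfg.snapshot_steps, dtype=np.int64)
                  if cfg.snapshot_steps is not None else np.empty(0, dtype=np.int64))
    snap_steps = np.sort(snap_steps)
    snap_t = np.zeros(snap_steps.size)
    snap_v = np.zeros((snap_steps.size, domain.n_active))

    term_enable = 0
    if events:
        term_enable = int(max(ev.t_on + ev.duration for ev in events) / cfg.dt) + 1
    term_quiet_steps = int(round(cfg.term_quiet / cfg.dt))

    status, done, n_rec, n_snap, info = _advance(
        states, nbr, w, params.to_array(), cfg.dt, n_steps, step0,
        *ev_pack, sites, rec_every, rec_t, rec_v,
        snap_steps, snap_t, snap_v,
        cfg.terminate_on_quiescence, cfg.term_voltage, term_quiet_steps,
        term_enable, DV_MAX, DT_SUB_MIN, DT_SUB_MAX, RATE_TABLES,
        cfg.reaction_first)
    if status == -1:
        raise IntegrationFailure(
            f"integration failure at node {info}, t = {(step0 + done) * cfg.dt} ms")
    final = FieldState(states=states, t=(step0 + done) * cfg.dt)
    return Recordings(
        times=rec_t[:n_rec], traces=rec_v[:n_rec], sites=sites,
        snapshot_times=snap_t[:n_snap], snapshots=snap_v[:n_snap],
        final=final if keep_final else None,
        terminated_at=(info * cfg.dt if status == 1 else None),
        events=list(events),
    )
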