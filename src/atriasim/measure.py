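"""Estimators for paced and reentrant recordings.

Action potential duration (APD) and diastolic interval (DI) are defined by
-70 mV threshold crossings: APD from the upstroke crossing to the
repolarization crossing, DI from a repolarization crossing to the next
upstroke. Conduction velocity (CV) comes from a least-squares fit of
activation time against distance along a probe line. CV- and
APD-restitution curves are assembled from steady-state pacing at a grid of
cycle lengths, and the local wavelength during reentry is estimated as
WL = APD x CV(DI) by reading CV off the restitution curve at the measured
diastolic interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CrossingSeries", "RestitutionCurve", "WavelengthEstimate",
    "detect_crossings", "compute_apd_di", "measure_cv",
    "build_restitution", "estimate_wavelength", "select_recording_sites",
    "APD_THRESHOLD",
]

APD_THRESHOLD = -70.0  # mV


@dataclass
class CrossingSeries:
    """Interpolated -70 mV crossing times (ms) of one voltage trace."""
    ups: np.ndarray
    downs: np.ndarray
    threshold: float = APD_THRESHOLD

    def __post_init__(self):
        if np.any(np.diff(self.ups) <= 0) or np.any(np.diff(self.downs) <= 0):
            raise ValueError("crossing times must be strictly increasing")


def detect_crossings(times: np.ndarray, trace: np.ndarray,
                     threshold: float = APD_THRESHOLD) -> CrossingSeries:
    """Linear-interpolated threshold crossings, classified by slope sign.

    A trace that never crosses the threshold yields an empty series.
    Sampling must be uniform with interval <= 1 ms.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(trace, dtype=float)
    if t.size != v.size:
        raise ValueError("times and trace must have equal length")
    if t.size >= 2:
        dt = np.diff(t)
        if dt.max() > 1.0 + 1e-9 or np.ptp(dt) > 1e-6 * dt[0]:
            raise ValueError("trace must be uniformly sampled at <= 1 ms")
    above = v >= threshold
    up_idx = np.flatnonzero(~above[:-1] & above[1:])
    dn_idx = np.flatnonzero(above[:-1] & ~above[1:])

    def interp(idx):
        frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
        return t[idx] + frac * (t[idx + 1] - t[idx])

    return CrossingSeries(ups=interp(up_idx), downs=interp(dn_idx),
                          threshold=threshold)


def compute_apd_di(series: CrossingSeries) -> tuple[np.ndarray, np.ndarray]:
    """APD_i = down_i - up_i and DI_i = up_{i+1} - down_i.

    A trailing upstroke without a matching repolarization (incomplete AP)
    is discarded.
    """
    ups, downs = series.ups, series.downs
    if ups.size and downs.size and downs[0] < ups[0]:
        downs = downs[1:]   # trace started mid-AP
    n = min(ups.size, downs.size)
    apd = downs[:n] - ups[:n]
    di = ups[1:n] - downs[:n - 1]
    return apd, di


def measure_cv(activation_times: np.ndarray, positions: np.ndarray) -> float:
    """CV (cm/ms) as the inverse slope of activation time vs distance.

    Requires >= 5 collinear probe points and monotone activation (a
    non-planar or blocked wave is rejected).
    """
    t = np.asarray(activation_times, dtype=float)
    x = np.asarray(positions, dtype=float)
    if t.size < 5:
        raise ValueError("need >= 5 probe points for a CV fit")
    order = np.argsort(x)
    if np.any(np.diff(t[order]) <= 0):
        raise ValueError("activation not monotone along the probe; wave not planar")
    slope = np.polyfit(x, t, 1)[0]
    return 1.0 / slope


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares non-decreasing fit."""
    y = np.asarray(y, float)
    level = y.copy()
    weight = np.ones_like(y)
    blocks = list(range(len(y)))
    i = 0
    vals = list(level)
    wts = list(weight)
    out_idx = [[k] for k in blocks]
    k = 0
    while k < len(vals) - 1:
        if vals[k] > vals[k + 1] + 1e-12:
            merged = (vals[k] * wts[k] + vals[k + 1] * wts[k + 1]) / (wts[k] + wts[k + 1])
            vals[k] = merged
            wts[k] += wts[k + 1]
            out_idx[k] += out_idx[k + 1]
            del vals[k + 1], wts[k + 1], out_idx[k + 1]
            if k > 0:
                k -= 1
        else:
            k += 1
    fit = np.empty_like(y)
    for v, idx in zip(vals, out_idx):
        fit[idx] = v
    return fit


@dataclass
class RestitutionCurve:
    """Monotone mapping DI -> CV (cm/ms) and DI -> APD (ms).

    Piecewise-linear interpolation between the sampled steady-state points;
    queries outside the sampled DI range use flat extrapolation and are
    flagged through :meth:`in_range`.
    """
    di: np.ndarray
    cv: np.ndarray
    apd: np.ndarray
    cycle_lengths: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        order = np.argsort(self.di)
        self.di = np.asarray(self.di, float)[order]
        self.cv = np.asarray(self.cv, float)[order]
        self.apd = np.asarray(self.apd, float)[order]
        if np.any(np.diff(self.di) <= 0):
            raise ValueError("DI samples must be distinct")
        # monotone (non-decreasing) interpolants: isotonic fit absorbs
        # measurement noise in the raw samples, which are kept as-is
        self.cv_fit = _pava(self.cv)
        self.apd_fit = _pava(self.apd)

    def in_range(self, di) -> np.ndarray:
        return (di >= self.di[0]) & (di <= self.di[-1])

    def cv_at(self, di) -> np.ndarray:
        return np.interp(di, self.di, self.cv_fit)

    def apd_at(self, di) -> np.ndarray:
        return np.interp(di, self.di, self.apd_fit)

    def max_apd_slope(self) -> float:
        """Maximum slope of the monotone piecewise-linear APD restitution."""
        seg = np.diff(self.apd_fit) / np.diff(self.di)
        return float(seg.max())


def build_restitution(domain, params, cycle_lengths,
                      site: int | None = None, **pacing_kwargs) -> RestitutionCurve:
    """Steady-state (DI, CV, APD) samples over a pacing-rate sweep.

    Each cycle length is paced to a stationary state on ``domain``; cycle
    lengths that lose 1:1 capture are dropped (recorded in
    ``meta['dropped']``). A cycle length that settles into 2:2 alternans
    contributes both branches (its long and short beats) as separate
    samples. Fewer than 3 valid cycle lengths is an error.
    """
    from .protocols import periodic_pacing   # runtime import: avoids cycle

    di_s, cv_s, apd_s, cl_s, dropped = [], [], [], [], []
    for cl in cycle_lengths:
        res = periodic_pacing(domain, params, cycle_length=cl,
                              until_steady=True, site=site, **pacing_kwargs)
        if not res.captured_1to1 or not res.steady:
            # lost 1:1 capture or never reached a stationary (1:1 or 2:2)
            # rhythm: unusable as a steady-state restitution sample
            dropped.append(cl)
            continue
        # sample (DI, APD) pairs from the final beats; each is accepted only
        # if the activation interval it closes matches the cycle length
        # (guards against partially captured or drifting rhythms)
        pairs = []
        a, d = res.apds, res.dis
        if a.size >= 2 and d.size >= 1 and abs(a[-2] + d[-1] - cl) < 5.0:
            pairs.append((d[-1], a[-1]))
        if (res.alternans and a.size >= 3 and d.size >= 2
                and abs(a[-3] + d[-2] - cl) < 5.0):
            pairs.append((d[-2], a[-2]))
        if not pairs:
            dropped.append(cl)
            continue
        for di, apd in pairs:
            if any(abs(di - d0) < 0.5 for d0 in di_s):
                continue
            di_s.append(float(di))
            apd_s.append(float(apd))
            cv_s.append(res.cv)
            cl_s.append(cl)
    if len(set(cl_s)) < 3:
        raise ValueError(
            f"only {len(set(cl_s))} cycle lengths achieved 1:1 capture; "
            f"restitution curve unusable (dropped: {dropped})")
    return RestitutionCurve(di=np.array(di_s), cv=np.array(cv_s),
                            apd=np.array(apd_s), cycle_lengths=np.array(cl_s),
                            meta={"dropped": dropped})


@dataclass(frozen=True)
class WavelengthEstimate:
    site: int
    time: float       # ms
    apd: float        # ms
    di: float         # ms
    cv: float         # cm/ms
    wl: float         # cm
    extrapolated: bool = False


def estimate_wavelength(apd: float, di: float, curve: RestitutionCurve,
                        site: int = -1, time: float = np.nan) -> WavelengthEstimate:
    """WL = APD x CV(DI) in cm; out-of-range DI is flagged, not dropped."""
    cv = float(curve.cv_at(di))
    ok = bool(curve.in_range(di))
    return WavelengthEstimate(site=site, time=time, apd=apd, di=di, cv=cv,
                              wl=apd * cv, extrapolated=not ok)


def select_recording_sites(domain, n: int = 16, seed: int = 0) -> np.ndarray:
    """Farthest-point sampling of ``n`` recording sites over active nodes.

    Greedy max-min design: the first site is drawn from the seeded RNG,
    each further site maximizes its distance to those already chosen.
    Returns active-node indices.
    """
    coords = np.argwhere(domain.active) * domain.dx
    m = coords.shape[0]
    if n >= m:
        return np.arange(m)
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(m))]
    dmin = np.linalg.norm(coords - coords[chosen[0]], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(coords - coords[nxt], axis=1))
    return np.array(sorted(chosen))
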