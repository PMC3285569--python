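"""Synthetic tissue geometries.

The 3D atrial anatomy the physiology targets is not distributed, so the
package generates surrogate domains that carry the structural features the
analysis depends on: heterogeneous conduction regions (fast pathway / bulk /
slow isthmus, calibrated to 120 / 65 / 36 cm/s plane-wave conduction at
sinus rate), inexcitable anatomical obstacles that reentrant waves can
anchor to, graded gap-junctional uncoupling (structural remodeling, a
uniform diffusion scale-down), and an optional diffuse-fibrosis variant
(random electrically inactive nodes sealed by no-flux faces).

Domains are regular 1D/2D grids with node spacing dx = 0.025 cm. Diffusion
coefficients are per-node; interfaces between regions use harmonic-mean
face coefficients in the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "TissueDomain",
    "REGION_D",
    "REGION_CV",
    "BULK", "FAST", "SLOW",
    "make_cable",
    "make_sheet",
    "make_annulus",
    "make_atrial_surrogate",
    "apply_structural_remodeling",
    "apply_random_fibrosis",
]

DX_DEFAULT = 0.025  # cm

BULK, FAST, SLOW = 0, 1, 2
LABEL_NAMES = {BULK: "bulk", FAST: "fast", SLOW: "slow"}
LABEL_IDS = {v: k for k, v in LABEL_NAMES.items()}

# Target plane-wave conduction velocities at sinus-rate pacing (cm/ms).
REGION_CV = {BULK: 0.065, FAST: 0.120, SLOW: 0.036}

# Diffusion coefficients (cm^2/ms) calibrated once so that a paced cable of
# each tissue class conducts at its target velocity at cycle length 1000 ms
# with dx = 0.025 cm, dt = 0.01 ms (see scripts/calibrate_diffusion.py).
REGION_D = {
    BULK: 1.9445e-3,
    FAST: 5.9802e-3,
    SLOW: 7.3807e-4,
}


@dataclass
class TissueDomain:
    """Discrete simulation domain.

    ``active``, ``labels`` and ``D`` are full-grid arrays; inactive nodes
    have label -1 and D = 0. ``structural_scale`` records the cumulative
    diffusion scale-down s in (0, 1].
    """

    shape: tuple[int, ...]
    dx: float
    active: np.ndarray
    labels: np.ndarray
    D: np.ndarray
    structural_scale: float = 1.0
    seed: int | None = None
    manifest: dict = field(default_factory=dict)
    obstacles: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.shape != tuple(self.shape):
            raise ValueError("active mask shape mismatch")
        if np.any((self.labels < 0) & self.active):
            raise ValueError("every active node needs a region label")
        if np.any(self.active & ~(self.D > 0)):
            raise ValueError("every active node needs D > 0")
        self._check_connected()

    # -- structure ------------------------------------------------------

    def _check_connected(self) -> None:
        struct = ndimage.generate_binary_structure(self.active.ndim, 1)
        _, n = ndimage.label(self.active, structure=struct)
        if n != 1:
            raise ValueError(f"active tissue must be one connected component, found {n}")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def node_ids(self) -> np.ndarray:
        """Flat grid index of each active node (solver node order)."""
        return np.flatnonzero(self.active.ravel())

    def grid_to_node(self) -> np.ndarray:
        """Map flat grid index -> active-node index (-1 if inactive)."""
        out = np.full(self.active.size, -1, dtype=np.int64)
        out[self.node_ids()] = np.arange(self.n_active)
        return out

    def connectivity(self) -> tuple[np.ndarray, np.ndarray]:
        """Neighbour table and diffusive face weights for the solver.

        Returns (nbr, w): both (n_active, 2*ndim). ``nbr[i, k]`` is the
        active-node index of node i's k-th orthogonal neighbour or -1 at a
        sealed face (grid boundary or inactive node). ``w[i, k]`` is the
        harmonic-mean face diffusion divided by dx^2 (ms^-1), so the
        explicit update is V_i += dt * sum_k w[i,k] (V_j - V_i).
        """
        if self.ndim == 1:
            grid2node = self.grid_to_node()
        else:
            grid2node = self.grid_to_node().reshape(self.shape)
        coords = np.argwhere(self.active)
        n = len(coords)
        D_act = self.D[tuple(coords.T)]
        nbr = np.full((n, 2 * self.ndim), -1, dtype=np.int64)
        w = np.zeros((n, 2 * self.ndim))
        for axis in range(self.ndim):
            for sgn, col in ((-1, 2 * axis), (+1, 2 * axis + 1)):
                shifted = coords.copy()
                shifted[:, axis] += sgn
                ok = (shifted[:, axis] >= 0) & (shifted[:, axis] < self.shape[axis])
                sel = np.where(ok)[0]
                j = grid2node[tuple(shifted[sel].T)]
                live = j >= 0
                sel, jj = sel[live], j[live]
                nbr[sel, col] = jj
                Di, Dj = D_act[sel], D_act[jj]
                w[sel, col] = 2.0 * Di * Dj / (Di + Dj) / self.dx ** 2
        return nbr, w

    def copy(self) -> "TissueDomain":
        return TissueDomain(
            shape=self.shape, dx=self.dx, active=self.active.copy(),
            labels=self.labels.copy(), D=self.D.copy(),
            structural_scale=self.structural_scale, seed=self.seed,
            manifest=dict(self.manifest), obstacles=list(self.obstacles),
        )


# ---------------------------------------------------------------------------
# Constructors
# ---------------------------------------------------------------------------

def _labels_to_D(labels: np.ndarray, active: np.ndarray) -> np.ndarray:
    D = np.zeros(labels.shape)
    for lab, d in REGION_D.items():
        D[(labels == lab) & active] = d
    return D


def make_cable(n_nodes: int, region_label: str | int = BULK,
               dx: float = DX_DEFAULT) -> TissueDomain:
    """Homogeneous 1D strand (n_nodes >= 50, i.e. >= 1.25 cm at default dx)."""
    if n_nodes < 50:
        raise ValueError("cable too short for APD/CV measurement (need >= 50 nodes)")
    lab = LABEL_IDS.get(region_label, region_label)
    if lab not in REGION_D:
        raise ValueError(f"unknown region label {region_label!r}")
    active = np.ones(n_nodes, dtype=bool)
    labels = np.full(n_nodes, lab, dtype=np.int8)
    return TissueDomain((n_nodes,), dx, active, labels,
                        _labels_to_D(labels, active))


def make_sheet(nx: int, ny: int, region_map: np.ndarray | str | int = BULK,
               active: np.ndarray | None = None,
               dx: float = DX_DEFAULT) -> TissueDomain:
    """2D sheet; ``region_map`` is a label grid or a single label."""
    shape = (nx, ny)
    if active is None:
        active = np.ones(shape, dtype=bool)
    active = np.asarray(active, dtype=bool)
    if isinstance(region_map, (str, int)):
        lab = LABEL_IDS.get(region_map, region_map)
        labels = np.full(shape, lab, dtype=np.int8)
    else:
        labels = np.asarray(region_map, dtype=np.int8)
        if labels.shape != shape:
            raise ValueError("region_map shape mismatch")
    labels = labels.copy()
    labels[~active] = -1
    if np.any(active & ~np.isin(labels, list(REGION_D))):
        raise ValueError("unlabeled or unknown-label active node")
    return TissueDomain(shape, dx, active, labels,
                        _labels_to_D(labels, active))


def make_annulus(r_outer: float = 1.15, width: float = 0.15,
                 dx: float = DX_DEFAULT, region_label: str | int = BULK,
                 margin: float = 0.1) -> TissueDomain:
    """Annular domain: a ring of tissue around one central inexcitable
    obstacle — the minimal anchored-reentry geometry. ``r_outer`` and
    ``width`` are in cm; the obstacle manifest records the inner perimeter
    and the mid-channel path length that bound anchored-reentry periods."""
    if width <= 2 * dx:
        raise ValueError("annulus channel must span more than two nodes")
    L = 2 * (r_outer + margin)
    n = int(round(L / dx))
    xs = (np.arange(n) + 0.5) * dx
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    c = L / 2
    r = np.hypot(X - c, Y - c)
    r_in = r_outer - width
    active = (r > r_in) & (r < r_outer)
    dom = make_sheet(n, n, region_label, active=active, dx=dx)
    r_mid = r_in + width / 2
    dom.obstacles = [{"id": "central", "center_cm": (c, c),
                      "radius_cm": float(r_in),
                      "perimeter_cm": float(2 * np.pi * r_in),
                      "mid_path_cm": float(2 * np.pi * r_mid)}]
    dom.manifest = {"kind": "annulus", "r_outer_cm": r_outer,
                    "width_cm": width}
    return dom


@dataclass(frozen=True)
class SurrogateConfig:
    """Layout of the 2D atrial surrogate.

    A square sheet with two large circular holes (standing in for the
    valve annuli), a few small holes (venous ostia), a slow-conducting
    isthmus bridging the large holes, and a fast-conducting strip
    (Bachmann's-bundle analogue) across the top. Radii in cm.
    """

    nx: int = 300
    ny: int = 300
    dx: float = DX_DEFAULT
    large_hole_radius: float = 0.9
    small_hole_radius: float = 0.25
    n_small_holes: int = 3
    fast_strip_width: float = 0.4
    isthmus_half_width: float = 0.35
    jitter: float = 0.15   # cm, random displacement of hole centres


def make_atrial_surrogate(seed: int = 0,
                          config: SurrogateConfig | None = None) -> TissueDomain:
    """Deterministic-for-seed 2D surrogate with obstacles and all three
    conduction classes; obstacle perimeters are reported in the manifest
    (perimeter / CV bounds the minimal period of anchored reentry)."""
    cfg = config or SurrogateConfig()
    rng = np.random.default_rng(seed)
    nx, ny, dx = cfg.nx, cfg.ny, cfg.dx
    Lx, Ly = nx * dx, ny * dx
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dx
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    def jit(v):
        return v + rng.uniform(-cfg.jitter, cfg.jitter)

    holes = []
    # two large annulus-analogue holes, left and right of centre
    holes.append((jit(0.30 * Lx), jit(0.45 * Ly), cfg.large_hole_radius, "annulus_L"))
    holes.append((jit(0.70 * Lx), jit(0.45 * Ly), cfg.large_hole_radius, "annulus_R"))
    # small venous-ostium holes along the upper half
    for k in range(cfg.n_small_holes):
        fx = 0.2 + 0.6 * (k + 0.5) / cfg.n_small_holes
        holes.append((jit(fx * Lx), jit(0.80 * Ly), cfg.small_hole_radius,
                      f"ostium_{k}"))

    active = np.ones((nx, ny), dtype=bool)
    obstacles = []
    for cx, cy, r, name in holes:
        mask = (X - cx) ** 2 + (Y - cy) ** 2 <= r ** 2
        if np.any(mask & ~active):
            raise ValueError(f"obstacle {name} overlaps an earlier obstacle")
        active &= ~mask
        obstacles.append({"id": name, "center_cm": (float(cx), float(cy)),
                          "radius_cm": float(r),
                          "perimeter_cm": float(2 * np.pi * r)})
    # check clearance between holes (no overlap through dilation)
    for i in range(len(holes)):
        for j_ in range(i + 1, len(holes)):
            xi, yi, ri, ni = holes[i]
            xj, yj, rj, nj = holes[j_]
            if np.hypot(xi - xj, yi - yj) <= ri + rj + 2 * dx:
                raise ValueError(f"obstacles {ni} and {nj} overlap")

    labels = np.full((nx, ny), BULK, dtype=np.int8)
    # fast strip across the top edge
    labels[:, Y[0] > Ly - cfg.fast_strip_width] = FAST
    # slow isthmus: band between the two large holes
    (x1, y1, r1, _), (x2, y2, r2, _) = holes[0], holes[1]
    ex, ey = x2 - x1, y2 - y1
    L = np.hypot(ex, ey)
    ex, ey = ex / L, ey / L
    tpar = (X - x1) * ex + (Y - y1) * ey
    tperp = -(X - x1) * ey + (Y - y1) * ex
    isthmus = (tpar > r1 * 0.8) & (tpar < L - r2 * 0.8) & \
              (np.abs(tperp) < cfg.isthmus_half_width)
    labels[isthmus] = SLOW
    labels[~active] = -1

    dom = TissueDomain((nx, ny), dx, active, labels,
                       _labels_to_D(labels, active), seed=seed,
                       manifest={"config": cfg.__dict__, "seed": seed},
                       obstacles=obstacles)
    return dom


# ---------------------------------------------------------------------------
# Remodeling transforms
# ---------------------------------------------------------------------------

def apply_structural_remodeling(domain: TissueDomain, s: float) -> TissueDomain:
    """Scale every node's diffusion coefficient by s in (0, 1].

    s = 0.5 is the maximal structural remodeling level; 0.83 and 0.70 are
    the intermediate levels used in the remodeling sweeps.
    """
    if not 0.0 < s <= 1.0:
        raise ValueError(f"structural scale must lie in (0, 1], got {s}")
    out = domain.copy()
    out.D = domain.D * s
    out.structural_scale = domain.structural_scale * s
    return out


def apply_random_fibrosis(domain: TissueDomain, fraction: float,
                          seed: int) -> TissueDomain:
    """Inactivate a uniformly random fraction of nodes (diffuse fibrosis).

    Inactivated nodes are sealed (no-flux faces); exactly
    ``floor(fraction * N)`` nodes are drawn. Random inactivation strands a
    few small islands of tissue; electrically isolated islands are pruned
    (also inactivated) so the domain keeps a single connected component.
    If pruning would remove more than 2% of the original nodes, the
    fraction has effectively disconnected the tissue and an error is
    raised with a diagnostic.
    """
    if not 0.0 <= fraction <= 0.5:
        raise ValueError("fibrosis fraction must lie in [0, 0.5]")
    out = domain.copy()
    if fraction == 0.0:
        return out
    rng = np.random.default_rng(seed)
    ids = domain.node_ids()
    k = int(np.floor(fraction * len(ids)))
    kill = rng.choice(ids, size=k, replace=False)
    act = out.active.ravel()
    act[kill] = False
    out.active = act.reshape(domain.shape)
    struct = ndimage.generate_binary_structure(out.active.ndim, 1)
    comp, n = ndimage.label(out.active, structure=struct)
    pruned = 0
    if n > 1:
        sizes = ndimage.sum_labels(out.active, comp, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        prune_mask = out.active & (comp != keep)
        pruned = int(prune_mask.sum())
        if pruned > 0.02 * len(ids):
            raise ValueError(
                f"fibrosis fraction {fraction} at seed {seed} disconnects "
                f"the tissue ({n} components, {pruned} nodes stranded); "
                f"use a lower fraction or another seed")
        out.active = out.active & ~prune_mask
    out.labels = out.labels.copy()
    out.labels[~out.active] = -1
    out.D = out.D.copy()
    out.D[~out.active] = 0.0
    out.manifest = dict(out.manifest,
                        fibrosis={"fraction": fraction, "seed": seed,
                                  "n_random": k, "n_pruned": pruned})
    out.seed = seed
    return out
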