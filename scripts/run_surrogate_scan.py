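#!/usr/bin/env python
"""Full-scale paired remodeling scans (long-running study driver).

Two studies, selectable with --mode:

ring (default; ~1-2 h on one core)
    Anchored-reentry episodes on an annulus-size series (8 path lengths
    spanning 6.5-12.9 cm) for the four remodeling arms: baseline,
    full electrical (f_E = 1), full structural (s = 0.5), and combined.
    Eight episodes per arm. Reports mean episode duration per arm, the
    one-sided sign tests between arms, and the Spearman rank correlation
    between per-episode wavelength (APD x CV at the episode's own period,
    from the preconditioning strand) and duration.

surrogate (days-scale on one core)
    Cross-gradient initiation scans on the 7.5 x 7.5 cm two-region atrial
    surrogate (300x300 nodes, obstacles, fast/bulk/slow classes) with
    coupling-interval scans at 10 ms steps over multiple locations, full
    filament analysis per episode, and the structural-vs-electrical
    maximal-filament-count comparison at matched wavelength. This is the
    scan whose per-episode cost (~15 min at 300x300, episode caps of
    seconds) makes it a standalone study rather than part of the test
    suite.

Results go to --out-dir as CSV plus a JSON summary.
"""

from __future__ import annotations

import argparse
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from atriasim import (make_annulus, make_atrial_surrogate, SurrogateConfig,
                      make_baseline_params, apply_electrical_remodeling,
                      apply_structural_remodeling, ring_pulse_field,
                      scan_initiations, seed_for)
from atriasim.solver import SolverConfig, run
from atriasim.reentry import episode_duration, mean_period
from atriasim.protocols import _default_stim_nodes, default_s2_region
from atriasim import io as aio

ARMS = {"baseline": (0.0, 1.0), "electrical": (1.0, 1.0),
        "structural": (0.0, 0.5), "combined": (1.0, 0.5)}


def ring_sites(dom, n=8):
    coords = np.argwhere(dom.active) * dom.dx
    cx, cy = dom.obstacles[0]["center_cm"]
    th = np.arctan2(coords[:, 1] - cy, coords[:, 0] - cx)
    out = []
    for t0 in np.linspace(-np.pi, np.pi, n + 1)[:-1]:
        sel = np.flatnonzero(np.abs(np.angle(np.exp(1j * (th - t0)))) < 0.07)
        if len(sel):
            out.append(int(sel[len(sel) // 2]))
    return np.array(out)


def ring_study(out_dir: Path, seed: int, cap: float = 1200.0) -> dict:
    radii = np.linspace(1.13, 2.15, 8)       # mid paths ~6.5 .. 12.9 cm
    base = make_baseline_params()
    rows = []
    for arm, (f_E, s) in ARMS.items():
        pars = apply_electrical_remodeling(base, f_E)
        for r_out in radii:
            t0 = time.time()
            dom = make_annulus(r_outer=float(r_out), width=0.15)
            if s != 1.0:
                dom = apply_structural_remodeling(dom, s)
            init = ring_pulse_field(dom, pars)
            cfg = SolverConfig(record_sites=ring_sites(dom), record_dt=1.0,
                               terminate_on_quiescence=True)
            rec = run(dom, pars, [], duration=cap, config=cfg,
                      initial=init.field)
            dur, sust = episode_duration(rec, t_init=0.0, cap=cap)
            per = mean_period(rec, t_init=0.0)
            rows.append({"arm": arm, "f_E": f_E, "s": s,
                         "r_outer_cm": float(r_out),
                         "path_cm": dom.obstacles[0]["mid_path_cm"],
                         "wl_cm": init.wavelength, "apd_ms": init.apd,
                         "cv_cm_per_ms": init.cv, "duration_ms": dur,
                         "sustained": sust, "period_ms": per,
                         "seed": seed})
            print(f"{arm:10s} path {rows[-1]['path_cm']:5.2f} cm  "
                  f"WL {init.wavelength:5.2f}  dur {dur:6.0f}  "
                  f"({time.time() - t0:.0f}s)", flush=True)
    df = pd.DataFrame(rows)
    aio.write_table(df, out_dir / "ring_episodes.csv")

    d = {a: df[df.arm == a].duration_ms.to_numpy() for a in ARMS}
    def one_sided_sign(a, b):
        wins = int(np.sum(b > a))
        n = int(np.sum(b != a))
        return stats.binomtest(wins, n, 0.5, alternative="greater").pvalue \
            if n else 1.0
    rho, p_rho = stats.spearmanr(df.wl_cm, df.duration_ms)
    summary = {
        "mean_duration_ms": {a: float(v.mean()) for a, v in d.items()},
        "p_base_lt_electrical": one_sided_sign(d["baseline"], d["electrical"]),
        "p_base_lt_structural": one_sided_sign(d["baseline"], d["structural"]),
        "p_electrical_lt_combined": one_sided_sign(d["electrical"], d["combined"]),
        "p_structural_lt_combined": one_sided_sign(d["structural"], d["combined"]),
        "spearman_wl_duration": float(rho),
        "spearman_p": float(p_rho),
    }
    return summary


def surrogate_study(out_dir: Path, seed: int, cap: float = 10_000.0) -> dict:
    dom0 = make_atrial_surrogate(seed=seed_for(seed, "geometry"),
                                 config=SurrogateConfig())
    base = make_baseline_params()
    locations = {
        "west": (_default_stim_nodes(dom0), default_s2_region(dom0, "sw")),
        "east": (_default_stim_nodes(dom0), default_s2_region(dom0, "ne")),
        "south": (_default_stim_nodes(dom0), default_s2_region(dom0, "se")),
    }
    levels = {"baseline": [(0.0, 1.0)],
              "electrical": [(0.5, 1.0), (1.0, 1.0)],
              "structural": [(0.0, 0.7), (0.0, 0.5)],
              "combined": [(1.0, 0.7), (1.0, 0.5)]}
    all_rows = []
    for arm, lv in levels.items():
        res = scan_initiations(
            dom0, base, locations, remodeling_levels=lv,
            coupling_intervals=np.arange(150.0, 301.0, 10.0),
            cap=cap, seed=seed_for(seed, "scan"))
        for r in res:
            summ = r.pop("summary")
            r.update(arm=arm,
                     duration_ms=summ.duration if summ else 0.0,
                     sustained=bool(summ.sustained) if summ else False,
                     max_filaments=summ.max_filaments if summ else 0,
                     mean_period_ms=summ.mean_period if summ else np.nan)
            all_rows.append(r)
        aio.write_table(pd.DataFrame(all_rows),
                        out_dir / "surrogate_episodes.csv")
        print(f"arm {arm}: {len(all_rows)} rows total", flush=True)
    df = pd.DataFrame(all_rows)
    ep = df[df.outcome == "episode"]
    summary = {"episodes_per_arm":
               ep.groupby("arm").size().to_dict(),
               "mean_duration_ms":
               ep.groupby("arm").duration_ms.mean().to_dict(),
               "max_filaments":
               ep.groupby("arm").max_filaments.max().to_dict()}

    # vulnerable-window check: the hyperpolarizing clamp should not shrink
    # (and typically widens) the set of coupling intervals that induce
    # reentry; compared on the combined arm at one location
    widths = {}
    for use_clamp in (True, False):
        res = scan_initiations(
            dom0, base, {"west": locations["west"]},
            remodeling_levels=[(1.0, 0.5)],
            coupling_intervals=np.arange(150.0, 301.0, 10.0),
            cap=2000.0, use_clamp=use_clamp,
            seed=seed_for(seed, "scan", 1))
        widths[use_clamp] = sum(r["outcome"] == "episode" for r in res)
    summary["vulnerable_cis_with_clamp"] = widths[True]
    summary["vulnerable_cis_without_clamp"] = widths[False]
    return summary


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--mode", choices=["ring", "surrogate"], default="ring")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("runs/scan"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    if args.mode == "ring":
        summary = ring_study(args.out_dir, args.seed)
    else:
        summary = surrogate_study(args.out_dir, args.seed)
    (args.out_dir / f"{args.mode}_summary.json").write_text(
        json.dumps(summary, indent=1, default=float))
    print(json.dumps(summary, indent=1, default=float))


if __name__ == "__main__":
    main()
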