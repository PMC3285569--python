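# atriasim

Monodomain simulation of human atrial tissue for studying how
**electrical** and **structural remodeling** perpetuate reentrant
arrhythmias (atrial fibrillation / flutter). The package is aimed at
computational electrophysiologists who want a self-contained, desk-scale
test bench for the wavelength hypothesis: remodeling shortens the atrial
wavelength WL = APD × CV — electrical remodeling mostly by shortening the
action potential duration (APD), structural remodeling mostly by slowing
conduction (CV) — and shorter wavelengths let reentry persist.

## What is inside

- **Cell model** — the Courtemanche–Ramirez–Nattel human atrial action
  potential with g_K1 × 1.75 and fixed [K+]i = 139.0 mM, [Na+]i = 11.2 mM;
  graded chronic-AF electrical remodeling
  (I_CaL −70%, I_to −50%, I_Kur −50% at the full level, linearly
  downscaled by a fraction f_E).
- **Tissue solver** — explicit monodomain finite differences
  (Δx = 0.025 cm, Δt = 0.01 ms, operator splitting, adaptive sub-stepping
  of the stiff kinetics, no-flux boundaries, heterogeneous diffusion with
  harmonic-mean interfaces).
- **Synthetic geometries** — strands, sheets, annuli (anchored-reentry
  rings), and a 7.5 cm two-region atrial surrogate with obstacles and
  fast (120 cm/s) / bulk (65 cm/s) / slow (36 cm/s) conduction classes;
  structural remodeling as a uniform diffusion scale-down
  (s ∈ {1, 0.83, 0.70, 0.5}) and an optional diffuse-fibrosis variant.
- **Protocols** — periodic pacing with steady-state and alternans
  detection, S1–S2 effective refractory period (ERP), cross-gradient
  reentry initiation with a hyperpolarizing clamp and coupling-interval
  scans, and wrapped-pulse ring initiation.
- **Analyses** — APD/DI from −70 mV crossings, CV fits, CV/APD
  restitution curves, wavelength estimation, filament detection from
  −30 mV isoline crossings 2 ms apart with k-means counting, episode
  duration/period, and dominant-wave (≥ 5 rotations) classification with
  obstacle anchoring and chirality.

See `docs/methods.md` for the model equations' provenance, numerical
choices and limitations.

## Worked example

Steady APD of a paced 6 cm strand, with and without full electrical
remodeling:

```python
from atriasim import (make_cable, make_baseline_params,
                      apply_electrical_remodeling, periodic_pacing)

base = make_baseline_params()            # g_K1 x1.75, fixed K_i/Na_i
full = apply_electrical_remodeling(base, 1.0)

for name, pars in [("baseline", base), ("remodeled", full)]:
    res = periodic_pacing(make_cable(240, "bulk"), pars,
                          cycle_length=1000.0, until_steady=True)
    print(f"{name}: APD = {res.steady_apd:.1f} ms, "
          f"CV = {res.cv * 1000:.1f} cm/s")
```

prints

```
baseline: APD = 244.4 ms, CV = 65.0 cm/s
remodeled: APD = 149.6 ms, CV = 64.8 cm/s
```

— electrical remodeling shortens the strand APD by ~95 ms at 1 Hz while
leaving conduction velocity untouched, so the wavelength falls from
≈ 15.9 cm to ≈ 9.7 cm. Structural remodeling does the converse
(`apply_structural_remodeling(domain, 0.5)` halves every diffusion
coefficient, scaling CV by √0.5 ≈ 0.71 and leaving APD within 2%).

Anchored reentry on an annulus then shows the consequence directly: a
wrapped-pulse wave on a ring whose path length exceeds the local
wavelength circulates indefinitely, and dies otherwise:

```python
from atriasim import (make_annulus, apply_structural_remodeling,
                      ring_pulse_field, run, SolverConfig)

dom = apply_structural_remodeling(make_annulus(r_outer=1.37), 0.5)
init = ring_pulse_field(dom, full)       # combined remodeling
print(f"wavelength {init.wavelength:.1f} cm on a "
      f"{dom.obstacles[0]['mid_path_cm']:.1f} cm path")
# -> wavelength 4.7 cm on a 8.1 cm path  (reentry sustains)
```

The CLI wraps the common workflows
(`atriasim simulate|restitution|scan|analyze config.yaml`), and
`scripts/run_surrogate_scan.py` drives the long-running episode studies
(annulus-size series; full 300×300 surrogate coupling-interval scans).

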