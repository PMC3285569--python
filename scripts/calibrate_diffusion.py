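#!/usr/bin/env python
"""Recalibrate the per-region diffusion coefficients.

The three tissue classes must conduct plane waves at 120 / 65 / 36 cm/s
(fast pathway / bulk / slow isthmus) at sinus-rate pacing on the reference
grid (dx = 0.025 cm, dt = 0.01 ms). Conduction velocity scales as the
square root of the diffusion coefficient, so a secant iteration on
D -> CV^2 converges in two or three cable simulations per region.

The resulting values are the REGION_D constants in atriasim.geometry;
rerun this script after any change to the cell model or solver numerics.
"""

import numpy as np

from atriasim import make_cable, make_baseline_params, REGION_CV, REGION_D
from atriasim.geometry import LABEL_NAMES
from atriasim.protocols import periodic_pacing


def cable_cv(D: float, cycle_length: float = 1000.0) -> float:
    dom = make_cable(240, "bulk")
    dom.D[:] = D
    res = periodic_pacing(dom, make_baseline_params(), cycle_length,
                          n_beats=4)
    if not np.isfinite(res.cv):
        raise RuntimeError(f"CV measurement failed at D = {D}")
    return res.cv


def calibrate(target_cv: float, d0: float, tol: float = 0.002) -> float:
    d = d0
    for _ in range(6):
        cv = cable_cv(d)
        err = cv / target_cv - 1.0
        print(f"  D = {d:.4e}  CV = {cv * 1000:6.2f} cm/s  err = {err:+.3%}")
        if abs(err) < tol:
            return d
        d *= (target_cv / cv) ** 2
    return d


def main() -> None:
    for label, cv in REGION_CV.items():
        print(f"{LABEL_NAMES[label]} (target {cv * 1000:.0f} cm/s):")
        d = calibrate(cv, REGION_D[label])
        print(f"  -> REGION_D[{LABEL_NAMES[label].upper()}] = {d:.4e}")


if __name__ == "__main__":
    main()
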