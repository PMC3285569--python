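# Methods

## Model

`atriasim` simulates human atrial tissue electrophysiology with the
monodomain reaction–diffusion equation

    ∂V/∂t = ∇·(D ∇V) − I_ion(V, y)/C_m + I_stim,

membrane kinetics given by the Courtemanche–Ramirez–Nattel (CRN) human
atrial ionic model (12 sarcolemmal currents, 15 gating variables, a
three-compartment calcium subsystem). Two standing modifications are
applied everywhere:

- the inward-rectifier conductance g_K1 is scaled by **1.75**, which pulls
  the resting potential (−83.7 mV) and action potential duration closer to
  experimental atrial values;
- the intracellular concentrations are **fixed** at [K+]i = 139.0 mM and
  [Na+]i = 11.2 mM (their time derivatives are forced to zero), removing
  the slow ionic drift that otherwise confounds minutes-long simulations.
  The fixed values equal the CRN resting state, so the modification is
  exact at rest.

The transcription of the CRN equations was validated against the source
model's published single-cell fingerprints with g_K1 unscaled: resting
potential −81.20 mV (published −81.2), maximal upstroke velocity
219 mV/ms (≈216), action potential amplitude 105.7 mV (≈105), and
APD(−70 mV) = 291 ms against a published APD90 near 300 ms obtained under
a different stimulus convention and free-running concentrations.

### Remodeling interventions

*Electrical remodeling* (chronic-AF ion-channel changes) is a graded
conductance scaling controlled by a fraction f_E ∈ [0, 1]:
g_CaL × (1 − 0.70 f_E), g_to × (1 − 0.50 f_E), g_Kur × (1 − 0.50 f_E).
f_E = 1 is the full chronic-AF phenotype; intermediate fractions scale the
percentage changes linearly.

*Structural remodeling* (gap-junctional uncoupling / diffuse fibrosis) is
a uniform scale-down of every diffusion coefficient by s ∈ (0, 1], with
s = 0.5 the maximal level and 0.83 / 0.70 the intermediate levels used in
sweeps. An alternative diffuse-fibrosis variant inactivates a random node
fraction (sealed no-flux faces); electrically isolated islands created by
the random draw are pruned, and a draw that strands more than 2% of nodes
is rejected as disconnecting.

## Numerics

Operator splitting per outer step of **Δt = 0.01 ms** on grids with
**Δx = 0.025 cm**: an explicit forward-Euler diffusion update (3/5/7-point
Laplacian in 1/2/3 dimensions, harmonic-mean face coefficients at region
interfaces, mirrored-ghost no-flux boundaries at the domain edge and at
inactive nodes), then the cell reaction. Either operator order is
supported; the two orders change strand APD by < 1 ms (tested).

The reaction step integrates the stiff CRN kinetics with **adaptive
forward-Euler sub-stepping**: sub-steps are sized so each voltage
increment stays below 0.2 mV, bounded to [10⁻⁴, 10⁻²] ms. In tissue, a
vectorized single-sub-step update handles every node whose increment is
already below the cap (the overwhelming majority) and the wavefront nodes
are re-integrated adaptively. All purely voltage-dependent rate functions
are pre-tabulated on a 0.01 mV grid and linearly interpolated; the exact
right-hand side remains available and is the reference for the
integration-accuracy oracle (adaptive trajectory within 0.1 mV of a
fixed 1 µs forward-Euler reference over a full action potential; APD
moves < 1 ms when the sub-step cap is halved).

Explicit stability is checked at solver construction
(Δt · max_i Σ_k w_ik ≤ 1 with w the face weights); the default Δt is
~16× below the bound for bulk tissue.

Initial conditions are the quiescent steady state obtained by 100 s of
unstimulated relaxation from the published CRN state, cached per
parameter set. Stimuli are 80 A/F for 1 ms (the printed "nA/µF" is read
as the model's current-per-capacitance convention; at magnitude 80 with
1 ms duration the distinction is immaterial for capture).

### Diffusion calibration

The three conduction classes target plane-wave velocities of 120 (fast
pathway), 65 (bulk), and 36 cm/s (slow isthmus) at sinus-rate pacing.
Since CV ∝ √D, a secant iteration on cable simulations fixes the
coefficients once (`scripts/calibrate_diffusion.py`):
D = 5.98 × 10⁻³ / 1.94 × 10⁻³ / 7.38 × 10⁻⁴ cm²/ms, each within 0.1% of
target.

At Δx = 0.025 cm the sodium upstroke spans only a few nodes, so slow
fronts are mildly lattice-pinned: the first Δx halving raises bulk CV by
~6%, the next by ~1% (converged), and the continuum √D scaling of CV
holds to 0.4% on the converged mesh but degrades to −6% at s = 0.5 on the
production grid. Calibrating each region's D to its target CV *on the
production grid* absorbs this discretization bias, which is why
calibration rather than continuum scaling sets the coefficients; the √D
law is therefore verified on the mesh-converged grid (Δx = 0.0125 cm).

## Measurements

- **APD / DI**: −70 mV threshold crossings, linearly interpolated;
  APD from upstroke to repolarization crossing, DI from repolarization to
  the next upstroke.
- **CV**: inverse slope of a least-squares fit of activation time vs
  distance along ≥ 5 probe nodes in mid-strand; non-monotone activation is
  rejected as non-planar.
- **Steady state**: pacing trains extend until the beat sequence is
  stationary — consecutive beats within 1 ms, or a repeating 2:2
  (alternans) pattern. The baseline model alternates at intermediate rates
  (e.g. 239/166 ms at a 400 ms cycle), a direct expression of its steep
  APD restitution; full electrical remodeling abolishes the alternans.
- **ERP**: S1–S2 at 1 ms resolution (bisection, validated against an
  exhaustive scan); the propagation criterion is an upstroke at a probe
  0.5 cm beyond the stimulus edge. The APD paired with ERP is that of the
  final S1 beat itself, measured in a dedicated S1-only run, so the pair
  describes the same action potential even under alternans.
- **Restitution curves**: steady-state (DI, CV) and (DI, APD) samples over
  a cycle-length sweep (default 1000–200 ms); alternans contributes both
  branches; samples whose closing activation interval deviates from the
  cycle length by > 5 ms (partial capture) are dropped, as are
  non-stationary cycle lengths. The interpolant is piecewise-linear on an
  isotonic (pool-adjacent-violators) fit — monotone by construction, flat
  extrapolation outside the sampled DI range, flagged.
- **Wavelength**: WL = APD × CV(DI), reading CV off the restitution curve
  at the measured DI. ERP-based wavelength would be 4–10% larger (the
  measured ERP−APD offset is 13–15 ms across the tested grid).

## Reentry machinery

- **Initiation (2D sheets/surrogates)**: cross-gradient protocol — a plane
  S1 wave, a premature S2 over a transverse quarter-domain block at a
  coupling interval measured from the S1 upstroke at the S2 centroid,
  optionally followed by a hyperpolarizing clamp (−80 mV, 1 ms) on the S2
  region 30 ms after S2. Coupling-interval scans step by 10 ms.
- **Initiation (annuli)**: a wrapped traveling-pulse initial condition.
  A strand matching the ring's diffusion is paced for 5 beats at the
  ring's natural period (mid-path length / CV) and the final wave's state
  profile is wrapped onto the ring by arc length, with the leading quarter
  at rest. Rate-matched APD and CV measured on that strand give each
  episode its own wavelength estimate. Whether the anchored wave then
  persists is wavelength-versus-path-length physics, uncontaminated by
  initiation transients.
- **Filaments**: intersections of the −30 mV isolines of two snapshots
  2 ms apart, restricted to the depolarizing branch of each contour (the
  wave tip is a stagnation point, so the branch filter keeps a ±1 mV
  tolerance band around it). Counting merges tip points agglomeratively at
  a 0.5 cm radius — mathematically the connected components of the
  radius graph — and refines assignments by k-means with that k. The
  counter is validated against a topological-charge (phase-singularity)
  oracle on plane-wave, single-spiral and figure-of-eight fields and
  against a connected-components oracle on random point sets.
- **Episode summaries**: duration to the last −70 mV upstroke at any
  recording site (early stop once the whole field stays below −60 mV for
  200 ms; both thresholds are configuration values); sustained means the
  episode reached the cap; mean period is the mean inter-activation
  interval over 16 recording sites (farthest-point sampled, seeded),
  skipping the first two activations per site; dominant waves persist
  ≥ 5 rotations — free tip tracks linked frame-to-frame by nearest
  neighbour (1 cm gate, rotations counted as net phase progression of the
  tip about the track mean), or anchored circulation detected from the
  monotone phase delay of activations around an obstacle's rim summing to
  about one period per lap (chirality from the delay's sign).

## Synthetic geometries and the desk-scale episode scan

The anatomically-derived whole-atria geometry that motivates this package
is not distributable, so all domains are synthetic: homogeneous strands,
labelled sheets, a 7.5 × 7.5 cm two-region "atrial surrogate" (two large
annulus-analogue holes, venous-ostium holes, a slow isthmus bridging the
large holes, a fast strip), and annuli (single-obstacle rings).

Whole-atria episode scans are hours-to-days of compute
(`scripts/run_surrogate_scan.py` runs them at full scale). The test suite
instead uses an **annulus-size series**: four ring path lengths (6.9, 8.1,
9.4, 10.7 cm) × four remodeling arms (baseline; f_E = 1; s = 0.5; both),
one episode each, capped at 1.2 s. The sizes were chosen once so that the
series brackets the arms' sustainability thresholds — baseline wavelength
(≈15 cm at sinus rate) exceeds every path, the combined-arm wavelength
(≈4–5 cm) is below every path, and the single-intervention thresholds fall
inside the series. This reproduces, at desk scale, the study's core
structure: episode duration grows with either intervention, grows most
with both, and rank-correlates negatively with the measured wavelength.

What the desk-scale scan does *not* show: free-wave fragmentation and
filament-count statistics (a ring cannot host free spirals, and its
anchored wave has no filament), multi-wave competition between anatomical
anchors, or episode durations beyond the cap. Those require the
full-surrogate scan in `scripts/run_surrogate_scan.py` (structural arms
there produce transient wavebreaks whose filament counts can be compared
with the electrical arms at matched wavelength).

## Known limitations

- The strand APDs of the modified model run ≈ 7–12% longer than published
  reference values for this preparation (244.4 / 149.6 / 150.6 / 115.4 ms
  here vs 228 / 135 / 134 / 103 ms at baseline-1 Hz / remodeled-1 Hz /
  baseline-5 Hz / remodeled-5 Hz), a nearly uniform offset; the
  remodeling *differences* agree closely (−94.8 vs −93 ms at 1 Hz; −35.2
  vs −31 ms at 5 Hz). The implementation reproduces the published CRN
  single-cell fingerprints and converges under Δt/Δx refinement, so the
  offset is attributed to undocumented implementation details of the
  codes behind the reference values; no parameter was adjusted to chase
  them.
- No anisotropy, no fiber orientation, no regional electrophysiological
  heterogeneity beyond the three conduction classes, no contractile or
  calcium-handling remodeling, no fibroblast effects on repolarization.
- Tissue is isothermal CRN everywhere; alternative atrial cell models are
  out of scope.
- The monodomain description omits bidomain/bath-loading effects.
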