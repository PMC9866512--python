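# Methods

`cntwater` post-processes molecular-dynamics trajectories of water confined
in cylindrical channels (carbon nanotubes and similar pores) and extracts
the quantities that characterise confined-water structure and dynamics:
radial density and coaxial-shell structure, lateral pair correlations,
hydrogen-bond statistics and lifetimes, the axial mean-squared displacement
with its anomalous-diffusion exponent and axial diffusion coefficient, and
the temperature dependence of transport (Arrhenius fits and the
fragile-to-strong crossover).  Every estimator is validated against
built-in synthetic generators whose ground truth is known in closed form.

Units are fixed throughout: Å for length, ps for time, K for temperature,
kJ/mol for energies (kB = 0.0083145 kJ/(mol·K)); diffusion coefficients
are reported in 10⁻⁵ cm²/s (1 Å²/ps = 10 × 10⁻⁵ cm²/s).

## Geometry and conventions

A channel is a `TubeGeometry`: a point on the axis, a unit axis direction,
a radius and an axial interval.  The diameter of an (n, m) carbon nanotube
follows from its chirality, d = (√3/π)·a·√(n² + m² + nm), with
a = 1.418 Å the C–C bond length; armchair (6,6)/(22,22)/(37,37) tubes give
8.12, 29.79 and 50.10 Å (0.8, 3 and 5 nm).

A water molecule is represented by its oxygen atom in every analysis.
Grouping assigns each H to its nearest O in frame 0 and requires exactly
two H within 1.2 Å per O.  "Inside the channel" means strict r < radius
with inclusive z bounds (the r = radius boundary is a measure-zero set;
counting it as outside is documented behaviour).  The axis is taken from
the configuration, never inferred silently; `fit_axis` is an explicit
helper that fits the principal axis of the wall atoms.  Trajectories are
assumed unwrapped along z within each residency interval; the residency
table records the maximal frame intervals a molecule spends inside the
channel, and displacement statistics never cross a residency gap.

## Structure

*Radial density*: per-annulus mean molecule count divided by the annulus
volume π(r₂²−r₁²)·L_z (default bin 0.2 Å).  The profile satisfies
Σ density·volume = mean in-channel count exactly; this identity is tested.

*Shell partitioning*: coaxial shells are separated at minima of the
Savitzky–Golay-smoothed profile (window 5 bins, order 2) between
successive peaks.  Peaks must be prominent by ≥ 10 % of the density range
(histogram minima and shallow maxima are noise-dominated), and the cut is
placed at the centre of the minimal plateau, since the valley between
well-separated shells is flat near zero.  Explicit boundaries pass through
unchanged.

*Lateral RDF*: pair distances are projected on the channel cross-section;
both molecules must be in-channel in the evaluated frame.  The histogram
is normalised by the ideal uniform filling of the cross-section disk, so a
uniform system gives g ≈ 1 at all r.  The finite-disk pair-distance
distribution is evaluated from the closed-form disk line-picking density
(deterministic and exact); a seeded Monte Carlo estimator of the same
distribution is kept as an option and cross-checked against the closed
form in the tests.  Peak *positions* — the physically interpreted readout,
first peak near 2.8 Å — are invariant to the normalisation choice.
Default RDF bin 0.05 Å.

*Transition detection*: the first-peak height (maximum of the 3-bin
smoothed g(r) at r < 3.5 Å) is tracked across temperatures; the step with
the maximal relative drop is reported as a transition interval when the
drop is ≥ 0.15 (default).  The threshold separates a sharp first-order
signature from gradual thermal decay (a few per cent per 10 K).

## Hydrogen bonds

Geometric criteria, both inclusive: |r_OO| ≤ 3.50 Å and the donor angle
(between O–H and O···O at the donor oxygen) ≤ 30°.  An alternative
convention measuring the deviation of the O–H···O angle from linearity at
the H is available as a switch.  Donor→acceptor pairs are directional.

The intermittent autocorrelation C(t) = ⟨h(τ)h(τ+t)⟩/⟨h(τ)⟩ pools all
time origins and pairs; rebinding after breakage counts.  C(t) is fitted
with C(t) ≈ A₁e^(−t/τ₁) + (1−A₁)e^(−t/τ₂) by bound-constrained least
squares (A₁ ∈ [0,1], τ > 0), multi-started from five log-spaced τ guesses,
with canonical ordering τ₁ ≤ τ₂.  Only lags with C > 0.01 enter the fit;
the noise tail otherwise destabilises τ₂.  The lifetime is the
amplitude-weighted mean τ_HB = A₁τ₁ + (1−A₁)τ₂.

Per-shell lifetimes attribute each bond to the shell of its donor's
time-averaged radius (instantaneous attribution is a switch), fit each
shell's own C(t), and report a standard error over five time-block
estimates.  Shells with fewer than 10 ever-bonded pairs are flagged
unreliable.

## Axial diffusion

The axial MSD uses multiple time origins inside fixed windows (defaults
from common practice with open-ended channels: 1 ns windows at 1 ps
sampling, up to 50 windows; non-overlapping first, half-overlapping when
the trajectory is short).  Only origin/lag pairs lying inside one
contiguous residency span contribute.  The per-window all-origin average
is computed by the FFT autocorrelation identity (O(n log n)).  Optional
per-frame centre-of-mass removal (`remove_com`) implements standard drift
removal; for a finite periodic system it strips the spurious 2(D/N)t
centre-of-mass term.

The long-time law MSD = 2·d·D_z·t^α is applied with d = 1: the MSD is
purely axial, so one dimension is the consistent choice.  Regimes are
identified by a continuous piecewise power law in log-log coordinates:
hinge basis functions give continuity, breakpoints are scanned
exhaustively over a log-spaced candidate grid, and the model order (0–3
breakpoints) is selected by small-sample-corrected AIC.  Fit weights are
sample counts × local log-spacing, so precision sets the weighting while
each log-time interval contributes by its extent.  Two numerical guards
matter in practice and are defaults: every segment must span ≥ 0.3
decades (long-lag MSD values are strongly correlated; without a span
floor a short tail segment fits pure noise), and adjacent segments with
slope difference < 0.02 are merged (a noiseless knee otherwise splits
into duplicate-slope segments).  Because a piecewise-linear model averages
any residual smooth crossover curvature into its last segment, the
reported long-time exponent is re-estimated over the final half-decade of
lags at full lag resolution; for clean power laws this is identical to
the hinge slope, while for slowly crossing-over curves (single-file
input) it removes an upward bias of about +0.03.

Mode labels interpolate the anchor regimes α = 0.5 (single-file), 1
(Fickian) and 2 (ballistic): single_file < 0.6 ≤ subdiffusive < 0.9 ≤
fickian ≤ 1.1 < superdiffusive < 1.8 ≤ ballistic; thresholds are
configurable.  D_z comes from the long-time prefactor/(2d); when the
long-time segment classifies as Fickian, the prefactor is re-estimated by
a count-weighted linear regression of MSD on t over that segment (the
free-exponent prefactor trades off against α and is several times
noisier).  Non-Fickian long-time segments still yield a value, flagged
with a caveat.  Per-shell D_z admits a molecule-window into a shell when
the molecule is resident for the whole window and spends ≥ 80 % of it in
that shell (the 80 % occupancy rule applied at window granularity, which
vectorises cleanly).

## Thermal analysis

`arrhenius_fit` regresses ln D on 1/T; ΔU = −slope·kB.  The
fragile-to-strong crossover is formalised as a continuous two-segment
linear fit in Arrhenius coordinates with the hinge scanned over interior
data points (≥ 3 per side).  The verdict is "crossover" only when the
two-segment model beats the single line by corrected AIC *and* the slope
difference exceeds its t-based 95 % uncertainty; this conjunction holds
the false-positive rate on pure-Arrhenius input with 5 % noise at ~5 %
(measured over 100 replicates).  T0 is the hinge temperature, and an
interval is reported by collecting hinges within 2 AICc units of the
optimum — the criterion profile is often flat across adjacent grid
points, which is exactly when a temperature *range* is the honest answer.
A hinge at the edge of the admissible range is unidentifiable: verdict
"none" with a boundary warning.  A Vogel–Fulcher fit of the fragile
branch is provided for characterisation but takes no part in the verdict,
which rests on the slope change in the Arrhenius plot.

## Synthetic generators

The generators emulate the statistical structure the estimators assume —
not water physics.  All are bit-reproducible for a fixed seed and return
ground-truth records sufficient to score every downstream estimate.

*Axial trajectories* (`gen_axial`): molecules sit on coaxial shells
(target radius, Gaussian radial jitter per frame, static azimuth) and
move axially in one of three modes.  Fickian: independent Gaussian
increments of variance 2·D·dt.  Ballistic: constant per-molecule
velocities ~ N(0, v_σ²).  Single-file: independent Brownian walkers on a
periodic line of length N/ρ, relabelled so trajectories never cross —
implemented exactly and fully vectorised by a winding-number identity
(tagged position = order statistic of the wrapped walkers plus L × a
winding term, with the cyclic label shift equal to the net
boundary-crossing count Σ⌊y/L⌋).  The tagged-particle MSD approaches
(2/ρ)√(Dt/π); convergence is slow (relative correction ~ 1/(ρ√(πDt)),
about 8 % at t = 500 ps for ρ = 0.5, D = 0.1), which the asymptote test
tolerances reflect.  Azimuths follow a golden-angle sequence over the
axial rank within each shell so that molecules close in z at frame 0 are
far apart on the shell circle and the O–H grouping of the start
configuration is always unambiguous; each molecule carries two dummy
hydrogens at +0.30/+0.60 Å along z so water-system construction works.
Hydrogen-bond analyses are not meaningful on this output.

*Bond processes* (`gen_bond_process`): each pair starts bonded and breaks
permanently with exact geometric survival (per-frame factor e^(−dt/τ) of
its population).  The headline parameter A₁ is the *amplitude* of the
fast component in the measured all-origin autocorrelation — the quantity
a biexponential fit reports.  Because an all-origin estimator weights
each population by its expected bonded duration, the population
assignment probability is q₁ ∝ A₁(1−e^(−dt/τ₁)); with that choice the
estimator's expectation is A₁e^(−t/τ₁) + (1−A₁)e^(−t/τ₂) up to
exponentially small window-edge factors, and the exact discrete-time
expectation is available as `bond_process_acf` for σ-level checks.  A
`weighting="population"` switch makes A₁ a plain population fraction
instead.

*D(T) series* (`gen_arrhenius_series`): exactly Arrhenius below T0 and a
Vogel–Fulcher branch above it, joined continuously at T0 (a kink, not a
jump), with optional lognormal relative noise.  Defaults (ΔU = 25 kJ/mol,
B = 330 K, T_vf = 150 K) give a low-T apparent activation energy about
twice the high-T one near the crossover — a clearly detectable but not
caricatured kink.

What the generators do *not* emulate: hydrogen-bond geometry dynamics in
`gen_axial` (its H atoms are placeholders), force-field energetics,
density layering that responds to temperature, or coupling between shell
occupancy and axial mobility.  Passing recovery tests therefore
demonstrates estimator correctness under the stated statistical models,
not agreement with any particular simulation or experiment.

## Problem sizes and determinism

Recovery experiments run at desk scale: 200 molecules × 10⁵ frames for
the single-file exponent (analysed in 1 ns windows, up to 100 windows,
with centre-of-mass removal; three generator replicates averaged in the
acceptance script), 5 × 10⁴ frames Fickian, 10⁴ frames ballistic, 10⁴
bond pairs, 14-point temperature grids.  Every random draw goes through
`numpy.random.default_rng` with an explicit seed; identical seeds give
byte-identical generator output and pipeline tables.

## Known limitations

- The RDF normalisation assumes the in-channel cross-section is a disk of
  the tube radius; strongly layered systems keep correct peak positions
  but g-scale values mix layering with the uniform reference.
- The single-file asymptote on a finite ring saturates at long times; MSD
  windows much longer than ~L²ρ²/D leave the validated regime.
- Crossover detection models the fragile branch as locally linear in
  1/T; strongly curved branches widen the reported T0 interval.
- Per-shell attribution (time-averaged donor radius; 80 % window
  occupancy) is one defensible formalisation; switches expose the
  instantaneous alternatives but Table-style per-shell numbers depend
  mildly on the choice.
- DCD reading requires the companion one-column element topology; PSF or
  force-field topologies are out of scope.
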