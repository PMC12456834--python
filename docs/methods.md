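# Methods

## Model

Two axillary buds on a 2-node stem explant compete to establish canalized
auxin transport into the shared stem. The state is (E, F, N, M): auxin
efflux and length of the top and bottom bud. Efflux dynamics combine a
basal rate `v0`, a Hill-type self-reinforcing feedback — efflux promotes
its own efflux, the core of canalization — and linear removal `mu`:

    dE/dt = v0 + v (S E)^n / ((S E)^n + (D (E+F) + K)^n) - mu E

(and symmetrically for F). Mutual inhibition is indirect: both buds raise
the stem sink term `D (E+F)`, which lifts the feedback threshold of both.
Growth is a saturating readout of efflux, `dN/dt = E^m / (Q^m + E^m)`, so
lengths are nondecreasing and bounded by one length unit per time step.
Time is measured in model "time steps"; no calibration of time steps to
experimental days is attempted — simulation/data comparisons are
trend-level (80–120 steps against 10–19 measured days).

Assumptions inherited from the underlying biology: bud auxin supply is
homeostatic (folded into constant coefficients), the explant is
symmetric apart from noise, and all spatial transport detail is abstracted
into the scalar efflux per bud.

## Parameters and calibration

Only (v0, mu) are swept in the analyses; the remaining constants define
the "calibrated slice". Defaults:

| parameter | value  | units / meaning |
|-----------|--------|-----------------|
| v0        | 0.09   | basal efflux rate (efflux / step); BRC1-repressed axis |
| v         | 1.0    | maximum feedback-driven efflux rate |
| S         | 1.5    | feedback efficiency (dimensionless) |
| n         | 4      | feedback Hill exponent |
| K         | 0.1125 | feedback threshold offset (efflux units) |
| D         | 0.45   | stem-sink coupling (dimensionless) |
| mu        | 0.6    | efflux decay rate (/step); PIN1-removal axis |
| Q         | 0.28   | growth half-saturation (efflux units) |
| m         | 10     | growth Hill exponent |
| eta       | 0.03   | noise scale (0 = deterministic) |

Slice axes: v0 in [0.005, 0.14], mu in [0.2, 6.0].

The calibration was found by a numerical search over (S, D, K, n) requiring,
at once: (i) the (v0, mu) plane shows the region sequence both-or-one ->
only-one -> one-or-neither -> neither as mu rises and v0 falls, with the
all-four-outcomes pocket at low v0; (ii) the six-class taxonomy is complete
across the slice plus ±50% single-parameter variants; (iii) the
deterministic canalization switch time strictly decreases across
v0 = 0.01 … 0.09; (iv) under noise, the probability that both buds activate
rises with v0 and falls with mu across the tristable region. One structural
difference from the published maps: with the stem-sink coupling strong
enough to produce an only-one region, the winner bud always retains an
asymmetric partner state at low mu, so a strictly monostable "both" region
does not occur on the base slice itself (it appears under the variants,
e.g. halved D); the "both buds always grow" zone is realized as the
p_both ≈ 1 part of the tristable region, which leaves the outcome gradient
and the genotype story unchanged.

The growth constants (Q, m) were chosen so that suppressed buds (efflux
≤ 0.16 anywhere on the slice) accumulate negligible length over 120 steps
while any state the classifier calls active grows strongly. A side effect
is that growth is near-saturated for all winning buds in the genotype
panel's mu range, so predicted maximum-rate differences across the panel
are small; the full-slice maximum-rate heatmap still declines at high mu.

## Numerics

Integration uses a drift-implicit theta scheme with trapezoidal drift
(theta = 1/2): each step solves the two-variable implicit system with a
damped Newton iteration (analytic Jacobian), and the chemical-Langevin
noise increment is explicit, built from the two reaction channels per bud
(production a = v0 + feedback, decay b = mu x):

    dx = (a - b) dt + eta (sqrt(a) dW1 - sqrt(b) dW2)

The trapezoidal drift makes the zero-noise limit second-order accurate,
which is what lets deterministic runs be verified against a high-accuracy
Runge-Kutta reference to 1e-5 relative error at dt = 0.005; a backward
(theta = 1) drift is first-order and cannot reach that tolerance at
practical step counts. Noise enters the efflux equations only; bud lengths
integrate the growth Hill of the updated efflux with a trapezoidal rule
and are exactly nondecreasing. Efflux values driven below zero by a noise
increment are clamped to zero and the events counted. Default dt = 0.1,
set by the step-halving criterion (halving dt moves 120-step deterministic
endpoints by < 1e-4 relative). Ensembles integrate all members (and, for
maps, all cells) in one vectorized sweep; per-row Newton updates freeze on
convergence so results are independent of batch composition. Replicate r
of map cell (i, j) uses seed `base_seed + r + n_sims (j + i n_cols)`.

## Steady states and classification

Fixed points of the efflux subsystem exploit its structure: once the stem
sink term `T = D (E+F) + K` is fixed, both coordinates solve the same
univariate polynomial (for integer n), so candidates come from polynomial
roots along the symmetric line plus a scan over T, each pair polished by a
damped Newton iteration on the full 2-D system; a lattice of extra starts
covers non-integer exponents. Residual tolerance 1e-10, deduplication
radius 1e-6, swap closure enforced. Stability is read from the analytic
Jacobian's eigenvalues (stable iff all real parts < -1e-8; saddles and
marginal points are "unstable"). Two efflux thresholds drive the six-class
table: a symmetric stable state at/above 0.4 counts as "both activate"
when it is the only attractor (class 1 vs 6), and at/above 0.24 as an
active coexisting state when an asymmetric pair is present (class 2 vs 4).
Configurations outside the table raise an explicit error; map builders
record such cells in a failure mask and repair them from neighbors
(identical neighbors copy, otherwise continuous channels take the mean and
class ids the neighbor value nearest the mean). Boundary pixels are cells
with more than one of their 8 neighbors (configurable to 4) differing in
stable-state count.

## Trace metrics

One extractor serves experimental-format (mm, days) and simulated traces:
a centered moving average (default window 3 samples, odd) followed by
centered differences. A bud is active if its smoothed rate strictly
exceeds 2.5 mm/day (experimental) or 0.02 length units/step (simulated);
lag is the time from trace start to the first crossing; the maximum growth
rate is the series maximum; the RGI of an active explant is the longest
final length over the summed final lengths. Simulated outcomes use the
3x final-length dominance rule, with "both" additionally requiring both
finals above 11x the initial length (a pair of equally dormant buds also
has ratio 1). Simulated trajectories are subsampled to unit time steps
before extraction, mirroring daily measurements. This derivative-based
extractor replaces parametric growth-curve fitting throughout; its
accuracy on known ground truth (median lag error well under a day, median
relative max-rate error under 10% across lags 1-8 d and rates 3-12 mm/day
at 0.2 mm noise) is verified in the test suite, with the caveat that daily
sampling systematically underestimates the peak rate of fast buds.

## Synthetic data

The generator emulates 2-node assays: per explant an outcome (both / one /
neither) is drawn from archetype probabilities; active buds are flat at
the initial length until a drawn switch day, then follow a logistic
segment anchored at 20% of its rise on the switch day, with maximum slope
equal to the drawn rate, toward a plateau; inhibited buds creep at a
residual rate; i.i.d. Gaussian noise is added and lengths truncated at 0.
The 20% anchor makes the switch day the identifiable ground truth: with
zero noise the extractor's threshold crossing lands exactly on it. An
optional stop-and-switch pattern caps the dominant bud early and activates
the other. What the generator does not emulate: correlated (random-walk)
measurement error, explant dropout dynamics, within-explant correlation of
lag and rate, or any mechanistic hormone signaling — so passing recovery
tests demonstrate extractor correctness under the stated noise model, not
robustness to every artifact of real measurements.

## Genotype placement

A genotype/treatment is placed on the (v0, mu) outcome map in the spirit of
the published data fit: match regions are the cells whose outcome fractions
lie within a total-variation tolerance (default twice the pooled binomial
standard error) of the observed fractions; biological knowledge enters as
equality groups (shared rows/columns) and strict orderings between bar
positions. Because outcome fractions are constant along their own level
curves, fractions alone cannot identify the position along such a curve;
the placement cost is therefore a statistical misfit — a multinomial
likelihood term n·KL(observed ‖ modeled), with the map's fractions smoothed
by a half-count pseudo-count so one flipped run out of n_sims cannot
dominate — plus, when lag / max-rate summaries are observed, squared
standardized mismatches against the corresponding heatmaps (median
statistic; the mean lag has a heavy right tail). Metric standard errors
combine the observation's and the map cell's, floored at half the
unit-step quantization for lag. The joint bar optimization alternates
exact per-axis dynamic programs over ordered group positions (ties resolve
to the middle of a flat optimum), from two deterministic starts, with an
en-bloc shift polish; each half-step is exact so the objective is
non-increasing and the result is reproducible. Manual bar positions can be
supplied to replicate a hand placement.

The reference panel positions place the brc1brc2-background row at the
steep upper edge of the tristable region (both buds activate on
essentially all explants, as observed for those lines), wild type
mid-region, and the strigolactone treatments / constitutive-signaling
backgrounds at progressively lower v0 and higher mu; along that series the
predicted one-bud frequency and median lag both rise, while mu-only
increases at high v0 shift outcomes with almost no lag change. Reduced-
transport (strigolactone-insensitive PIN1) lines live on a slice with S
lowered by 20%, keeping each background's v0 and taking the receptor
mutant's mu.

## Problem sizes and defaults

Maps default to 100 stochastic runs per multistable cell (50 also used in
places by the published figures; configurable) for 120 time steps. The
test suite runs grids of at most 40x40 and ensembles of at most 200; the
full 159x159 maps are supported through the same configuration and were
exercised during development. The heatmap simulations run 120 steps (one
source gives 12, read as typographic; exposed as configuration).

## Known limitations

* Absolute (v0, mu) placement precision is limited by the outcome-fraction
  gradient (~0.03 per grid cell along v0 at 40x40) against binomial noise
  at n = 100 explants; individual flat-region labels can land a few cells
  off even when the constrained constellation is recovered.
* The six-class table is exhaustive for this calibration, but nothing
  forbids other stable configurations elsewhere in parameter space; they
  raise an explicit classification error rather than being coerced.
* No continuation/bifurcation tracing: region boundaries are detected
  discretely on the grid.
* No spatially resolved canalization; PIN and auxin concentrations are
  folded into the efflux variables.
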