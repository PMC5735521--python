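# Methods

## The timing model

AVT pacing is modelled purely at the timing level. The junctional focus is
a rate source; ventricular events occur at the instantaneous cycle length
CL = 60000/HR ms (the single bpm↔ms constant, defined once in
`device_core`). The inversely connected pacemaker schedules an atrial
stimulus a ventriculoatrial interval (VAI) after each sensed R wave, so the
interval from atrial pacing to the next ventricular sensing is
AP–VS = CL − VAI. All internal arithmetic is unrounded; integer-ms values
are produced only at presentation, rounded half-up, matching how devices
program and clinical tables print intervals.

The device caps the VAI via the maximum tracking rate (MTR) through a
15-row lookup table spanning MTR 90–230 bpm, VAI_max 400–190 ms, shipped as
package data (`data/vai_max_table.csv`) and overridable via config. The
physical device's behaviour for MTR values between the 10-bpm rows is not
documented; the lookup **rounds up** to the next tabulated MTR, returning
the shorter maximum. This is the conservative choice — a programmed VAI
never exceeds a tabulated limit, and it leaves the interval minima of the
M10/M20 recipes (83 and 96 ms) unchanged.

The M10/M20 recipes set MTR = HR + 10 or HR + 20 with the VAI at its
maximum. M20 is unavailable above 210 bpm (device MTR ceiling 230 bpm);
both are unavailable when HR + offset falls below the table (90 bpm).

## Curve analysis

AP–VS(HR) curves are sampled on a uniform grid, by default 10-bpm steps
over 130–220 bpm (M10) and 130–210 bpm (M20). The 10-bpm default matches
the granularity of the lookup table; rates below 130 bpm are excluded from
regression because the VAI_max pins at 400 ms there and the curves plunge.
Regression is ordinary least squares (scipy `linregress`) with R² the
squared Pearson correlation; an independent normal-equations oracle checks
it in the tests.

Gradients are forward finite differences. By default they are taken on the
**integer-ms view** of the curve (`resolution="device"`); an
`resolution="exact"` option differentiates the unrounded samples. The
distinction is substantive: with exact arithmetic the M20 curve rises by
+0.039 ms/bpm between 170 and 180 bpm (112.94 → 113.33 ms), a sub-ms ripple
created by the interaction of the hyperbolic cycle length with the 20-ms
table step, which vanishes at the 1-ms resolution at which intervals are
actually programmed. The monotonicity statement "M20 never rises" is
therefore a device-resolution statement; M10 is non-monotone at any
resolution (it rises by ~2.5 ms between 180 and 190 bpm).

The regression characteristics published for these curves (M10: gradient
−0.28 ms/bpm, intercept 143 ms, R² 0.87; M20: −0.56, 209, 0.94) are treated
as approximate cross-checks, not exact targets: the sampling behind them is
unstated, and no grid consistent with the stated 130–220 bpm range
reproduces the M20 line (the default grid gives −0.50 / 199.5 / 0.93; M20
cannot be programmed above 210 bpm at all). The M10 line and the ordering
R²(M20) > R²(M10) do reproduce on the default grid.

The PQ-duration reference curve is a **synthetic stand-in** (piecewise
linear, 170 ms at 60 bpm falling monotonically to 92 ms at 260 bpm, ~160 ms
at 100 bpm and ~100 ms at 220 bpm): the literature PQ datasets behind the
original comparison are not redistributable here, so residuals against the
default reference characterise shape, not published values. Users can
supply their own anchors. The regression characteristics of six observers'
estimated curves ship as a read-only fixture
(`data/observer_regressions.csv`) for documentation and plotting; the raw
estimates behind them are unavailable, so nothing is recomputed from that
fixture.

## Safety band and intervention thresholds

The safety band is 80–165 ms, endpoints inclusive-safe (unsafe is strictly
< 80 or > 165 ms): below it, atrial contraction against closed AV valves;
above it, pacemaker-induced tachycardia. Threshold analysis freezes the
VAI at the value chosen for the original rate HR₀ and scans rate drifts in
the clinically used quanta — +5 bpm upward, −10 bpm downward, both
configurable — reporting the largest drift whose every intermediate
multiple keeps the interval in band. An upward scan also stops if the
frozen VAI no longer fits the shortened cycle; a baseline already outside
the band reports zero tolerances with a flag. The drift table reports
round-half-up integer ms per (HR₀, ΔHR, method) cell, flagging
unprogrammable cells (M20 at 220 bpm) instead of failing.

## The rate-adaptive ideal relation

The hemodynamically ideal AP–VS interval mimics the AV node: a 130 ms
plateau at low rates, a 95 ms floor at high rates (which still clears a
90 ms effective post-atrial ventricular refractory period by the required
5 ms sensing window), and a linear −0.4 ms/bpm transition — the reported
physiologic rate-dependence of the PQ interval. Two forms are provided:

* **piecewise**: plateau for HR ≤ 100·x₁ = 122.5 bpm, floor for
  HR ≥ 100·x₂ = 210 bpm, slope −m = −0.4 ms/bpm between;
* **smooth**: a difference of order-n Butterworth log-magnitude sums in
  x = HR/100 (natural log, radians), with pole quality factors
  Qᵢ = 1/(2 sin(π(2i−1)/2n)). The additive constant c enters once, outside
  the sum. With the defaults (x₁ = 1.225, x₂ = 2.1, m = 0.4, c = 1.3,
  n = 8) the limits are exactly 100·c = 130 ms and
  100·(c − m(x₂ − x₁)) = 95 ms; n controls corner sharpness — n = 8 keeps
  the smooth curve within 0.5 ms of the plateaus outside the corners and
  within ~2 ms of the piecewise form at mid-range.

The pace-sense offset (the delay between the atrial stimulus and atrial
myocardial activation) has no separately published value; it is absorbed
into the 95–130 ms band. `recommend_interval` accepts an additive
clinician offset (default 0) and emits warnings — never failures — when the
value leaves the safety band or crowds the sensing window.

## Simulator and synthetic traces

The simulator is event-driven: rate changes take effect at the next
ventricular event, with no intra-beat changes and no retrograde conduction
(1:1 retrograde capture scenarios are out of scope). Fixed policies keep
the VAI frozen at the starting-rate value; with `readjust="on_violation"`
the VAI is re-derived from the current rate at each unsafe beat and a
READJUST event logged. If re-derivation is impossible (M20 above 210 bpm)
the next beat is logged UNAVAILABLE and left unpaced, and the previous VAI
is kept thereafter — the continuation rule is this package's choice. The
ADAPTIVE policy sets AP–VS to the smooth ideal each beat; since its range
[95, 130] ms lies inside [80, 165] ms it can never log an unsafe beat.

The trace generator produces constant, linear-ramp and
plateau-plus-Gaussian-noise rate profiles, sampled every 500 ms, clipped to
60–260 bpm, seeded through `numpy.random.default_rng`. The noise profile
(default SD 6 bpm) emulates the spontaneous rate wander of the arrhythmia
only as white jitter: it has no autocorrelation, no circadian or
therapy-driven trends, and no ectopic beat-to-beat irregularity. Passing
simulator tests therefore demonstrate correctness of the timing logic under
the modelled rate dynamics, not clinical performance on real JET episodes.

Test and acceptance runs use desk-scale problem sizes — 1-bpm sweeps of the
analytic curves (≤ 201 points) and 30–120 s simulated episodes (a few
hundred beats) — which these analyses fully resolve; all quantities except
the seeded noise trace are deterministic.

## Known limitations

* No hemodynamic model: the 95–130 ms band is taken as given, not derived.
* No electrical layer (sensing thresholds, capture, lead impedance).
* The ideal-curve parameters are fixed defaults, not fitted to patient data.
* The default PQ reference is synthetic (see above).
* Intermediate-MTR behaviour of the physical device is undocumented; the
  round-up policy is conservative but unverified against hardware.
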