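# avtpace

Timing analysis and beat-by-beat simulation of **AVT pacing** — R-wave
synchronised atrial pacing, the temporary pacing technique used to restore
atrioventricular synchrony in infants with postoperative **junctional
ectopic tachycardia (JET)**.

## The problem

In AVT pacing the wires of an external dual-chamber pacemaker are connected
inversely: the junctional R wave is sensed on the atrial channel and an
atrial stimulus is delivered through the ventricular output, just before the
next QRS complex. The programmed AV-delay therefore acts as an effective
*ventriculoatrial interval* (VAI), and the clinically important interval
between atrial pacing and ventricular sensing is

```
AP–VS = CL − VAI,    CL = 60000 / HR   (ms, HR in bpm)
```

The device caps the VAI indirectly through the programmed maximum tracking
rate (MTR) via a fixed lookup table. The two conventional recipes, **M10**
and **M20**, set the MTR 10 or 20 bpm above the junctional rate and program
the VAI to that maximum. Because CL is hyperbolic in HR while the table
falls in 10-bpm steps, the resulting AP–VS(HR) curves are non-intuitive:
M10 can produce intervals as short as 83 ms, M20 bottoms out at 96 ms, and
neither is safely extrapolated by eye. Intervals below 80 ms risk atrial
contraction against closed AV valves; above 165 ms they risk
pacemaker-induced tachycardia.

`avtpace` implements:

* the device timing model (cycle-length arithmetic, MTR→VAI_max lookup,
  M10/M20 recipes) — `avtpace.device_core`;
* AP–VS curve sampling, gradients, OLS regression with Pearson R², and
  comparison against a PQ-duration reference — `avtpace.curve_analysis`;
* the 80–165 ms safety band and intervention-threshold analysis: how far
  the junctional rate may drift before a frozen VAI leaves the band —
  `avtpace.threshold_policy`;
* the proposed **rate-adaptive ideal AP–VS relation**: a 130 ms plateau
  below ~122 bpm, a 95 ms floor above 210 bpm, a −0.4 ms/bpm ramp between,
  expressed both piecewise-linearly and as a smooth closed form built from
  Butterworth log-magnitude sums,

  ```
  y(x) = (m/2n) Σᵢ { ln[(1−e^{2(x−x₂)})² + e^{2(x−x₂)}/Qᵢ²]
                   − ln[(1−e^{2(x−x₁)})² + e^{2(x−x₁)}/Qᵢ²] } + c,
  Qᵢ = 1/(2 sin φᵢ),  φᵢ = π(2i−1)/(2n),   x = HR/100, y = AP–VS/100 ms
  ```

  with defaults x₁ = 1.225, x₂ = 2.1, m = 0.4, c = 1.3, n = 8 —
  `avtpace.rate_adaptive`;
* a beat-by-beat simulator comparing fixed-VAI policies against the
  rate-adaptive one over synthetic junctional-rate traces —
  `avtpace.simulator`;
* a CLI (`avt`) and YAML configuration — `avtpace.cli`, `avtpace.config`.

## Worked example

How far may the junctional rate climb from 200 bpm before an M20 setting
(VAI frozen at its 200 ms maximum for MTR 220) leaves the safe band?

```
$ avt thresholds --hr0 200 --method m20
{
  "avtpace_version": "0.1.0",
  "hr0_bpm": 200.0,
  "method": "M20",
  "vai_fixed_ms": 200.0,
  "tolerated_increase_bpm": 10.0,
  "tolerated_decrease_bpm": 30.0,
  "limiting_interval_up_ms": 85.71428571428572,
  "limiting_interval_down_ms": 152.94117647058823,
  "baseline_safe": true
}
```

A 10 bpm rise is tolerated (AP–VS 85.7 ms at 210 bpm, still ≥ 80 ms); at
+15 bpm the interval would fall to 79.1 ms and the VAI must be
reprogrammed. Downward, 30 bpm is tolerated before the interval exceeds
165 ms. The rate-adaptive ideal interval at 100 bpm:

```
$ avt ideal --hr 100
# avtpace 0.1.0 ideal mode=formula offset=0.0 hr=100
hr_bpm,ap_vs_ms,warning
100.0,129.93260732428064,
```

i.e. the smooth curve sits on its 130 ms plateau. In Python:

```python
>>> import avtpace as a
>>> round(min(a.ap_vs_for_method(hr, "M10") for hr in range(130, 221)))
83
>>> a.tolerated_excursion(160, "M20").tolerated_decrease
10.0
```

Other subcommands: `avt curve`, `avt gradient`, `avt regress`, `avt table`,
`avt generate-trace`, `avt simulate` (see `avt --help`).

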