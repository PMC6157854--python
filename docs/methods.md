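# Methods

## Dosing model

Contrast administration is modelled as a first-pass bolus into a single
well-mixed compartment. With flow `F` (mL/s), agent iodine concentration `Ic`
(mgI/mL), cardiac output `CO` (mL/s) and mixing volume `V` (mL), the blood
concentration follows `dc/dt = (F·Ic − CO·c)/V` with `c(0) = 0`, whose closed
form `c(t) = (F·Ic/CO)(1 − e^{−CO·t/V})` is what `concentration_at_time`
evaluates. The model ignores recirculation, bolus dispersion in the venous
path, and saline chasers; it is a steady-infusion approximation valid for the
8–10 s first-pass window of prospectively triggered coronary scans. `CO` and
`V` default to 90 mL/s and 100 mL purely to make the curve concrete; the flow
rule below never uses them.

Attenuation is taken proportional to iodine concentration and inversely
proportional to tube voltage, with total blood volume `BV` as the dilution
factor: `HU = k·F·Ic/(kVp·BV)`. The direction matters: a larger blood volume
dilutes more, so larger patients need more flow — this is why `BV` divides.

### Calibration

All constants are pinned by a single reference operating point: a male
patient of 1.80 m and 80 kg (Nadler BV 5.319 L) scanned at 120 kV with
7.0 mL/s and reaching 350 HU. This yields

* `k = 350·120·5.319/(7.0·300) ≈ 106.38`
* `c_cal = 7.0/(5.319·120) ≈ 0.010966 mL·s⁻¹ per L·kV`

and the personalised flow rule `F = c_cal·BV·kVp`, which by construction maps
every (BV, kVp) back to 350 HU. The 350 HU target deliberately overshoots the
300 HU diagnostic threshold as a safety margin.

A nominal worksheet formulation of the same rule circulates with the literal
constant 0.0002; that value is dimensionally irreconcilable with the
reference anchor (it yields 0.13 mL/s instead of 7.0) and with plausible
clinical flows under any unit reading of BV we could construct. The package
therefore derives the constant from the anchor by default and exposes the
literal value only as the audit option `flow_constant: printed`, which logs a
warning. Similarly, secondary descriptions of the Nadler formula sometimes
quote height in centimetres; the 0.3669/0.3561 coefficients are the classical
metre-based ones, and only metres reproduce both the anchor arithmetic and a
realistic cohort mean BV (≈ 4.7 L), so heights are metres everywhere (the CLI
converts inputs > 3 from cm).

### Protocol generation

Injection time equals scan time (8 s high-pitch, 10 s adaptive-sequence); an
optional `injection_time_buffer_s` reflects the +1 s site-level variability
seen in recorded injection times. Main bolus = flow × injection time. The
test bolus used for scan-delay timing is sized as flow × 2.1 s: the duration
is not stated anywhere explicitly and was inferred from the stable ≈ 2.0–2.2 s
test-volume/flow ratio across all published protocol groups; it is
configurable. Flows and volumes are rounded to 0.1 (injector granularity);
IDR and TIL are stored exactly and rounded to 0.1 only for display. TIL
counts the main bolus only. Flows above 7.5 mL/s attach a cannula-safety
warning (18–22 G access) rather than failing.

The heart-rate rule assigns high pitch at ≤ 70 bpm (inclusive boundary) and
adaptive sequence at 70–90 bpm; above 90 bpm the modelled protocol family
ends (such patients received a retrospective helical scan, out of scope) and
an explicit error is raised.

## Synthetic cohort

The generator emulates a 114-patient CCTA referral population
(55 men / 59 women). Only pooled height/weight statistics are published
(1.71 ± 0.10 m, 77.5 ± 16.0 kg), so the sex-specific split is this package's
choice: men ~ N(1.78, 0.07²) m and N(85, 14²) kg, women ~ N(1.65, 0.07²) m
and N(70, 13²) kg, height–weight correlation 0.5 (conventional, not
published). These pool to the published marginals at the 55:59 ratio and give
mean Nadler BVs of ≈ 5.4 L (men) and ≈ 4.1 L (women), matching the reported
sex-specific means. Draws are truncated by rejection to the patient
plausibility windows; a configuration whose acceptance rate falls below 1% is
rejected as infeasible. Heart rate is N(64.1, 11.2²) bpm truncated to
[40, 90]: > 90 bpm patients are excluded by construction because they leave
the modelled protocol family. Pacemaker carriers (fixed 120 kV) are not
generated by default (`pacemaker_rate = 0`).

Automated tube-voltage selection is proprietary and driven by topogram
attenuation; the emulator replaces it with a deterministic, monotone step
function of blood volume whose thresholds sit at the cohort's 52.6th and
85.1st BV percentiles, reproducing the observed 70/80/90 kV shares
(52.6/32.5/14.9%) by construction. Fixed-litre thresholds can be supplied for
sensitivity analyses.

What the generator does **not** reproduce: the dependence of selected kV on
scan mode observed clinically (kV and heart rate are sampled independently
here), the scatter of the vendor's voltage decisions around any body-size
proxy, intra-patient timing failures, and any image content. Consequently,
simulated tail kV groups are populated by the most extreme blood volumes of
each sex, and their group-mean injection parameters sit slightly outside the
narrow published ranges for three of twelve sex × mode × kV groups
(women/adaptive-sequence/80 kV, men/adaptive-sequence/90 kV, women/high-
pitch/90 kV — the last populated by ~1 patient per cohort). Passing
enclosure checks on the other nine groups shows the dosing chain is
calibrated correctly; the three misses measure the fidelity limit of a
deterministic BV-threshold voltage emulator, not a dosing error.

## Image quality

Definitions follow ROI practice on coronary CTA: image noise = SD of the
intravascular attenuation; `SNR = vessel/vessel SD`;
`CNR = (vessel − fat)/fat SD` with epicardial fat as background. Diagnostic
flags: attenuation ≥ 300 HU (inclusive — a segment at exactly 300.0 HU is
diagnostic) and CNR > 10 (strict). A patient's "overall" value is the
unweighted mean across their assessable segments; no vessel weighting is
applied (the clinical aggregation rule is unstated; simple mean adopted).

The synthetic ROI generator draws per-segment vessel attenuation
N(predicted HU, 43²), image noise N(42, 6²), fat mean N(−80, 15²) and fat SD
N(30, 5²) (SDs floored at 1 HU), with per-segment non-assessability sampled
from the published distal-segment dropout rates (segment 4: 6.1%, 9: 10.5%,
10: 7.9%, 12: 13.2%, 13: 4.4%, 14: 13.2%; 1% elsewhere), giving ≈ 96%
assessable segments. The fat priors are typical textbook values, not
measured ones. These are generative stand-ins calibrated to published
summary statistics; clinical image-quality outcomes (98.2% diagnostic scans,
per-segment attenuation tables) derive from patient images and are treated
as soft consistency checks only, never as reproduction targets. Subjective
Likert grades are stored when supplied in input CSVs but never generated.

## Numerical and testing choices

* All randomness flows through `numpy.random.Generator` seeded explicitly;
  identical seed + configuration gives byte-identical outputs.
* The concentration closed form is property-tested against numerical
  integration of its defining ODE at relative tolerance 1e-6.
* The flow/attenuation round-trip identity, the algebraic male−female Nadler
  difference (0.0108·h³ − 0.00089·w + 0.4208) and monotonicity in every
  contracted argument are asserted on random and grid inputs.
* Test problem sizes: 20,000 per sex for cohort-moment tests, 100,000 per sex
  in the acceptance script, 100 replicates of n = 114 for group-range
  enclosure, 1,000 replicates for the scan-mode share.
* kV values are whitelisted to the scanner's selectable steps
  (70–120 in 10 kV increments); pacemaker patients bypass the emulator with
  a fixed 120 kV.

## Known limitations

Single-compartment, no recirculation; no patient-specific cardiac output
(late-peak timing failures are therefore invisible to the model); the
voltage emulator is a body-size proxy, deterministic where the vendor's
algorithm is not; no scan-delay computation, radiation-dose estimation or
image processing of any kind.
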