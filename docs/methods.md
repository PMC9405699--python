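# Methods

This note documents how `gaitool` turns the G.A.I.T. instrument — a
31-item, 62-point ordinal observational measure of gait coordination —
into an executable scoring engine, what the synthetic data emulate, and the
numerical and design choices made where the printed instrument leaves the
matter open.

## 1. The rubric encoding

The packaged rubric (`data/rubric.yaml`) carries one record per printed
item: section (stance-and-swing / stance / swing), plane and view, branches
(items 11, 12, 15 have two; item 13 has four; all others one), and every
printed score level with a stable descriptor code. Duplicate numeric
scores within an item ("2 = almost none or no weight shift" vs "2 =
excessive weight shift") are distinguishable by code everywhere — in
reports, diffs, and the form round-trip.

**Boundary convention.** The printed thresholds reuse boundary values
ambiguously (e.g. "1 = 5–15°", "2 = > 15°, but < 30°", "3 = > 30°" leaves
30° unassigned). Realized intervals follow one rule: the level-0 interval
is closed; successive abnormal intervals are lower-open/upper-closed moving
away from normal. Every finite value then maps to exactly one level, and
a shared boundary belongs to the milder level. The realized interval for
every interval-type level is written in the rubric file.

**Gaps.** Some measured values are abnormal but covered by no printed
level (initial-swing knee flexion above 60°; weight shift between the
normal band and the excessive cutoff; swing hip-flexion peak in (30°, 32°]).
Because anything abnormal can never score 0, such values map to the
abnormal level whose realized interval is nearest (ties to the milder
score) and the item is flagged for review. Flags are never silent: they
survive serialization, the printed form and the round-trip.

**Point anchors.** Where the instrument prints a single normal value with
no band ("10° dorsiflexion at heel off", "~ 25 mm shift", "20° of extension
past neutral"), the realized level-0 band is the printed value ± 3° (± 10 mm
for weight shift; ≥ 12° reached for terminal-stance hip extension). These
half-widths are engine configuration (`MeasuredModeHeuristics`), not part
of the instrument, and are listed with defaults in `config.py`. A
zero-width realization would make the normative template sit exactly on a
threshold and turn noise-free scoring into a coin flip.

**Sign conventions.** Flexion, dorsiflexion, inversion, anterior pelvic
tilt, and trunk lean toward the assessed side are positive; knee
hyperextension is negative knee flexion. Angles in degrees, displacements
and foot-floor heights in millimetres.

## 2. Measured-mode classifiers

Items whose levels are thresholds on one measurement (elbow flexion, knee
initial-swing/midswing peaks, push-off plantarflexion, pelvic drop, ...)
are resolved directly from the realized intervals, checked most severe
first so duplicate-score levels keep their printed precedence. Pattern
items (stance ankle movement, midstance knee branches, terminal-stance
knee, hip extension, toe posture, ...) use explicit decision rules over a
small set of named measurements; the rules and their thresholds:

* **Branch selection** (items 11/12/13/15) follows the sign of the dominant
  deviation: hyperextension (negative knee flexion) selects the extension
  branch; excess dorsiflexion selects the dorsiflexion branch; otherwise
  the flexion/plantarflexion branch.
* **Item 13 C/D (control quality).** "Uncontrolled" or "snapping" return to
  extension is not derivable from position alone. Measured mode uses a
  knee angular-velocity heuristic: peak extension velocity during midstance
  above 2× (uncontrolled) or 3.5× (snapping) the normative template's peak
  (60 °/s), gated on early-midstance flexion with a near-extended end
  position. The result is *always* flagged for review; observed mode is
  authoritative for these branches. Branch D (buckling) is observed-only.
* **Item 1 (shoulder position).** The printed sub-descriptors (depressed /
  elevated / retracted / protracted) need direct observation. Measured
  mode scores the static shoulder-angle offset (> 10° ⇒ abnormal, flagged);
  an abnormal measured result always defers to the rater via the flag.
* **Item 3 (arm swing)** scores "reduced" when sagittal shoulder excursion
  falls below half the normative excursion (30°); both fractions are
  configurable.
* **Excessive inversion** (items 16/30) uses a 10° threshold; hip-hiking
  bands (item 21) are 3–8° (mild) and > 8° (moderate/severe); the
  "excessive weight shift" cutoff is 2 × the printed 25 mm normal. None of
  these magnitudes are printed by the instrument; all are configuration.

Measurement names, the events they are read at, and the shared window
arithmetic live in `measurements.py`; both the recorded-data path and the
simulator's oracle consume that one implementation, so they cannot drift
apart on *where* a value is read.

## 3. Gait events and cycle selection

A *step* is one initial contact of the assessed side (the instrument scores
each side separately; contralateral contacts are not required). Initial
contact is detected on the foot-contact signal — the pointwise minimum of
heel and toe height — as the crossing of a floor-proximity level, refined
to a 2 mm crossing; toe-off is the toe channel leaving the floor. The
floor is estimated robustly as the 10th percentile of the (smoothed)
height signal: the bout minimum is an extreme statistic and collapses
under noise. Contact runs require 50 ms of dwell with 2 mm hysteresis to
reject chatter. Channels are smoothed with a Savitzky–Golay filter
(order 3, 0.11 s window; 0.05 s for the contact channels, where a long
window rounds the touchdown corner and biases contact times by several
milliseconds).

Events a human rater identifies by phase rather than by contact are placed
at standard cycle percentages (configurable): loading response ends at
10%, the midstance window is 10–40% with the instant read at 30%,
heel-rise at 40%, midswing at the midpoint of the detected swing, terminal
swing the last 13% of the cycle. The one percentage the instrument itself
anchors — 15° knee flexion at 14% of the cycle — is honoured by the
normative template.

Administration rules: at least six steps, the first two and last two
excluded (acceleration/deceleration), all items scored on one selected
middle step — the median eligible step, ties to the earlier one.

## 4. The synthetic generator

The normative template is a periodic shape-preserving piecewise-cubic
(PCHIP) curve per channel through the instrument's printed normal anchors;
anchors the instrument does not print (shoulder excursion 30°, foot
clearance heights, pelvic obliquity magnitudes, toe posture 5°) use
conventional normal-gait values and are plain constants in
`synthetic.BASE_TEMPLATE`. Seventeen channels are emitted (sagittal /
coronal / transverse joint and trunk angles, pelvis lateral displacement,
heel/toe heights, toe angle), which is every channel the rubric needs.

Deviations (the vocabulary in `synthetic.DEVIATIONS`: equinus, foot drop,
vaulting, stiff knee, hyperextension patterns, circumduction, scissoring,
hip hiking, Trendelenburg, trunk lean, weight-shift changes, ...) edit
template anchors; a profile is a named set of deviations. The packaged
suite (`data/profiles.yaml`, 60 profiles) covers every item at every score
level reachable from kinematics; observed-mode fixtures cover the
remainder (shoulder sub-descriptors, midstance branches C/D).

`generate` tiles the deformed template over `n_steps` assessed-side steps
(default 8) at a cadence of 55 cycles/min (≈ 1.09 s cycles, a typical
comfortable pace when expressed per side), 100 Hz sampling, with the
first/last two steps slowed by 15%/7% and scaled to 80%/90% amplitude —
large enough that scoring a ramp step demonstrably changes item scores,
which is what makes the middle-step rule observable in tests. Optional
Gaussian noise (σ in degrees for angles, millimetres for
heights/displacements) is added per sample from a seeded generator;
identical seeds give bit-identical output.

**Event convention.** Ground-truth initial contact and toe-off are defined
as the template's own 2 mm floor-proximity crossings, computed analytically
on the deformed template, and the template phase axis is shifted once so
initial contact sits exactly at phase 0. Generator truth and the
detector's crossing rule are therefore the *same definition*, and detected
events agree with truth to within interpolation error (≤ 1 sample in
tests) without the oracle ever running the detector. A corollary worth
knowing: for toe-first contact patterns (equinus), the cycle starts at toe
contact, so "knee flexion at initial contact" is read there — the mild
item-11 score the equinus profile earns is a property of the contact
definition, not a bug.

**The oracle.** `expected_scores` evaluates the deformed template on a
dense phase grid with the true toe-off percentage and applies the rubric
predicates — no tiling, sampling, noise, or event detection. Expected
scores are never hand-entered anywhere; the suite asserts pipeline ==
oracle exactly (noise-free) on all 60 profiles, and ≥ 95% item agreement
across 100 seeded draws at σ = 1° (measured agreement ≈ 99%). Profiles
that sit near a printed threshold on purpose are marked
`boundary_adjacent` and tested separately, since agreement there measures
the noise, not the pipeline.

## 5. Adjustments

Order: item scoring → orthosis midpoint → device minimums → assist
escalation → footwear exclusions → totals. All adjustments are floors
("at a minimum" semantics) and the pipeline is idempotent; raw
pre-adjustment scores and machine-readable reasons are kept on every
adjusted or excluded item. The midpoint of an even-cardinality abnormal
score set rounds up (consistent with "a higher score may be indicated").
The trunk/weight-shift item set for the assist rule is {4, 5, 6, 7, 19,
20} by default and configurable, because the instrument names the concepts
rather than the ids; the item set an orthosis affects is user-declared,
defaulting for an AFO to the ankle/toe items {15, 16, 17, 29, 30} (the
instrument prints only the item-16 example). Device minimums apply
whenever a device is declared — whether the device is loaded is not
observable from the score sheet.

## 6. Psychometrics

`icc` implements ICC(2,1) — two-way random effects, absolute agreement,
single measures — from the ANOVA mean squares, with the standard F-based
95% CI (Satterthwaite degrees of freedom) and the mean squares reported
for audit. The form was chosen as the common default for clinical
test–retest/inter-rater designs; the published reliability values for the
instrument came from patient recordings and are not re-estimated here. A
zero-variance matrix yields ICC 0 with a warning rather than NaN. The
implementation is cross-checked in tests against an independent brute-force
mean-squares computation and against `pingouin.intraclass_corr`.

MCID interpretation uses absolute change (reported alongside the
lower-is-better convention): subacute 1.5–4 points reported as a band
(below / within / above), chronic 11.8 (FAC 3 / household) or 5.19
(FAC 4–5 / community) as thresholds; the chronic anchor is mandatory. The
bilaterally-averaged summary is available only as an explicitly labelled
extra and always carries the caveat that the published chronic MCID was
derived from bilateral averages, which may have inflated it.

## 7. What the synthetic data do and do not show

The generator emulates the *kinematic shape* of normal and deviated
hemiparetic-style gait: smooth periodic joint curves hitting the printed
normal anchors, deviations with realistic signs and magnitudes,
acceleration/deceleration ramps, and additive Gaussian measurement noise.
It does not emulate: stride-to-stride variability of patients (each middle
cycle is identical up to noise), soft-tissue/marker artefacts or
correlated sensor error, bilateral interaction (only the assessed side is
synthesized), fatigue drift, or forward dynamics (curves are kinematic
templates, not physics). Passing the oracle-equivalence suite therefore
shows the pipeline reads and scores kinematics correctly under the
instrument's rules; it does not validate the instrument on real patients,
and the published patient-derived reliability and validity figures are
deliberately out of scope.

## 8. Known limitations

* Items 1 and 13 C/D are rater judgements; the measured-mode heuristics for
  them are flagged advisories, never authoritative.
* The normal knee angle at initial contact is internally inconsistent in
  the instrument itself (item 11's level 0 reads "neutral/not
  hyperextended" where item 13's level 0 anchors 4° flexion); both are
  encoded as printed, and the template uses the 4° anchor — which leaves
  the template 1° from item 11's realized 5° boundary, the one place where
  1° of measurement noise can flip a normal item to a mild score.
* Trunk "static alignment" in measured mode is estimated from the walking
  channels (the signed value of minimal magnitude over the cycle), not
  from a separate standing record.
* CSV is the only ingestion format in this release; an events-override CSV
  can stand in for contact channels, and a C3D adapter slot is the obvious
  next extension.
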