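# gaitool

Scoring engine, kinematic pipeline, synthetic-gait generator and
psychometrics for the **Gait Assessment and Intervention Tool (G.A.I.T.)**,
a 31-item observational measure of gait coordination used in stroke and
multiple-sclerosis rehabilitation.

## The problem and who this is for

Gait coordination is the simultaneous performance of the spatial and
temporal components of walking — e.g. *knee flexion angle* (spatial) *at
toe-off* (temporal). Instrumented motion capture is the gold standard for
measuring it, but most clinics score gait by structured observation
instead. The G.A.I.T. is an observational instrument built for exactly
that: 31 ordinal items, each scoring one joint-movement component at a
named event of the gait cycle, with per-item maxima that sum to **62
points**; a total of **0 is a totally normal gait** and lower is always
more normal.

`gaitool` is for clinicians and movement-analysis researchers who want the
instrument as executable software:

* **observed mode** — a rater enters the descriptor selected for each item
  (with its checkbox sub-descriptors) on a structured form and the engine
  applies the instrument's scoring and administration rules;
* **measured mode** — joint-angle/displacement time series for one walking
  bout (wide CSV) are segmented into gait cycles, the administration rules
  are enforced (≥ 6 steps, the first/last two excluded, one middle step
  scored), each item's measurement is read at its named event, and the
  printed thresholds are applied;
* a **synthetic gait generator** provides normative and deviated
  (hemiparetic-style) trajectories with known ground-truth scores, so the
  whole pipeline is testable without patient data;
* **psychometrics** — the ICC(2,1) routine used in rater training and
  interpretation of score changes against published minimal clinically
  important difference (MCID) bands.

## The instrument in brief

Items 1–4 cover both phases (shoulder, elbow, arm swing, static trunk),
items 5–18 the stance phase, items 19–31 the swing phase. Each item offers
levels scored 0 up to the item's maximum (1–3); some items have branches
(e.g. item 13, knee at midstance, branches A–D for flexion, hyperextension
and two control-quality patterns) and some levels share a numeric score but
keep distinct descriptors ("almost none or no weight shift" vs "excessive
weight shift", both 2). Administration rules adjust scores for context: an
orthosis fixes affected items at the midpoint of their abnormal scores (an
AFO gives ankle-inversion item 16 a 2), an assistive device floors weight
shift (7) and Trendelenburg (8) at 1, physical assistance escalates
trunk/weight-shift items (moderate assist of one ⇒ item 4 = 3, item 5 = 2),
and shoes exclude the toe items (18, 31) with the total possible score
adjusted to 60. Anything abnormal can never score 0: measured values in
gaps between printed levels map to the nearest abnormal level and are
flagged for review.

Published interpretation bands implemented here: subacute stroke MCID
1.5–4 points (a range); chronic stroke 11.8 points (FAC 3 / household
ambulator anchor) or 5.19 points (FAC 4–5 / community ambulator anchor).

## Worked example

Simulate a toe-walking (equinus) bout and score it through the measured
pipeline:

```console
$ gaitool simulate --profile equinus --seed 3 --out sim
wrote sim/trajectories.csv, events.csv, expected_sheet.json (expected total 6 / 62)

$ gaitool score --input sim/trajectories.csv --out scored
Total Score: 6 / 62
wrote scored/sheet.json and scored/sheet.md
```

The total of 6/62 decomposes into: item 15 (ankle movement, stance) = 3,
"no heel contact with excessive plantarflexion to heel off"; item 29
(ankle movement, swing) = 2, "plantarflexion throughout"; and item 11
(knee at initial contact) = 1, mild flexion at the forefoot-first contact.
The pipeline's score matches the generator's analytically derived expected
sheet exactly. Interpreting a change for a chronic-stroke household
ambulator whose total improved from 19 to 6:

```console
$ gaitool interpret --pre 19 --post 6 --population chronic_stroke --anchor FAC3_household
change of 13 points (chronic_stroke, FAC3_household): at or above the published 11.8-point MCID (FAC3_household); meets the published MCID
  note: direction of improvement: lower total = more normal gait
```

Other subcommands: `gaitool form` (blank observed-mode entry form),
`gaitool icc --input raters.csv` (rater agreement with ANOVA mean squares),
`gaitool diff a/sheet.json b/sheet.json` (two-rater consensus workflow),
`gaitool simulate --list` (the packaged deviation-profile suite).

The same functionality is available as a library:

```python
from gaitool import load_profiles, generate, score_trajectories, SimulationConfig

bout = generate(load_profiles()["normal"], SimulationConfig(seed=1))
result = score_trajectories(bout.trajectories)
print(result.sheet.total, "/", result.sheet.max_possible)   # 0 / 62
```

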