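# pmhrank

Personalized ordering of mental-health intervention activities for
non-professional caregivers, from questionnaire answers to a ranked plan.

Home caregivers of chronically ill patients carry a documented burden on
their own mental health. mHealth intervention apps propose short daily
activities (gratitude exercises, mindfulness, problem-solving prompts) to
strengthen **positive mental health (PMH)**, a six-factor model of
wellbeing: personal satisfaction (F1), prosocial attitude (F2),
self-control (F3), autonomy (F4), problem-solving & self-actualization
(F5), and interpersonal relationship skills (F6). Every caregiver is weak
in different factors, so the *order* in which a fixed set of activities is
proposed should be personal: first the activities that shore up the
factors most at risk. `pmhrank` implements that personalization pipeline
for researchers and developers of such intervention apps.

## Method

**1. Factor levels by conjunctive OWA.** A 39-item questionnaire is scored
so each item gives a value s<sup>c</sup>(q) ∈ [0..3] (negatively phrased
items are reverse-coded). For factor *f<sub>j</sub>* with item set *Q*
(n = |Q|), the caregiver's competence level is an ordered weighted average
over the descending-sorted scores,

&nbsp;&nbsp;&nbsp;&nbsp;l<sub>j</sub>(c) = Σ<sub>i=1..n</sub> ω<sub>i</sub> · s<sub>σ(i)</sub><sup>c</sup>,&nbsp;&nbsp;&nbsp;&nbsp;ω<sub>i</sub> = (i/n)<sup>α</sup> − ((i−1)/n)<sup>α</sup>,

with weights generated by the RIM quantifier x<sup>α</sup>. α = 1 is the
arithmetic mean; α > 1 is conjunctive — weight moves onto the lowest
scores, so one weak answer lowers the whole level. The deployed default is
α = 3, which separates caregivers who are uniformly strong from those with
a hidden weakness.

**2. Reward–penalty marginal utilities.** Each activity *a* carries an
impact vector imp<sub>j</sub>(a) ∈ {−1, +1} (designed to improve factor
*f<sub>j</sub>* or not). Its marginal utility for the caregiver on factor
*f<sub>j</sub>* with level *l* is

&nbsp;&nbsp;&nbsp;&nbsp;g<sub>j</sub>(a) = k<sub>pos</sub> − l&nbsp;&nbsp;if imp = +1;&nbsp;&nbsp;&nbsp;0&nbsp;&nbsp;if imp = −1 and l ≥ 2.5;&nbsp;&nbsp;&nbsp;l − k<sub>neg</sub>&nbsp;&nbsp;if imp = −1 and l < 2.5,

ranging over [−k<sub>neg</sub>, k<sub>pos</sub>] with defaults
k<sub>pos</sub> = 4 > k<sub>neg</sub> = 3: improving a weak factor is
rewarded, ignoring a weak factor is penalized, and activities not touching
an already-satisfied factor (l ≥ 2.5) are neutral.

**3. Additive (MAUT) ranking.** The overall utility is the Sum of Scores
u(a) = Σ<sub>j</sub> g<sub>j</sub>(a); activities are proposed in
descending u, a complete and transitive weak order (ties broken
deterministically by descending activity id).

## Worked example

```python
from pmhrank import UtilityParams, reference_fixtures, rank_for_levels, sample_catalogue

fx = reference_fixtures()                       # bundled reference tables
levels = fx["cohort_levels"]["User 3"]      # (1.76, 3.00, 3.00, 1.54, 3.00, 1.36)
plan = rank_for_levels(levels, sample_catalogue(), UtilityParams())
print(plan.table.round(2).to_string(index=False))
```

```
 rank activity_id  overall_utility    F1  F2  F3    F4  F5    F6
    1        R9A3             3.42  2.24 0.0 0.0 -1.46 0.0  2.64
    2        R1A1             3.06  2.24 0.0 0.0  2.46 0.0 -1.64
    3        R7A1             0.58 -1.24 0.0 1.0  2.46 0.0 -1.64
    4        R6A2             0.58 -1.24 1.0 0.0  2.46 0.0 -1.64
    5        R2A1             0.14  2.24 1.0 0.0 -1.46 0.0 -1.64
    6        R8A1            -2.34 -1.24 1.0 0.0 -1.46 1.0 -1.64
    7        R1A2            -2.34 -1.24 0.0 1.0 -1.46 1.0 -1.64
```

This caregiver is strong in F2/F3/F5 but weak in F1, F4 and F6. Activity
R9A3 ranks first (u = 3.42) because it improves the two weakest factors F1
(marginal 4 − 1.76 = 2.24) and F6 (2.64); R1A2 ranks last because it
targets factors the caregiver already satisfies while ignoring the weak
ones (three −1.x penalties).

The `examples/` directory has one short script per capability
(questionnaire scoring, level estimation with the α-policy sweep, activity
ranking, synthetic cohorts). A thin CLI wraps the same functions:

```bash
pmhrank synth --n 200 --seed 42 --out cohort.csv --truth truth.csv
pmhrank levels --answers cohort.csv --alpha 3 --out levels.csv
pmhrank rank --levels levels.csv --activities catalogue.json --out plan.csv
pmhrank reproduce      # recompute the bundled reference tables
```

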