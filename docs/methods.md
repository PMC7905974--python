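# Methods

This note documents the model implemented by `pmhrank`, its parameters,
the numerical conventions, the synthetic-data generator, and the design
choices made where the method description left the design open.

## Pipeline

The package turns one caregiver's questionnaire answers into a
personalized order over a fixed catalogue of intervention activities, in
three stages:

1. **Scoring.** Each of the 39 items is answered on a four-step frequency
   scale and mapped to a score in {0, 1, 2, 3}; negatively phrased items
   are reverse-coded so that higher always means better positive mental
   health. Fractional scores in [0, 3] are accepted on input so that
   previously aggregated levels can re-enter the pipeline.
2. **Level estimation (OWA).** Each of the six PMH factors has a disjoint
   item set (sizes 8, 5, 5, 5, 9, 7). The factor level is the OWA of its
   item scores: sort descending, dot with weights
   `w_i = (i/n)^alpha − ((i−1)/n)^alpha` from the RIM quantifier `x^alpha`.
3. **Utility and ranking (MAUT).** Marginal utility per (activity,
   factor) via the reward–penalty rule below; overall utility is the sum
   across factors; activities are ranked by descending overall utility.

## Model assumptions

- Items load on exactly one factor each (the incidence map is a partition);
  the OWA treats the items of a factor as exchangeable evidence, which is
  what makes a quantifier-based weight vector meaningful.
- Preferential independence across factors holds by construction: each
  marginal utility depends only on that factor's level and the activity's
  impact on it, which licenses the additive aggregation.
- Impacts are binary (+1 designed to improve, −1 not); no graded impact
  strengths are modelled.
- The catalogue is fixed and every activity is eventually performed; only
  the order is personalized. Selecting a diverse *subset* of activities is
  out of scope.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `alpha` | quantifier exponent; aggregation policy | 3 | conjunctive: a factor counts as satisfied only if essentially all its items are; separates "uniformly strong" from "one hidden weakness", which the mean (α = 1) cannot |
| `k_positive` | reward at level 0 for an improving activity | 4 | reward exceeds penalty, favouring activities that fix weaknesses over merely avoiding irrelevant ones |
| `k_negative` | penalty magnitude at level 0 for a non-improving activity | 3 | see above; marginal utilities span [−3, 4] |
| `neutral_threshold` | level from which a −1 impact is neutral | 2.5 | a factor at ≥ 2.5 of 3 is "good enough"; ignoring it costs nothing |
| `precision` | console display rounding | 2 d.p. | matches the reference tables; files always keep full precision |

All are exposed in the library API, the CLI and the batch `RunConfig`.

## Numerical conventions

- **α = 0 limit.** The quantifier boundary condition `quant(0) = 0` is
  enforced explicitly, so α = 0 yields the existential weights
  (1, 0, …, 0) — the pure maximum. Large α needs no special casing.
- **Ties among equal scores** cannot affect the OWA (the sorted values are
  equal), so no tie rule is needed there; this is property-tested.
- **Display rounding is half-up** (2.125 → 2.13), matching the convention
  of the reference tables; Python's built-in banker's rounding would
  differ on exact half values (one cell of the published α-sweep grid sits
  exactly at 2.125). Implemented in `round_half_up`, used only at the
  display/comparison layer; all computation is double precision.
- **Ranking tie-break is descending activity id.** The reference rankings
  break every printed utility tie this way (verified across all twelve
  published caregiver rankings, which reproduce exactly under this rule);
  ascending id is available as an option. Rank indices are sequential
  1..n after tie resolution.
- **Histogram bins** are [0, 1), [1, 2), [2, 3] — half-open except the
  upper bin, which is closed so a perfect level of 3 is counted.
- **Missing answers** are rejected by default. In the explicit permissive
  mode the factor's weights are regenerated at the answered-item count
  (quantifier renormalization) and the level vector is flagged
  `incomplete`; conjunctive aggregation is sensitive to silently absent
  low scores, hence reject-by-default.
- **Files round-trip at full precision** (`%.17g` on write, round-trip
  float parsing on read); the `--precision` flag affects only the tables
  echoed to the console. Unicode minus signs in inputs are normalized to
  ASCII.

## Known input-precision limitation

The bundled reference level vectors are published rounded to 2 d.p.
Overall utilities recomputed from them can therefore differ from the
published overall-utility table by up to ±0.02 on some cells (the
published table was evidently computed from unrounded internal levels,
which are not available); one cell of the reference table is moreover
internally inconsistent with its own marginal-utility table by 0.01. The
reproduction suite treats the fully worked cells as exact and allows a
documented ±0.05 on rows whose inputs are only available rounded. None of
the published *rankings* are affected: all twelve reproduce exactly.

## Synthetic cohorts

The generator (`pmhrank.synthetic`) stands in for real cohort data, which
is not redistributable. Per caregiver it draws a latent level for each
factor — by default uniformly from {0, 1.5, 3}, i.e. weak / medium /
strong profiles; a continuous-uniform mode exists — and emits item scores
`clamp(round(latent) + offset, 0, 3)` with offset noise P(0) = 0.6,
P(±1) = 0.2. A configurable fraction of caregivers carries a
**weak-single-item archetype**: one factor is set to full competence but
one of its items is answered 0. This is the signature case separating the
conjunctive policy (level drops markedly) from the mean (weakness averaged
away). Generation is fully determined by the seed, which is recorded in
the truth table.

What the generator does **not** emulate: correlated factors, item-specific
difficulty or reverse-coding behaviour, response styles (acquiescence,
central tendency), longitudinal change over the intervention. Passing
recovery tests therefore show that the pipeline preserves planted ordinal
structure under simple answer noise — not that it is robust to real
psychometric artefacts.

## Problem sizes used in the test and reproduction suites

Reference-table reproduction uses the published inputs as-is (5 and 12
caregivers, 7 activities). Property suites use: 200-caregiver synthetic
cohorts for latent-level recovery (Spearman > 0.9 per factor at the
default noise); 1,000 random 20-activity instances for ranking-oracle and
sum-vs-average equivalence; a 301-point level grid for utility branch
monotonicity. These sizes give stable Monte-Carlo behaviour while keeping
the default suite fast.

## Design choices where the method description was open

- **Item polarities** beyond the two published examples are unknown; the
  default configuration marks only q1 negative and everything else
  positive, and polarity is part of the questionnaire configuration file.
  All bundled fixtures start from already-scored answers, so polarity
  never enters the reproduction path.
- **Level provenance:** levels computed in-pipeline feed the utility stage
  at full precision; levels supplied from a file are used exactly as
  given.
- **Dataclasses over a validation framework:** inputs are small and
  schema-light; frozen dataclasses with explicit checks keep the
  dependency surface minimal.
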