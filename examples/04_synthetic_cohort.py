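"""Generate a synthetic cohort and check the pipeline recovers the truth.

Draws 200 caregivers with latent factor levels on {0, 1.5, 3}, adds
answer noise, runs the conjunctive (alpha = 3) aggregation and reports
the Spearman correlation between latent and estimated levels per factor,
plus the cohort-level histogram used to inspect level distributions.
"""

from scipy.stats import spearmanr

from pmhrank import (
    CohortSpec,
    cohort_level_histogram,
    compute_level_vector,
    default_questionnaire,
    generate_cohort,
)
from pmhrank.questionnaire import FACTORS

config = default_questionnaire()
sheets, truth = generate_cohort(CohortSpec(n_caregivers=200, seed=42), config)
levels = [compute_level_vector(s, config, alpha=3.0) for s in sheets]

print("Spearman(latent, estimated) per factor:")
for j, f in enumerate(FACTORS):
    rho = spearmanr(truth[f], [v.as_array()[j] for v in levels]).statistic
    print(f"  {f}: {rho:.3f}")
print()
print("caregivers per level bin (conjunctive aggregation):")
print(cohort_level_histogram(levels).to_string())
print()
print("correlations near 1 mean the OWA levels preserve the planted ordering")
print("of caregivers despite answer noise; the histogram splits the cohort")
print("into needs-support [0,1), middling [1,2) and satisfied [2,3] groups.")
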