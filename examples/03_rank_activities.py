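"""Rank intervention activities for one caregiver by additive utility.

Takes the published level vector of the worked-example caregiver
("User 3": strong in F2/F3/F5, weak in F1/F4/F6), scores each of the
seven sample activities with the reward-penalty rule (k_pos = 4,
k_neg = 3, neutral threshold 2.5) and prints the personalized order.
"""

from pmhrank import UtilityParams, reference_fixtures, rank_for_levels, sample_catalogue

fx = reference_fixtures()
levels = fx["cohort_levels"]["User 3"]
plan = rank_for_levels(levels, sample_catalogue(), UtilityParams())

print(f"levels of {levels.caregiver_id}: "
      + ", ".join(f"{f}={v:.2f}" for f, v in levels.levels.items()))
print()
print(plan.table.round(2).to_string(index=False))
print()
print("R9A3 comes first (utility 3.42): it improves F1 and F6, this caregiver's")
print("weakest factors; R1A2 comes last because it targets factors already high")
print("and ignores the weak ones (negative marginals on F1, F4, F6).")
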