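"""Score a caregiver's linguistic questionnaire answers.

Builds a small two-item questionnaire (one positively and one negatively
phrased statement), scores one caregiver's answers, and prints the
resulting 0..3 scores.  Higher always means better mental health, so the
negative item's scale is reversed.
"""

from pmhrank import Question, QuestionnaireConfig, score_sheet

config = QuestionnaireConfig((
    Question("q11", factor="F6", polarity="positive"),  # "I can put myself in others' shoes"
    Question("q1", factor="F2", polarity="negative"),   # "I find it difficult to accept others"
))

sheet = score_sheet("caregiver-42", {
    "q11": "quite often",
    "q1": "always or almost always",
}, config)

for qid, score in sheet.scores.items():
    q = config.question(qid)
    print(f"{qid} ({q.polarity}, factor {q.factor}): answered -> score {score:.0f}")
print()
print("q11 'quite often' scores 2 of 3; q1 is negatively phrased, so answering")
print("'always or almost always' scores 0: that caregiver struggles with acceptance.")
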