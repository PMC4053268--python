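"""Score comorbidity burden from ICD-10 diagnosis codes.

The Charlson index sums weights over 17 comorbidity groups (1 to 6
points each); within the diabetes and cancer hierarchies only the more
severe member counts.
"""

from hosprisk import charlson_index

patients = {
    "uncomplicated MI": ["I21.0"],
    "MI + reinfarction (same group, counted once)": ["I21.0", "I22.1"],
    "diabetes with and without complications": ["E10.2", "E11.9"],
    "metastatic cancer (supersedes the primary)": ["C50.1", "C78.0"],
    "multimorbid": ["I21", "I50", "N18", "C80", "B20"],
}

for label, codes in patients.items():
    s = charlson_index(codes)
    print(f"{label}: codes={codes} -> score {s.score} ({s.category})")
# The score feeds the disease-risk block of the logistic models; the
# categories (0 / 1-2 / 3-4 / >=5) are the summary bands used for
# cohort demographics.
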