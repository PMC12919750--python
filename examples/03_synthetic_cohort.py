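"""Generate a synthetic diabetic cohort.

Draws 2,000 records (scaled down from the default 10,000 for a quick demo)
by stratified sampling, applies the physiological filters, labels each record
with the deterministic triage rule, and reports the class mix — which should
sit near the 55/30/15 reference proportions.
"""

import dataclasses
from collections import Counter

from nutrikiosk.cohort import CohortConfig, generate_cohort, split_train_test

cfg = dataclasses.replace(CohortConfig(seed=42, n_target=2000), label_noise_rate=0.0)
records, rejections = generate_cohort(cfg)

print(f"generated {len(records)} records; filter rejections: {dict(rejections)}")
shares = Counter(r.label for r in records)
for label in ("ADEQUATE", "MINOR_ADJUSTMENT", "REQUIRES_CONSULTATION"):
    print(f"  {label:<22} {100 * shares[label] / len(records):5.1f} %")

train, test = split_train_test(records, 0.8, seed=42)
print(f"\nstratified 80/20 split: {len(train)} train / {len(test)} test")
r = records[0]
print(f"\nfirst record: {r.age_years} y {r.sex}, BMI {r.bmi}, {r.diabetes_type}, "
      f"control {r.glycemic_control}, {r.kcal_need:.0f} kcal/d -> {r.label}")
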