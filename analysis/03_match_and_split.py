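#!/usr/bin/env python
"""Propensity matching and grouped splits on the phantom cohort.

Demonstrates that 1:1 nearest-neighbor matching on the propensity logit
(age + sex) reduces the age imbalance between classes, and that the
70:15:15 subject-grouped split keeps classes balanced. Writes the match
pairs and the split assignment to results/.
"""

from pathlib import Path

import pandas as pd

import shortcut_audit as sa
from shortcut_audit.cohort import standardized_mean_difference, split_table

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

cfg = sa.PhantomConfig(grid_shape=(16, 16, 16), n_subjects_per_class=30,
                       age_offset=3.0, seed=0)
cohort = sa.generate_cohort(cfg)
# match a smaller case group into the full control pool so the greedy
# nearest-neighbor selection actually has room to improve balance
cases = [s for s in cohort.subjects if s.class_label == "patient"][:20]
controls = [s for s in cohort.subjects if s.class_label == "control"]

before = standardized_mean_difference([s.age for s in cases],
                                      [s.age for s in controls])
pairs = sa.propensity_logit_match(cases, controls)
matched_cases = {p for p, _ in pairs}
matched_controls = {c for _, c in pairs}
after = standardized_mean_difference(
    [s.age for s in cases if s.subject_id in matched_cases],
    [s.age for s in controls if s.subject_id in matched_controls],
)
pd.DataFrame(pairs, columns=["case_id", "control_id"]).to_csv(
    RESULTS / "match_pairs.tsv", sep="\t", index=False
)
print(f"matched {len(pairs)} case-control pairs")
print(f"age standardized mean difference: {before:.3f} before -> {after:.3f} after")

assignment = sa.grouped_split(cohort.subjects, sa.SplitSpec(seed=1))
tab = split_table(assignment)
tab.to_csv(RESULTS / "split_assignment.tsv", sep="\t", index=False)
counts = tab["subset"].value_counts()
print("split sizes:", dict(counts))
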