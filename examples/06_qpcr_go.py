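"""Delta-delta-Ct fold change, the pooled t-test, and GO percentages.

A qPCR table with target and reference (normalizer) cycle thresholds
yields a relative fold change 2^(-ddCt); gene sets are summarised per
GO sub-tree as the share of category assignments.
"""

import pandas as pd

from mahex import category_percentages, ddct_fold_change, students_t
from mahex.fixtures import go_membership

# proliferation-marker qPCR: treated wells amplify the target two
# cycles earlier while the normalizer is stable -> 4-fold induction
ct = pd.DataFrame({
    "group": ["control"] * 4 + ["treated"] * 4,
    "target_ct": [25.1, 25.0, 24.9, 25.0, 23.0, 23.1, 22.9, 23.0],
    "reference_ct": [20.0, 20.1, 19.9, 20.0, 20.0, 20.1, 19.9, 20.0],
})
fold = ddct_fold_change(ct)
print(f"relative expression fold change: {fold:.2f}")

t = students_t(ct.loc[ct.group == "control", "target_ct"],
               ct.loc[ct.group == "treated", "target_ct"])
print(f"Student's t on target Ct: t = {t.t:.2f}, p = {t.p:.2e}")

bp = go_membership("biological_process")
res = category_percentages(set(bp["gene"]), bp)
print("top biological-process categories:")
for _, row in res.head(3).iterrows():
    print(f"  {row.category[:60]}: {row['count']} genes ({row.percent}%)")
# Percentages divide by all category assignments in the sub-tree, so
# a 5-gene category among 28 assignments reports 18%.
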