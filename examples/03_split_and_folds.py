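"""Modality-consistent splitting with a DSC-anchored common test set.

The test set is drawn only from patients that have every modality (the
DSC subset), so results are directly comparable across modality groups;
each modality's training pool is its own patients minus that shared test
set. Five CV folds then partition each training pool.
"""

import spottune3d as st

cohort = st.generate_cohort(st.CohortSpec())
split = st.split_cohort(cohort.records, st.SplitPlan(seed=0))

print("training set sizes per modality group:")
for group in ("structural", "dti", "dsc"):
    print(f"  {group:11s} {len(split.train[group])}")
print(f"common test set: {len(split.test)} patients")

folds = st.make_cv_folds(split.train["structural"], 5, seed=0)
print(f"structural CV fold sizes: {[len(f) for f in folds]}")
print()
print("183/151/132 training patients with a shared 57-patient test set;")
print("folds differ in size by at most one patient.")
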