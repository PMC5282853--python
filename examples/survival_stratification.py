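"""Prognostic index and risk-group survival comparison.

Builds a toy cohort where one module's mean methylation carries a real
hazard effect, computes the prognostic index (Cox coefficients are
supplied, as they would come from an external model fit), splits
patients at the median index, and compares the groups by log-rank.
"""

import numpy as np
import pandas as pd

from emdn.downstream import km_curves, logrank_test, prognostic_index, split_risk_groups
from emdn.netio import ClinicalTable

rng = np.random.default_rng(3)
n = 120
patients = [f"p{i:03d}" for i in range(n)]

# module-level mean methylation per patient (2 modules x patients)
module_means = pd.DataFrame(
    rng.uniform(0.2, 0.8, size=(2, n)), index=["m1", "m2"], columns=patients
)
beta = np.array([2.5, 0.0])  # only module m1 is prognostic

index = prognostic_index(beta, module_means)
groups = split_risk_groups(index)

# survival times with a hazard that increases with the index
times = rng.exponential(scale=10.0 / np.exp(index - index.mean()))
events = (rng.uniform(size=n) < 0.8).astype(int)
clin = ClinicalTable(table=pd.DataFrame({"time": times, "event": events},
                                        index=patients))

stat, p = logrank_test(groups, clin)
print(f"high-risk patients: {(groups == 'high').sum()}, "
      f"low-risk: {(groups == 'low').sum()}")
print(f"log-rank chi-square = {stat:.2f}, p = {p:.2e}")
curves = km_curves(groups, clin)
for name, sub in curves.groupby("group"):
    t_half = sub.loc[sub["survival"] <= 0.5, "time"].min()
    print(f"median survival ({name} risk): {t_half:.1f}")
# A small p-value means the median split on the prognostic index
# separates patients into groups with genuinely different survival.
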