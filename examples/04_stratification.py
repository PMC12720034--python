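"""Bootstrap ROC stratification of RP vs non-RP patients.

Patients are ranked by their mean baseline-corrected PTV T2; 5000 bootstrap
resamples of the cohort give a median ROC curve with 95% CI, a Mann-Whitney
p-value, and the Youden-optimal classification cut-off.
"""

import numpy as np

from t2rp import bootstrap_roc, mann_whitney_u, optimal_cutoff
from t2rp.config import PipelineConfig
from t2rp.phantom import generate_cohort
from t2rp.pipeline import process_patient

cfg = PipelineConfig()
cfg.phantom.seed = 4
cases = generate_cohort(cfg.phantom)
values, labels = [], []
for case in cases:
    params, _ = process_patient(case, cfg)
    values.append(params.t2_ptv_mean_ms)
    labels.append(int(case.is_rp))
values, labels = np.array(values), np.array(labels)

summary = bootstrap_roc(values, labels, n_boot=5000, seed=0)
u, p, significant = mann_whitney_u(values[labels == 1], values[labels == 0])
cut = optimal_cutoff(summary, values, labels)

print(f"cohort: {labels.sum()} RP / {(1 - labels).sum()} non-RP patients")
print(f"PTV parameter medians:  RP {np.median(values[labels == 1]):.1f} ms, "
      f"non-RP {np.median(values[labels == 0]):.1f} ms")
print(f"median bootstrap AUC:   {summary.auc_median:.2f} "
      f"[{summary.auc_lo:.2f}, {summary.auc_hi:.2f}]")
print(f"Mann-Whitney:           U = {u:.0f}, p = {p:.4f}"
      + (" (significant at 0.05)" if significant else ""))
print(f"Youden index:           {cut.youden_max:.2f} at cut-off {cut.cutoff_ms:.1f} ms "
      f"(sens {cut.sens_at_cutoff:.2f}, spec {cut.spec_at_cutoff:.2f})")
# An AUC near 0.8-0.9 with p < 0.05 mirrors the stratification power
# expected for a ~10 ms group separation at n = 24; the cut-off feeds the
# voxel-wise RP segmentation.
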