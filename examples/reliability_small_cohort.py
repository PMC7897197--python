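"""Run the imaging pipeline end to end on a small cohort and report
reliability statistics.

Eight subjects: each 67-frame series is synthesized pixel by pixel, fitted
into a T1 map, and measured by two simulated raters (label maps eroded by
1 px and shifted by up to 1 px, emulating independently drawn ROIs).
Prints the pooled regional means, the inter-rater ICC(2,1), the intra-rater
(left vs right) Bland-Altman bias, and the worst pairwise Wilcoxon
rank-sum p-value between brain structures.  Expect ICC near 1 for brain
regions (lower for the eye, whose boundary contrast is extreme) and small
left-right biases.
"""

import numpy as np

from t1norm import (
    AcquisitionProtocol,
    CohortConfig,
    PipelineConfig,
    analyze_measurements,
    fit_cohort,
)

pcfg = PipelineConfig(
    protocol=AcquisitionProtocol(),
    cohort=CohortConfig(
        n_subjects=8,
        age_sampling="from_list",
        ages=(0.5, 1.5, 3.0, 5.0, 7.0, 10.0, 13.0, 16.0),
        master_seed=4,
    ),
)
measurements, ages = fit_cohort(pcfg, progress=True)
result = analyze_measurements(measurements, ages, pcfg)

print(f"\n{'region':24s} {'pooled 5-18y':>12s} {'ICC(2,1)':>9s} {'L-R bias':>9s}")
for region in pcfg.cohort.regions:
    name = region.name
    pooled = result["pooled"].get(name, float("nan"))
    icc = result["icc"][name].icc_value
    ba = result["intra_ba"].get(name)
    bias = f"{ba.bias_ms:+7.1f}" if ba else "     na"
    print(f"{name:24s} {pooled:12.1f} {icc:9.3f} {bias:>9s}")
worst_p = np.nanmax(result["contrasts"].to_numpy())
print(f"\nworst pairwise structure contrast p = {worst_p:.2e}")
print("(neighbouring structures need the full 100-subject cohort to reach "
      "p < 0.01)")
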