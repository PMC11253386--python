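"""Calibrate the HRD-high threshold on a BRCA-mutated cohort.

The threshold is placed at the 5th percentile of the HRD scores of samples
with known BRCA1/2 mutations, so at least 95% of them classify HRD-high.
Here the scores come from the synthetic cohort generator, which emulates a
55-sample mutated cohort with two low-scoring outliers.
"""

from acornhrd import calibrate_threshold
from acornhrd import simulate as sim

scores = sim.cohort_ii_event_counts(n=55, seed=2024)
threshold, achieved = calibrate_threshold(scores, target_agreement=0.95)

print(f"cohort size:            {len(scores)}")
print(f"calibrated threshold:   {threshold}")
print(f"achieved agreement:     {achieved:.1%} "
      f"({int(round(achieved * len(scores)))}/{len(scores)} scores >= {threshold})")
# The threshold is the largest integer t such that >= 95% of the mutated
# cohort scores are at or above t; samples scoring >= t are called HRD-high.
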