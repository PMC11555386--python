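"""Find the size/shape threshold that separates two diagnostic groups.

Simulates a cohort whose disease subjects carry an 8% excess of small round
aggregates, draws the group ECDF difference with its 99% KS band, and scans
joint (area <= a, circularity >= c) thresholds for the maximal per-subject
fraction difference tested by permutation.
"""

import numpy as np

from speckpull import (CohortSpec, ecdf_difference, simulate_cohort,
                       threshold_search)

spec = CohortSpec(n_control=10, n_disease=10, morphology_effect=0.08,
                  aggregates_per_subject=300, seed=0)
cohort, morph = simulate_cohort(spec)
groups = dict(cohort.groupby("subject")["group"].first())

pooled_d = np.concatenate([m["area_um2"] for s, m in morph.items()
                           if groups[s] == "disease"])
pooled_c = np.concatenate([m["area_um2"] for s, m in morph.items()
                           if groups[s] == "control"])
diff = ecdf_difference(pooled_d, pooled_c, confidence=0.99)
print(f"pooled area ECDF difference: D = {diff.D:.3f}, "
      f"99% KS band = {diff.band:.3f} "
      f"({'outside' if diff.D > diff.band else 'inside'} the band)")

res = threshold_search(morph, groups, seed=0)
print(f"threshold: area <= {res.area_max:.4f} um^2 "
      f"and circularity >= {res.circ_min:.2f}")
print(f"small-round fraction difference {100 * res.delta_fraction:.1f}% "
      f"(p = {res.p_value:.2e}, significant: {res.significant})")
# the planted small-round component ends at d = 150 nm (area 0.0177 um^2);
# the scan localizes that boundary and recovers the ~8% planted excess
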