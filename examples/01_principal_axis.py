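"""Derive the principal axis of regional neonatal cortical MRI metrics.

Simulates a small term cohort with a planted rank-1 axis, runs the full
axis pipeline (hemisphere averaging, MAD outlier removal, pooled z-scoring,
covariance eigendecomposition) and compares the recovered region scores with
the planted ones.
"""

import numpy as np
import pandas as pd

from natalaxis import imaging, syndata

table, truth = syndata.generate_imaging_cohort(n_term=120, n_preterm=0, seed=7)
axis, zparams = imaging.compute_axis(table)

print("variance explained per component (%):",
      np.round(100 * axis.variance_fraction, 1))
print("\nPC1 region scores (primary regions at one extreme):")
print(axis.pc1_scores.sort_values().round(2).to_string())

planted = pd.Series(truth.axis_region_scores)
r = np.corrcoef(axis.pc1_scores.reindex(planted.index), planted)[0, 1]
print(f"\ncorrelation with planted axis: r = {r:.4f}")
# PC1 captures nearly all group-level variance because the generator plants a
# rank-1 structure; the recovered ordering matches the planted region scores.
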