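"""From inequality covariates to classes and penalties.

Shows the two assignment schemes: the binary top-percentile cut (the
worst 15% of locations by a per-capita rate form one penalized class)
and the graded linear ramp (locations above the 90th percentile of a
socioeconomic indicator get a delta growing linearly to 1 + Delta).
"""

import numpy as np

from ineqrad import assign_binary_top, per_capita, ramp_scheme, union_binary_top

rng = np.random.default_rng(0)
L = 40
populations = rng.integers(1_000, 100_000, size=L)
casualties = rng.poisson(populations * 2e-4)
flood_exposure = rng.gamma(0.5, 2_000, size=L)

# --- binary scheme: top 15% by casualties per capita, union with floods ----
rates = per_capita(casualties, populations)
labels_conflict = assign_binary_top(rates, 0.15)
labels_union = union_binary_top([rates, flood_exposure], 0.15)
print(f"conflict-only penalized locations: {int((labels_conflict == 2).sum())} of {L}")
print(f"conflict OR flood (union) penalized: {int((labels_union == 2).sum())} of {L}")

# --- graded ramp: delta rises linearly above the 90th percentile ----------
gini = rng.beta(8, 12, size=L)
scheme, labels = ramp_scheme(gini, pct=90, Delta=1e-7)
deltas = scheme.delta_array()
print(f"\nramp on a Gini-like covariate: {scheme.n_classes} classes "
      f"({scheme.n_classes - 1} above the 90th percentile)")
print(f"delta range: {deltas.min():.9f} .. {deltas.max():.9f}")
print("\nEach distinct delta is its own class; the covariate maximum gets")
print("exactly 1 + Delta and everything at or below the percentile stays at 1.")
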