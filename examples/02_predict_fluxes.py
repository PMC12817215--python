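"""Predict OD fluxes for a synthetic system, with and without inequality.

Generates a 30-location system with Zipf populations where 15% of
locations are penalized (delta = 1 + 1e-4), then predicts fluxes with the
standard radiation model and the two-class modified model, using the
same known outflows T_i.  The printed tallies count origin-destination
cells each model over-, correctly and under-estimates against the
ground-truth fluxes.
"""

import numpy as np

from ineqrad import (
    SyntheticSystemConfig,
    build_probability_matrix,
    compute_distances,
    error_matrix,
    estimation_tally,
    generate_od,
    generate_system,
    predict_fluxes,
)

cfg = SyntheticSystemConfig(L=30, true_delta=1 + 1e-4, penalized_fraction=0.15)
system, scheme = generate_system(cfg, seed=42)
distances = compute_distances(system)
observed = generate_od(system, scheme, "two_class", sampling="multinomial", seed=42)
T = observed.outflows.astype(float)

print(f"{len(system)} locations, total movers = {int(T.sum())}, "
      f"{int((system.classes == 2).sum())} penalized locations\n")

for model in ("standard", "two_class"):
    P = build_probability_matrix(system, scheme, model, distances=distances)
    pred = predict_fluxes(P, T, round_to_int=True)
    over, correct, under = estimation_tally(error_matrix(pred, observed))
    total_err = int(np.abs(pred.matrix - observed.matrix).sum())
    print(f"{model:>10}: over {over:4d}  correct {correct:4d}  under {under:4d}"
          f"   total |error| = {total_err}")

print("\nThe modified model correctly estimates more cells because it knows")
print("which locations are penalized; 'correct' means the rounded predicted")
print("flux equals the observed count exactly.")
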