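"""The full statistical protocol: is the inequality-aware model better?

Generates ground-truth fluxes from the two-class model (delta = 1+1e-4,
multinomially sampled), then runs the comparison protocol: one-sided
Mann-Whitney on absolute errors, Hamming distances with a binomial test,
and permutation nulls where classes are reassigned randomly.  The
modified model is declared superior only if the tests are significant
AND beat the 5% quantile of the permutation null.
"""

from ineqrad import SyntheticSystemConfig, compare_models, generate_od, generate_system

cfg = SyntheticSystemConfig(L=25, true_delta=1 + 1e-4, penalized_fraction=0.15)
system, scheme = generate_system(cfg, seed=7)
observed = generate_od(system, scheme, "two_class", sampling="multinomial", seed=7)

report = compare_models(system, scheme, observed, model="two_class", n_reps=200, seed=7)

print(f"Mann-Whitney U = {report.mw_u:.0f}, one-sided p = {report.mw_p:.3g}")
print(f"Hamming distance: modified {report.hamming_mod} vs standard {report.hamming_std}")
print(f"binomial test p = {report.binomial_p:.3g}")
print(f"permutation null (n = {report.n_reps}):")
print(f"  MW 5% quantile {report.mw_null_q05:.0f}  -> pass: {report.mw_perm_pass}")
print(f"  Hamming 5% quantile {report.hamming_null_q05:.0f}  -> pass: {report.hamming_perm_pass}")
print(f"\nverdict: modified model {'IS' if report.significant else 'is NOT'} significantly better")
print("\nSmall p-values say the modified model's errors are smaller and its")
print("error sparsity finer; passing the permutation null says this comes from")
print("the covariate itself, not from the extra parameters.")
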