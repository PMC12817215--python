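# Methods

## Model

A system is a set of L locations with populations, pairwise distances
and class labels c_i ∈ {1…C}. Each class k carries a scale δ_k > 0 that
compresses its benefit density: p^(k)(z) = δ_k · p(z δ_k), with class 1
the δ = 1 reference. We use the uniform reference density on [0, 1]
throughout, so class k's density is uniform on [0, 1/δ_k]; δ_k > 1 means
worse opportunities. The behavioural model is absorption–emission: a
mover from i draws a threshold as the maximum of m_i draws from the
origin-class density and moves to the closest location whose opportunity
(maximum of n_j draws from its own class density) strictly exceeds the
threshold. Movement probabilities follow from the order-statistic
integral

P(i→j) = ∫ P_{m_i}(z) · Π_k F_k(z)^{s_ij^(k)} · (1 − F_{c_j}(z)^{n_j}) dz,

where F_k is the class-k CDF, P_m the max-order-statistic density of the
origin class, and s_ij^(k) the class-k population strictly inside the
circle of radius r_ij around i (excluding i and j). Probabilities are set
to zero on the diagonal and rows are normalized to 1; fluxes are
T_ij = T_i · p_ij with known (or regression-estimated) outflows T_i,
rounded to the nearest integer (ties half away from zero). Normalization
precedes multiplication by T_i, which precedes rounding.

Three analytic routes produce the same probabilities and are
cross-checked in the tests:

1. **Two-class closed forms** for the four origin/destination class
   combinations (exact for any δ, any populations).
2. **Linearized model**, first order in each δ_k − 1:
   p = p^R [1 + Σ_k ρ^(k) (δ_k − 1)] with
   ρ^(k) = s^(k) + m·1[c_i = k] − (m + s)·1[c_j = k].
   This per-class superposition reproduces all four two-class
   coefficients and is invariant under a common shift of all δ_k, as the
   exact model is (rescaling every class rescales the benefit axis and
   changes nothing). It is validated numerically against the integral
   engine: the residual is second order in the penalties.
3. **Integral engine** for any C: with uniform densities the integrand
   is piecewise polynomial with breakpoints at the support ends 1/δ_k;
   each piece is integrated exactly, in log space so that populations up
   to 10^6 neither overflow nor underflow.

A fourth, non-analytic route — the agent-level Monte-Carlo simulator —
realizes the decision process directly (inverse-transform sampling of
the maximum, z = δ⁻¹U^{1/n}, exact and O(1) per draw) and serves as the
independent oracle for all three.

### Conventions and numerical choices

- **Circle membership is strict** (r_il < r_ij): locations exactly at the
  destination's distance are excluded from s_ij, making ties
  deterministic in the analytic model.
- **Closed forms for δ < 1.** The printed two-class expressions assume
  the penalized support [0, 1/δ] sits inside the reference support. For
  δ < 1 (class 2 advantaged) they are evaluated through the model's
  rescaling invariance — swap the class roles and use δ' = 1/δ — which is
  exact; the integral engine needs no such case split and confirms the
  identity to ~10⁻¹².
- **Equidistant destinations in the simulator** are visited in uniformly
  random order per agent. The analytic model assigns identical tied
  destinations identical probability; any deterministic visit order
  would favour the first tied destination and make the simulator a
  biased oracle. (Exact ties are measure-zero for continuous
  coordinates; this only matters for constructed fixtures.)
- δ^(−x) is always computed as exp(−x ln δ).
- Distances: haversine with mean Earth radius 6371.0088 km for lat/lon
  input, Euclidean for planar km input, chosen from the input schema.
- Negative linearized probabilities (penalty too large for the linear
  regime) are clipped at 0 before normalization and counted in the
  returned matrix and the logs. The linear regime requires
  (m + s)(δ − 1) ≪ 1, which is why graded-ramp analyses use Δ of order
  10⁻⁷ when populations are of order 10⁵.
- Rows with zero outflow, or all-zero probability rows, are left as
  zeros (no imputation), logged.

## Class assignment

- **Binary top-percentile**: the top ⌈fraction·L⌉ locations by covariate
  (count-based cut, default fraction 0.15) form class 2; ties at the cut
  are resolved by stable input order and logged; multiple covariates
  combine as the union of penalized sets. Covariate preprocessing
  helpers: per-capita rates and mid-bin estimates for binned counts.
- **Linear ramp**: δ = 1 at or below the chosen percentile (linear
  interpolation estimator, numpy's default) and grows linearly to 1+Δ at
  the covariate maximum; each distinct δ is its own class. δ and Δ are
  inputs, never fitted — the model is deliberately free of optimization.

## Statistical comparison protocol

Given observed integer fluxes, both models redistribute the same
outflows T_i and the absolute error matrices are compared (diagonal
cells excluded — both models force T_ii = 0):

- **Mann–Whitney**, one-sided, alternative "modified errors
  stochastically smaller". For joint sample sizes ≤ 20 the p-value is an
  exact enumeration over all rank assignments under the mid-p convention
  (P(U<u) + ½P(U=u)); larger samples use the tie-corrected normal
  approximation without continuity correction. The two conventions are
  mutually consistent (identical samples give p = 0.5 under both) and
  agree to two decimals at joint sizes 15–20 for untied samples. With
  heavily tied samples at those sizes the exact distribution has
  probability steps larger than 0.01, so two-decimal agreement with any
  continuous approximation is impossible in principle; the asymptotic
  branch is only engaged at sample sizes where ties are averaged over
  hundreds of cells. An optional joint-zero filter removes cells where
  both models have zero error (used for commuting-style data where most
  cells are zero for both).
- **Hamming distance** (number of nonzero error cells) with an exact
  binomial test: the modified model's Hamming distance is referred to
  Binomial(L², p̂) with p̂ estimated from the standard model; the p-value
  is the exact CDF, accumulated term by term in log space.
- **Permutation null**: the modified model is re-run under random class
  assignments preserving class sizes (default 1000 repetitions for
  binary schemes, 200 for ramp schemes on large systems); the observed
  MW U and Hamming distance must fall below the 5% quantile of their
  null distributions.
- **Verdict**: the modified model is declared superior only when both
  parametric tests are significant at α = 0.05 *and* both permutation
  comparisons pass. Because the verdict is a conjunction, an option
  allows skipping the (expensive) permutation stage when the parametric
  tests already fail; the verdict is unchanged.

## Synthetic data

The generator stands in for field data: populations follow a Zipf
rank-size law (exponent 1, largest city 5·10⁴ by default; lognormal
optional), coordinates are uniform in a 500 km box, a penalized fraction
(default 0.15) forms true class 2 with true δ default 1+10⁻⁴, outflows
are T_i = round(0.0785·m_i) (the commuting-regression coefficient), and
observed OD counts are sampled multinomially from a chosen ground-truth
variant. The observable covariate is the true class indicator with a
configurable fraction of flips plus uniform jitter, so the
covariate-to-class machinery can be exercised end to end. Defaults were
chosen once as a realistic desk-scale regime: with total population
~2·10⁵, intervening populations reach 10⁴–10⁵, so a penalty of 10⁻⁴ per
draw produces order-one flux changes — the same compounding that makes
tiny δ−1 effective in real systems.

What the generator does not emulate: real settlement geography and
spatial correlation, survey noise and under-coverage in flow data,
heavy-tailed covariates correlated with population, temporal dynamics or
return migration. Passing tests therefore demonstrate internal
consistency and statistical behaviour under the model's own assumptions,
not fidelity to any particular country's data.

Problem sizes used in the tests and the acceptance script (L ≤ 50
systems for equivalence checks, L = 25 with 200 permutation repetitions
and 200 calibration replicates for the protocol, 10⁵ agents for
simulator agreement) were chosen to make every check sharp at desk
scale.

## Known limitations

- The uniform benefit density is an ansatz chosen for closed forms;
  heavy-tailed benefit distributions (e.g. Pareto income-like ones)
  would change long-range fluxes and are not implemented.
- Lexicographic preference for the nearest acceptable destination is a
  first-order approximation of choice behaviour; like all radiation-type
  models, predictions are statistical reconstructions, not cell-exact.
- The linearized model degrades (and clips) once (m+s)(δ−1) approaches
  1; use the closed forms or the integral engine there.
- Centroid averaging of raw lat/lon is inappropriate within a few
  degrees of the antimeridian.
- The binomial Hamming test treats cells as independent Bernoulli
  trials, ignoring row-sum constraints; it matches the protocol's usage
  as a comparative, not absolute, measure.
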