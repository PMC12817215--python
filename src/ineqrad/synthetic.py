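"""Synthetic urban systems and OD fluxes with known ground truth.

The generator emulates the ingredients of a real mobility study at desk
scale: heavy-tailed (Zipf rank-size or lognormal) populations scattered
uniformly in a planar box, a penalized subset of locations forming class
2 with a known true delta, a continuous inequality covariate that tracks
the true class up to configurable noise, and OD counts sampled
multinomially from a chosen ground-truth model variant.  It also provides
the two-city system used to illustrate the crossover where the penalized
larger city starts losing more people than it attracts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import ODMatrix, build_probability_matrix, modified_probability_two_class, predict_fluxes
from .locations import LocationTable, ValidationError, compute_distances
from .scheme import InequalityScheme

#: default fraction of a location's population that moves (T_i = f * m_i),
#: the value recovered by the commuting-data regression
DEFAULT_MOBILE_FRACTION = 0.0785


@dataclass(frozen=True)
class SyntheticSystemConfig:
    """Parameters of a generated system.

    ``population_law`` is ``"zipf"`` (rank-size: ``p_max / rank**zipf_exponent``)
    or ``"lognormal"``; locations are uniform in a ``box_km x box_km``
    square.  ``penalized_fraction`` of locations (ceil) form true class 2.
    The observable covariate equals the true class-2 indicator with
    ``covariate_flip_fraction`` of indicators flipped, plus Uniform(0,
    ``covariate_jitter``) to make it continuous for percentile cuts.
    """

    L: int = 30
    population_law: str = "zipf"
    zipf_exponent: float = 1.0
    p_max: int = 50_000
    lognormal_mu: float = 8.0
    lognormal_sigma: float = 1.0
    box_km: float = 500.0
    penalized_fraction: float = 0.15
    true_delta: float = 1.0 + 1e-4
    covariate_flip_fraction: float = 0.0
    covariate_jitter: float = 0.25
    mobile_fraction: float = DEFAULT_MOBILE_FRACTION

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValidationError("L must be >= 2")
        if self.population_law not in ("zipf", "lognormal"):
            raise ValidationError(f"unknown population law {self.population_law!r}")
        if self.box_km <= 0:
            raise ValidationError("degenerate box: box_km must be > 0")
        if not (0.0 < self.penalized_fraction < 1.0):
            raise ValidationError("penalized_fraction must lie in (0, 1)")
        if self.true_delta <= 0:
            raise ValidationError("true_delta must be > 0")


def generate_system(config: SyntheticSystemConfig, seed: int | np.random.Generator = 0):
    """Generate a reproducible system with known classes.

    Returns ``(LocationTable, InequalityScheme)``; the table carries the
    noisy ``covariate`` column and the true class labels, and the scheme
    maps class 2 to ``config.true_delta``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = config.L
    if config.population_law == "zipf":
        ranks = np.arange(1, L + 1, dtype=float)
        pops = np.maximum(1, np.round(config.p_max / ranks**config.zipf_exponent)).astype(np.int64)
        rng.shuffle(pops)
    else:
        pops = np.maximum(
            1, np.round(rng.lognormal(config.lognormal_mu, config.lognormal_sigma, size=L))
        ).astype(np.int64)
    coords = rng.uniform(0.0, config.box_km, size=(L, 2))
    k = math.ceil(config.penalized_fraction * L)
    penalized = rng.choice(L, size=k, replace=False)
    classes = np.ones(L, dtype=np.int64)
    classes[penalized] = 2
    indicator = (classes == 2).astype(float)
    flips = rng.random(L) < config.covariate_flip_fraction
    indicator[flips] = 1.0 - indicator[flips]
    covariate = indicator + rng.uniform(0.0, config.covariate_jitter, size=L)
    table = LocationTable(
        ids=np.array([f"loc{i:03d}" for i in range(L)], dtype=object),
        coords=coords,
        populations=pops,
        classes=classes,
        coord_system="planar",
        covariates=pd.DataFrame({"covariate": covariate}),
    )
    return table, InequalityScheme.two_class(config.true_delta)


def generate_od(
    system: LocationTable,
    scheme: InequalityScheme,
    model_variant: str = "two_class",
    mobile_fraction: float = DEFAULT_MOBILE_FRACTION,
    sampling: str = "expected",
    seed: int | np.random.Generator = 0,
    distances: np.ndarray | None = None,
) -> ODMatrix:
    """Ground-truth OD fluxes: ``T_i = round(f * m_i)`` redistributed by a model.

    ``sampling="expected"`` rounds ``T_i * p_ij``; ``"multinomial"``
    samples each origin's destinations multinomially (row sums then equal
    ``T_i`` exactly).
    """
    if sampling not in ("expected", "multinomial"):
        raise ValidationError(f"unknown sampling mode {sampling!r}")
    if distances is None:
        distances = compute_distances(system)
    P = build_probability_matrix(system, scheme, model_variant, distances=distances)
    T = np.floor(mobile_fraction * system.populations + 0.5).astype(np.int64)
    if sampling == "expected":
        return predict_fluxes(P, T, round_to_int=True)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(system)
    out = np.zeros((L, L), dtype=np.int64)
    for i in range(L):
        if T[i] == 0:
            continue
        row = P.matrix[i]
        if row.sum() <= 0:
            raise ValidationError(f"origin {i} has T_i > 0 but a zero-probability row")
        out[i] = rng.multinomial(T[i], row / row.sum())
    return ODMatrix(matrix=out, ids=system.ids)


def two_city_fixture(n1: int = 10_000, n2: int = 1_000_000, delta: float = 1.0):
    """Two-location system with the larger city penalized.

    Returns ``(system, scheme, p12, p21)`` with the *unnormalized*
    modified probabilities in both directions (with two locations there is
    no intervening population, so ``s = 0``).
    """
    if n1 < 1 or n2 < 1:
        raise ValidationError("city populations must be >= 1")
    system = LocationTable(
        ids=np.array(["city1", "city2"], dtype=object),
        coords=np.array([[0.0, 0.0], [100.0, 0.0]]),
        populations=np.array([n1, n2]),
        classes=np.array([1, 2]),
        coord_system="planar",
    )
    scheme = InequalityScheme.two_class(delta)
    p12 = modified_probability_two_class(n1, n2, 0, 0, 1, 2, delta)
    p21 = modified_probability_two_class(n2, n1, 0, 0, 2, 1, delta)
    return system, scheme, p12, p21


def two_city_probabilities(n1: int, n2: int, delta: float) -> tuple[float, float]:
    """Unnormalized (p12, p21) for the two-city system at a given delta."""
    _, _, p12, p21 = two_city_fixture(n1, n2, delta)
    return p12, p21


def crossover_delta(
    n1: int = 10_000,
    n2: int = 1_000_000,
    lo: float = 1.0,
    hi: float = 2.0,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> float:
    """Penalty delta* at which outflow from the penalized large city wins.

    Finds by bisection the delta where the unnormalized ``p21`` (from the
    penalized, larger city 2 to city 1) equals ``p12``; for delta beyond
    it, people are more likely to leave the large city than to move to it
    — unattainable under the standard model.  ``delta = 1`` must start
    with ``p12 > p21`` (the larger city attracts more).
    """

    def gap(delta: float) -> float:
        p12, p21 = two_city_probabilities(n1, n2, delta)
        return p21 - p12

    g_lo = gap(lo)
    if g_lo >= 0:
        raise ValidationError("no crossover: p21 >= p12 already at the lower delta")
    g_hi = gap(hi)
    while g_hi < 0:
        hi *= 2.0
        if hi > 1e6:
            raise ValidationError("no crossover found below delta = 1e6")
        g_hi = gap(hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if gap(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
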