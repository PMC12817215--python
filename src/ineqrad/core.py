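"""Analytic flux probabilities for the standard and inequality-aware radiation models.

The standard radiation model gives the probability that a mover from
origin i (population m) stops at destination j (population n) with total
intervening population s as::

    p_R = m * n / ((m + s) * (m + n + s))

The inequality-aware variant partitions locations into classes ``k`` with
benefit densities ``p^(k)(z) = delta_k * p(z * delta_k)``; for the uniform
reference density the two-class fluxes have closed forms (implemented in
:func:`modified_probability_two_class`), a first-order expansion in
``delta - 1`` (:func:`linearized_probability`), and for any number of
classes the defining order-statistic integral is evaluated exactly
piecewise (:func:`general_probability_integral`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .locations import (
    InterveningPopulation,
    LocationTable,
    ValidationError,
    compute_distances,
    intervening_population,
)
from .scheme import InequalityScheme

logger = logging.getLogger(__name__)

MODEL_VARIANTS = ("standard", "two_class", "linearized", "integral")

#: |delta - 1| band outside which the linearized closed form is warned about
LINEAR_WARN_BAND = 1e-2


@dataclass
class FluxProbabilityMatrix:
    """Row-normalized matrix of movement probabilities ``p_ij``.

    ``matrix`` has zero diagonal and every row with at least one positive
    entry sums to 1.  ``n_clipped`` counts linearized entries clipped at 0
    before normalization; ``zero_rows`` flags rows left all-zero.
    """

    matrix: np.ndarray
    model: str
    n_clipped: int = 0
    zero_rows: np.ndarray | None = None


@dataclass
class ODMatrix:
    """Origin-destination flux matrix ``T_ij`` with zero diagonal."""

    matrix: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValidationError("OD matrix must be square")
        if np.any(self.matrix < 0):
            raise ValidationError("OD fluxes must be non-negative")
        if np.any(np.diag(self.matrix) != 0):
            raise ValidationError("OD matrix must have a zero diagonal (p_ii = 0 convention)")

    @property
    def outflows(self) -> np.ndarray:
        """Total movers leaving each origin, T_i."""
        return self.matrix.sum(axis=1)


def radiation_probability(m, n, s):
    """Standard radiation probability ``m n / ((m+s)(m+n+s))``.

    Accepts scalars or broadcastable arrays; populations must be >= 1 and
    intervening populations >= 0.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(m < 1) or np.any(n < 1):
        raise ValidationError("populations m, n must be >= 1")
    if np.any(s < 0):
        raise ValidationError("intervening population s must be >= 0")
    out = m * n / ((m + s) * (m + n + s))
    return out.item() if out.ndim == 0 else out


def _powm(delta: float, exponent):
    """delta**(-exponent) via log space (robust for exponents up to ~1e6)."""
    return np.exp(-np.asarray(exponent, dtype=float) * math.log(delta))


def modified_probability_two_class(m, n, s1, s2, origin_class: int, dest_class: int, delta: float):
    """Closed-form two-class probability for the (origin -> destination) case.

    ``s1``/``s2`` are the class-1/class-2 intervening populations; class 2
    is penalized by ``delta`` (class 1 is the delta = 1 reference).  At
    ``delta = 1`` every case reduces exactly to the standard radiation
    probability with ``s = s1 + s2``.

    The closed forms assume the penalized support ``[0, 1/delta]`` lies
    inside the reference support, i.e. ``delta >= 1``.  For ``delta < 1``
    (class 2 advantaged) the model's invariance under a common rescaling of
    both benefit scales maps the system exactly onto a ``delta' = 1/delta
    > 1`` system with the class roles swapped, so that case is evaluated as
    the swapped closed form — still exact for any ``delta > 0``.
    """
    if delta <= 0:
        raise ValidationError(f"delta must be > 0, got {delta}")
    if origin_class not in (1, 2) or dest_class not in (1, 2):
        raise ValidationError("origin_class and dest_class must be 1 or 2")
    if delta < 1.0:
        return modified_probability_two_class(
            m, n, s2, s1, 3 - origin_class, 3 - dest_class, 1.0 / delta
        )
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if np.any(s1 < 0) or np.any(s2 < 0):
        raise ValidationError("intervening populations must be >= 0")
    s = s1 + s2
    pR = radiation_probability(m, n, s)
    case = (origin_class, dest_class)
    if case == (2, 1):
        out = pR * _powm(delta, s1) * (1.0 + (m + s) / n * (1.0 - _powm(delta, n)))
    elif case == (2, 2):
        out = pR * _powm(delta, s1)
    elif case == (1, 2):
        out = pR * _powm(delta, m + s1)
    else:  # (1, 1)
        out = pR * (
            s2 * (m + s) * _powm(delta, m + n + s1) / (n * (m + n + s1))
            + (m + s) * (m + n + s) / ((m + s1) * (m + n + s1))
            - s2 * (m + n + s) * _powm(delta, m + s1) / (n * (m + s1))
        )
    return out.item() if np.ndim(out) == 0 else out


def linearized_rho(m, n, s1, s2, origin_class: int, dest_class: int):
    """First-order coefficient rho in ``p = p_R [1 + rho (delta - 1)]``.

    The four two-class cases: rho(2->1) = m + s2, rho(2->2) = -s1,
    rho(1->2) = -m - s1, rho(1->1) = s2.
    """
    m = np.asarray(m, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    s = s1 + s2
    # equivalently s2 + m*[origin penalized] - (m+s)*[destination penalized]
    return s2 + (m if origin_class == 2 else 0.0) - ((m + s) if dest_class == 2 else 0.0)


def linearized_probability(
    m, n, s1, s2, origin_class: int, dest_class: int, delta: float, warn_band: float = LINEAR_WARN_BAND
):
    """Two-class probability linearized around delta = 1.

    Accurate to O((delta-1)^2); a warning is logged when ``|delta - 1|``
    exceeds ``warn_band``.  Values driven below zero by a large expansion
    term are clipped at 0 (and logged).
    """
    if delta <= 0:
        raise ValidationError(f"delta must be > 0, got {delta}")
    if abs(delta - 1.0) > warn_band:
        logger.warning("linearized model used outside its |delta-1| <= %g band (delta=%g)", warn_band, delta)
    pR = radiation_probability(m, n, np.asarray(s1, float) + np.asarray(s2, float))
    rho = linearized_rho(m, n, s1, s2, origin_class, dest_class)
    out = pR * (1.0 + rho * (delta - 1.0))
    n_neg = int(np.sum(np.asarray(out) < 0))
    if n_neg:
        logger.warning("linearized probability clipped at 0 for %d value(s)", n_neg)
        out = np.clip(out, 0.0, None)
    return out.item() if np.ndim(out) == 0 else out


def _log_power_integral(a: float, b: float, p: float) -> float:
    """log of the integral of z**p over [a, b], for 0 <= a < b and p > -1."""
    lb = (p + 1.0) * math.log(b)
    if a <= 0.0:
        return lb - math.log(p + 1.0)
    ratio = (p + 1.0) * (math.log(a) - math.log(b))
    return lb + math.log1p(-math.exp(ratio)) - math.log(p + 1.0)


def general_probability_integral(
    m: float,
    n: float,
    s_by_class,
    origin_class: int,
    dest_class: int,
    deltas,
) -> float:
    """Movement probability from the defining order-statistic integral.

    Evaluates, for uniform benefit distributions scaled per class,

    ``P = \\int_0^{1/delta_o} P_m(z) * prod_k F_k(z)**s_k * (1 - F_d(z)**n) dz``

    where ``P_m`` is the density of the maximum of m draws from the origin
    class (``m * delta_o**m * z**(m-1)`` on its support) and ``F_k(z) =
    min(1, delta_k z)`` is the class-k CDF.  The integrand is piecewise
    polynomial with breakpoints at the support ends ``1/delta_k``; each
    piece is integrated exactly in log space.  Works for any number of
    classes and any positive deltas.
    """
    deltas = np.asarray(deltas, dtype=float)
    s_by_class = np.asarray(s_by_class, dtype=float)
    if deltas.ndim != 1 or s_by_class.shape != deltas.shape:
        raise ValidationError("deltas and s_by_class must be 1-D with one entry per class")
    if np.any(deltas <= 0):
        raise ValidationError("all deltas must be > 0")
    if np.any(s_by_class < 0):
        raise ValidationError("intervening populations must be >= 0")
    C = len(deltas)
    if not (1 <= origin_class <= C and 1 <= dest_class <= C):
        raise ValidationError("origin/destination class out of range")
    if m < 1 or n < 1:
        raise ValidationError("populations m, n must be >= 1")
    d_o = deltas[origin_class - 1]
    d_d = deltas[dest_class - 1]
    supports = 1.0 / deltas
    z_max = supports[origin_class - 1]
    z_dest = supports[dest_class - 1]
    cuts = np.unique(np.concatenate([supports, [z_max, z_dest]]))
    cuts = cuts[cuts <= z_max * (1.0 + 1e-15)]
    edges = np.concatenate([[0.0], cuts])
    total = 0.0
    log_base = math.log(m) + m * math.log(d_o)
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a <= 1e-300:
            continue
        if a >= z_dest * (1.0 - 1e-15):
            continue  # destination CDF saturated: integrand is 0
        active = supports >= b * (1.0 - 1e-12)
        alpha = (m - 1.0) + float(s_by_class[active].sum())
        logC = log_base + float((s_by_class[active] * np.log(deltas[active])).sum())
        term1 = math.exp(logC + _log_power_integral(a, b, alpha))
        term2 = math.exp(logC + n * math.log(d_d) + _log_power_integral(a, b, alpha + n))
        total += term1 - term2
    return min(max(total, 0.0), 1.0)


def build_probability_matrix(
    locations: LocationTable,
    scheme: InequalityScheme | None = None,
    model: str = "standard",
    distances: np.ndarray | None = None,
    intervening: InterveningPopulation | None = None,
    normalize: bool = True,
) -> FluxProbabilityMatrix:
    """Full L x L movement-probability matrix for a model variant.

    ``model`` is one of ``standard`` (ignores classes), ``two_class``
    (nonlinear closed forms, requires exactly two classes), ``linearized``
    (first-order in each ``delta_k - 1``, any number of classes) or
    ``integral`` (exact order-statistic integral, any number of classes).
    The diagonal is zero and rows are normalized to sum to 1; rows that are
    all zero before normalization are left as zeros and logged.
    """
    if model not in MODEL_VARIANTS:
        raise ValidationError(f"unknown model {model!r}; choose from {MODEL_VARIANTS}")
    if distances is None:
        distances = compute_distances(locations)
    if intervening is None:
        intervening = intervening_population(locations, distances)
    L = len(locations)
    pops = locations.populations.astype(float)
    m = pops[:, None]
    n = pops[None, :]
    s = intervening.s_total.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pR = m * n / ((m + s) * (m + n + s))
    n_clipped = 0

    if model == "standard":
        P = pR
    else:
        if scheme is None:
            raise ValidationError(f"model {model!r} requires an InequalityScheme")
        deltas = scheme.delta_array()
        C_table = locations.n_classes
        if scheme.n_classes < C_table:
            raise ValidationError("scheme does not cover every class in the table")
        C = scheme.n_classes
        sk = np.zeros((C, L, L))
        sk[: intervening.n_classes] = intervening.s_by_class.astype(float)
        if model == "two_class":
            if C != 2:
                raise ValidationError("two_class model requires exactly 2 classes")
            delta = deltas[1]
            s1, s2 = sk[0], sk[1]
            P = np.empty((L, L))
            oc = locations.classes[:, None]
            dc = locations.classes[None, :]
            for a in (1, 2):
                for b in (1, 2):
                    mask = (oc == a) & (dc == b)
                    if np.any(mask):
                        P[mask] = np.asarray(
                            modified_probability_two_class(
                                np.broadcast_to(m, (L, L))[mask],
                                np.broadcast_to(n, (L, L))[mask],
                                s1[mask],
                                s2[mask],
                                a,
                                b,
                                delta,
                            )
                        )
        elif model == "linearized":
            eps = deltas - 1.0  # per-class delta_k - 1
            if np.any(np.abs(eps) > LINEAR_WARN_BAND):
                logger.warning(
                    "linearized model used with max |delta-1| = %g outside its %g band",
                    np.abs(eps).max(),
                    LINEAR_WARN_BAND,
                )
            rho_sum = np.tensordot(eps, sk, axes=(0, 0))
            eps_loc = eps[locations.classes - 1]
            rho_sum += m * eps_loc[:, None] - (m + s) * eps_loc[None, :]
            P = pR * (1.0 + rho_sum)
            neg = P < 0
            np.fill_diagonal(neg, False)
            n_clipped = int(neg.sum())
            if n_clipped:
                logger.warning("clipped %d negative linearized probabilities at 0", n_clipped)
                P = np.clip(P, 0.0, None)
        else:  # integral
            P = np.zeros((L, L))
            classes = locations.classes
            for i in range(L):
                for j in range(L):
                    if i == j:
                        continue
                    P[i, j] = general_probability_integral(
                        pops[i], pops[j], sk[:, i, j], int(classes[i]), int(classes[j]), deltas
                    )
    P = np.array(P, dtype=float)
    np.fill_diagonal(P, 0.0)
    zero_rows = P.sum(axis=1) == 0
    if normalize:
        if np.any(zero_rows):
            logger.warning("%d row(s) are all zero before normalization; left as zeros", int(zero_rows.sum()))
        sums = P.sum(axis=1, keepdims=True)
        P = np.divide(P, sums, out=np.zeros_like(P), where=sums > 0)
    return FluxProbabilityMatrix(matrix=P, model=model, n_clipped=n_clipped, zero_rows=zero_rows)


def predict_fluxes(P: FluxProbabilityMatrix, outflows, round_to_int: bool = True) -> ODMatrix:
    """Predicted OD fluxes ``T_ij = T_i * p_ij``.

    ``outflows`` is the per-origin total ``T_i``; with ``round_to_int``
    fluxes are rounded to the closest integer (ties half away from zero).
    """
    T = np.asarray(outflows, dtype=float)
    if T.ndim != 1 or len(T) != P.matrix.shape[0]:
        raise ValidationError("outflows must be a vector of length L")
    if np.any(T < 0):
        raise ValidationError("outflows must be non-negative")
    flux = T[:, None] * P.matrix
    if round_to_int:
        flux = np.floor(flux + 0.5)  # half away from zero (entries are >= 0)
        flux = flux.astype(np.int64)
    return ODMatrix(matrix=flux)


def estimate_mobile_fraction(observed: ODMatrix, locations: LocationTable) -> float:
    """Fraction of each population that moves, from a no-intercept regression.

    Fits ``T_i = f * m_i`` by least squares on the observed outflow totals,
    returning the slope f (the US-commuting analysis uses f = 0.0785).
    """
    pops = locations.populations.astype(float)
    if np.all(pops == 0):
        raise ValidationError("populations are all zero")
    T = observed.outflows.astype(float)
    slope, *_ = np.linalg.lstsq(pops[:, None], T, rcond=None)
    return float(slope[0])
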