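"""Mapping inequality covariates to location classes and penalty scales.

Two schemes are supported, mirroring the two study designs the model was
built for:

* **binary top-percentile**: the top fraction (default 15%) of locations
  by a covariate (e.g. conflict casualties per capita, flood exposure)
  form a single penalized class with a common ``delta = 1 + 10**n``;
  multiple covariates combine as the union of their penalized sets.
* **linear delta ramp**: locations above the 90th percentile of a
  socioeconomic covariate get a ``delta`` growing linearly from 1 at the
  percentile to ``1 + Delta`` at the covariate maximum; every distinct
  ``delta`` is its own class, so there are (number above the percentile)
  plus one classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .locations import ValidationError
from .scheme import InequalityScheme

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PenalizationRule:
    """Configuration of a covariate-to-class scheme.

    ``scheme`` is ``binary_top_pct`` (fields ``fraction``, ``delta``) or
    ``linear_ramp`` (fields ``percentile``, ``Delta``); ``covariates``
    names the column(s), combined as a union for the binary scheme.
    """

    scheme: str
    covariates: tuple[str, ...]
    fraction: float = 0.15
    delta: float = 1.0 + 1e-4
    percentile: float = 90.0
    Delta: float = 1e-7
    combine: str = "union"

    def __post_init__(self) -> None:
        if self.scheme not in ("binary_top_pct", "linear_ramp"):
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        if not (0.0 < self.fraction < 1.0):
            raise ValidationError("fraction must lie in (0, 1)")
        if not (0.0 < self.percentile < 100.0):
            raise ValidationError("percentile must lie in (0, 100)")
        if self.delta <= 0 or self.Delta <= 0:
            raise ValidationError("delta and Delta must be > 0")
        if self.combine != "union":
            raise ValidationError("only union combination of covariates is supported")


def per_capita(values, populations):
    """Elementwise rate ``values / populations`` (e.g. casualties per capita)."""
    values = np.asarray(values, dtype=float)
    populations = np.asarray(populations, dtype=float)
    if np.any(populations <= 0):
        raise ValidationError("populations must be > 0 for per-capita rates")
    return values / populations


def mid_bin(bin_lower, bin_width):
    """Mid-point estimate for covariates reported in count bins.

    Used when a covariate (e.g. people affected by floods) is only known
    at a coarse resolution: a location in bin ``[lower, lower + width)``
    is assigned ``lower + width / 2``.
    """
    return np.asarray(bin_lower, dtype=float) + float(bin_width) / 2.0


def assign_binary_top(values, fraction_penalized: float = 0.15) -> np.ndarray:
    """Binary class labels: the top ``ceil(fraction * L)`` locations get class 2.

    The cut is count-based (exactly ``ceil(fraction * L)`` penalized
    absent ties at the boundary); ties at the cut value are resolved by
    stable original order, which is logged.  A constant covariate makes
    the penalized set order-dependent and triggers a warning.
    """
    values = np.asarray(values, dtype=float)
    L = len(values)
    if not (0.0 < fraction_penalized < 1.0):
        raise ValidationError("fraction_penalized must lie in (0, 1)")
    k = math.ceil(fraction_penalized * L)
    if k < 1 or k >= L:
        raise ValidationError(f"penalized count {k} must leave both classes non-empty (L={L})")
    if np.all(values == values[0]):
        logger.warning("constant covariate: penalized set depends only on location order")
    # stable sort descending by value: ties keep original (id) order
    order = np.argsort(-values, kind="stable")
    labels = np.ones(L, dtype=np.int64)
    labels[order[:k]] = 2
    cut = values[order[k - 1]]
    n_tied = int(np.sum(values == cut))
    if n_tied > 1 and np.sum(values >= cut) > k:
        logger.warning(
            "tie at the penalization cut value %g (%d locations); resolved by stable order", cut, n_tied
        )
    return labels


def union_binary_top(value_columns, fraction_penalized: float = 0.15) -> np.ndarray:
    """Union of per-covariate penalized sets: class 2 if penalized under any."""
    labels = None
    for values in value_columns:
        lab = assign_binary_top(values, fraction_penalized)
        labels = lab if labels is None else np.maximum(labels, lab)
    if labels is None:
        raise ValidationError("at least one covariate column required")
    return labels


def assign_linear_ramp(values, pct: float = 90.0, Delta: float = 1e-7) -> np.ndarray:
    """Per-location delta from the linear ramp above a percentile.

    ``delta = 1`` at or below the percentile ``q`` (linear-interpolation
    estimator) and ``delta = 1 + Delta * (v - q) / (v_max - q)`` above it,
    so the covariate maximum gets exactly ``1 + Delta``.
    """
    values = np.asarray(values, dtype=float)
    if Delta <= 0:
        raise ValidationError("Delta must be > 0")
    q = float(np.percentile(values, pct))
    v_max = float(values.max())
    if v_max <= q:
        raise ValidationError(
            f"degenerate ramp: covariate maximum {v_max} does not exceed the {pct}th percentile {q}"
        )
    deltas = np.ones_like(values)
    above = values > q
    deltas[above] = 1.0 + Delta * (values[above] - q) / (v_max - q)
    return deltas


def ramp_scheme(values, pct: float = 90.0, Delta: float = 1e-7):
    """Scheme and class labels from the linear ramp.

    Each distinct delta value becomes its own class (class 1 is delta = 1),
    giving ``#locations above the percentile (with distinct values) + 1``
    classes.  Returns ``(InequalityScheme, class_labels)``.
    """
    deltas = assign_linear_ramp(values, pct=pct, Delta=Delta)
    return InequalityScheme.from_location_deltas(deltas)
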