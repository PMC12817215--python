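"""Class-to-penalty mapping for the inequality-aware radiation model.

Every location class ``k = 1..C`` carries a scale factor ``delta_k > 0``
that compresses its benefit distribution: the class-k density is
``p^(k)(z) = delta_k * p(z * delta_k)`` for a common reference density
``p``.  Class 1 is the unpenalized reference (``delta_1 = 1``);
``delta_k > 1`` means class k offers worse opportunities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .locations import LocationTable, ValidationError


@dataclass(frozen=True)
class InequalityScheme:
    """Map from class label to its benefit-scale factor ``delta_k``."""

    delta_of_class: dict[int, float]

    def __post_init__(self) -> None:
        deltas = self.delta_of_class
        if not deltas:
            raise ValidationError("scheme must cover at least class 1")
        for k, d in deltas.items():
            if d <= 0:
                raise ValidationError(f"delta for class {k} must be > 0, got {d}")
        if 1 not in deltas:
            raise ValidationError("class 1 (the reference) must be present")

    @property
    def n_classes(self) -> int:
        return max(self.delta_of_class)

    def delta_array(self) -> np.ndarray:
        """Deltas indexed by class, as a length-C array (class k at k-1)."""
        C = self.n_classes
        out = np.empty(C, dtype=float)
        for k in range(1, C + 1):
            if k not in self.delta_of_class:
                raise ValidationError(f"scheme does not cover class {k}")
            out[k - 1] = self.delta_of_class[k]
        return out

    def deltas_for(self, locations: LocationTable) -> np.ndarray:
        """Per-location delta values."""
        arr = self.delta_array()
        if locations.n_classes > self.n_classes:
            raise ValidationError(
                f"scheme covers classes 1..{self.n_classes} but table has "
                f"{locations.n_classes}"
            )
        return arr[locations.classes - 1]

    @classmethod
    def uniform(cls) -> "InequalityScheme":
        """The no-inequality scheme (standard radiation model)."""
        return cls({1: 1.0})

    @classmethod
    def two_class(cls, delta: float) -> "InequalityScheme":
        """Binary scheme: class 1 reference, class 2 penalized by ``delta``."""
        return cls({1: 1.0, 2: float(delta)})

    @classmethod
    def from_location_deltas(cls, per_location_delta: np.ndarray):
        """Build a scheme and class labels from per-location delta values.

        Each distinct delta becomes its own class; delta == 1 is class 1 and
        larger deltas get increasing labels.  Returns ``(scheme, classes)``.
        """
        d = np.asarray(per_location_delta, dtype=float)
        if np.any(d <= 0):
            raise ValidationError("per-location deltas must be > 0")
        uniq = np.unique(d)
        if uniq[0] != 1.0:
            uniq = np.concatenate([[1.0], uniq[uniq != 1.0]])
        else:
            uniq = np.concatenate([[1.0], uniq[1:]])
        mapping = {float(v): k + 1 for k, v in enumerate(uniq)}
        classes = np.array([mapping[float(v)] for v in d], dtype=np.int64)
        scheme = cls({k: float(v) for v, k in mapping.items()})
        return scheme, classes
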