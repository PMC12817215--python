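"""Urban-system container, distance matrices and intervening populations.

The radiation-model family operates on a set of L locations with
populations, pairwise distances and (for the inequality-aware variants) a
class label per location.  This module holds the :class:`LocationTable`
container and the purely geometric derived quantities: the symmetric
distance matrix ``r_ij`` and the intervening-population tensors ``s_ij``
and ``s_ij^(k)`` (population strictly inside the circle of radius ``r_ij``
centred at the origin, excluding origin and destination, total and split
by class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: mean Earth radius in km, used for great-circle distances
EARTH_RADIUS_KM = 6371.0088


class ValidationError(ValueError):
    """Raised when an input table violates a model precondition."""


@dataclass
class LocationTable:
    """A system of L locations.

    Parameters
    ----------
    ids
        Unique location labels (length L).
    coords
        ``(L, 2)`` array.  Interpreted as ``(lat, lon)`` in degrees when
        ``coord_system="lonlat"`` or ``(x, y)`` in km when ``"planar"``.
    populations
        Positive integers; ``m_i`` when the location acts as an origin,
        ``n_j`` as a destination.
    classes
        Integer class labels ``c_i`` forming a contiguous set ``1..C``.
        Defaults to all ones (the homogeneous, standard-radiation system).
    covariates
        Optional per-location real-valued columns (inequality proxies).
    """

    ids: np.ndarray
    coords: np.ndarray
    populations: np.ndarray
    classes: np.ndarray | None = None
    coord_system: str = "planar"
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.populations = np.asarray(self.populations)
        if self.classes is None:
            self.classes = np.ones(len(self.ids), dtype=np.int64)
        self.classes = np.asarray(self.classes, dtype=np.int64)
        L = len(self.ids)
        if L < 2:
            raise ValidationError("a mobility system needs at least 2 locations")
        if len(np.unique(self.ids)) != L:
            raise ValidationError("location ids must be unique")
        if self.coords.shape != (L, 2):
            raise ValidationError(f"coords must have shape ({L}, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        if self.coord_system not in ("lonlat", "planar"):
            raise ValidationError(f"unknown coord_system {self.coord_system!r}")
        if self.coord_system == "lonlat":
            lat, lon = self.coords[:, 0], self.coords[:, 1]
            if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
                raise ValidationError("lat must lie in [-90, 90], lon in [-180, 180]")
        if not np.issubdtype(self.populations.dtype, np.number):
            raise ValidationError("populations must be numeric")
        if np.any(self.populations < 1):
            bad = self.ids[self.populations < 1]
            raise ValidationError(f"populations must be >= 1 (offending ids: {list(bad)})")
        self.populations = self.populations.astype(np.int64)
        if self.classes.shape != (L,):
            raise ValidationError("classes must be one label per location")
        present = np.unique(self.classes)
        if present[0] != 1 or not np.array_equal(present, np.arange(1, len(present) + 1)):
            raise ValidationError(
                "class labels must form a contiguous set starting at 1; got "
                f"{present.tolist()}"
            )
        if self.covariates is not None and len(self.covariates) != L:
            raise ValidationError("covariates must have one row per location")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_classes(self) -> int:
        return int(self.classes.max())

    def with_classes(self, classes: np.ndarray) -> "LocationTable":
        """Return a copy of the table with a new class assignment."""
        return LocationTable(
            ids=self.ids.copy(),
            coords=self.coords.copy(),
            populations=self.populations.copy(),
            classes=np.asarray(classes, dtype=np.int64).copy(),
            coord_system=self.coord_system,
            covariates=None if self.covariates is None else self.covariates.copy(),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LocationTable":
        """Build a table from a dataframe with the standard column schema.

        Requires ``id`` and ``population``; coordinates either as
        ``lat``/``lon`` (degrees) or ``x_km``/``y_km``; optional ``class``;
        every remaining column is kept as a covariate.
        """
        cols = set(df.columns)
        for required in ("id", "population"):
            if required not in cols:
                raise ValidationError(f"missing required column {required!r}")
        has_geo = {"lat", "lon"} <= cols
        has_planar = {"x_km", "y_km"} <= cols
        if has_geo and has_planar:
            raise ValidationError("both lat/lon and x_km/y_km present: ambiguous coordinate system")
        if has_geo:
            coords = df[["lat", "lon"]].to_numpy(float)
            system = "lonlat"
        elif has_planar:
            coords = df[["x_km", "y_km"]].to_numpy(float)
            system = "planar"
        else:
            raise ValidationError("need either lat/lon or x_km/y_km coordinate columns")
        pops = df["population"].to_numpy()
        bad = np.flatnonzero(~(pops >= 1))
        if bad.size:
            raise ValidationError(
                f"population must be >= 1; offending row(s) {bad.tolist()} "
                f"(id {df['id'].iloc[bad[0]]!r})"
            )
        classes = df["class"].to_numpy(np.int64) if "class" in cols else None
        reserved = {"id", "population", "class", "lat", "lon", "x_km", "y_km"}
        covs = [c for c in df.columns if c not in reserved]
        return cls(
            ids=df["id"].astype(str).to_numpy(object),
            coords=coords,
            populations=pops,
            classes=classes,
            coord_system=system,
            covariates=df[covs].reset_index(drop=True) if covs else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        if self.coord_system == "lonlat":
            out = pd.DataFrame({"id": self.ids, "lat": self.coords[:, 0], "lon": self.coords[:, 1]})
        else:
            out = pd.DataFrame({"id": self.ids, "x_km": self.coords[:, 0], "y_km": self.coords[:, 1]})
        out["population"] = self.populations
        out["class"] = self.classes
        if self.covariates is not None:
            for c in self.covariates.columns:
                out[c] = self.covariates[c].to_numpy()
        return out


@dataclass
class InterveningPopulation:
    """Intervening-population tensors.

    ``s_total[i, j]`` is the total population strictly within distance
    ``r_ij`` of origin i, excluding i and j; ``s_by_class[k-1, i, j]`` its
    class-k part.  ``s_total == s_by_class.sum(axis=0)`` exactly.
    """

    s_total: np.ndarray
    s_by_class: np.ndarray = field(repr=False)

    @property
    def n_classes(self) -> int:
        return self.s_by_class.shape[0]


def haversine_matrix(latlon_deg: np.ndarray, radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Pairwise great-circle distances in km for ``(lat, lon)`` degrees."""
    lat = np.radians(latlon_deg[:, 0])[:, None]
    lon = np.radians(latlon_deg[:, 1])[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * radius_km * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    return d


def compute_distances(locations: LocationTable, metric: str = "auto") -> np.ndarray:
    """Symmetric zero-diagonal distance matrix ``r_ij`` in km.

    ``metric="auto"`` picks haversine for lat/lon tables and Euclidean for
    planar ones; requesting the metric that does not match the coordinate
    system is a configuration error.
    """
    if metric == "auto":
        metric = "haversine" if locations.coord_system == "lonlat" else "euclidean"
    if metric == "haversine":
        if locations.coord_system != "lonlat":
            raise ValidationError("haversine distances require lat/lon coordinates")
        return haversine_matrix(locations.coords)
    if metric == "euclidean":
        if locations.coord_system != "planar":
            raise ValidationError("euclidean distances require planar km coordinates")
        diff = locations.coords[:, None, :] - locations.coords[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
        np.fill_diagonal(d, 0.0)
        return d
    raise ValidationError(f"unknown metric {metric!r}")


def intervening_population(
    locations: LocationTable, distances: np.ndarray
) -> InterveningPopulation:
    """Per-class intervening populations ``s_ij^(k)``.

    Membership in the circle is strict (``r_il < r_ij``): locations exactly
    at distance ``r_ij`` — including the destination itself — are excluded,
    which makes equidistant ties deterministic.
    """
    L = len(locations)
    C = locations.n_classes
    pops = locations.populations.astype(np.int64)
    s_by_class = np.zeros((C, L, L), dtype=np.int64)
    for i in range(L):
        d = distances[i]
        order = np.argsort(d, kind="stable")
        sorted_d = d[order]
        for k in range(1, C + 1):
            pk = np.where(locations.classes[order] == k, pops[order], 0)
            cum = np.concatenate([[0], np.cumsum(pk)])
            # number of locations strictly closer than each destination
            idx = np.searchsorted(sorted_d, d, side="left")
            s = cum[idx]
            # origin i sits at distance 0 and is counted whenever d_ij > 0
            if locations.classes[i] == k:
                s = s - np.where(d > 0, pops[i], 0)
            s_by_class[k - 1, i] = s
        s_by_class[:, i, i] = 0
    s_total = s_by_class.sum(axis=0)
    return InterveningPopulation(s_total=s_total, s_by_class=s_by_class)
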