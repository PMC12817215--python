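"""CSV readers/writers, preprocessing helpers and run metadata.

Formats are deliberately minimal: a location table CSV (``id`` plus
``lat``/``lon`` or ``x_km``/``y_km``, ``population``, optional ``class``
and covariate columns) and a long-format OD CSV
(``origin_id, destination_id, flux``) where absent pairs are zero.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ODMatrix
from .locations import LocationTable, ValidationError

logger = logging.getLogger(__name__)


def read_locations(path) -> LocationTable:
    """Read and validate a location table CSV."""
    df = pd.read_csv(path)
    if df["id"].duplicated().any() if "id" in df.columns else False:
        dupes = df["id"][df["id"].duplicated()].unique()
        raise ValidationError(f"duplicate location id(s): {list(dupes)}")
    return LocationTable.from_dataframe(df)


def write_locations(locations: LocationTable, path) -> None:
    locations.to_dataframe().to_csv(path, index=False)


def read_od(path, location_ids) -> ODMatrix:
    """Read a long-format OD CSV into a dense matrix.

    Pairs absent from the file are zero; duplicate (origin, destination)
    pairs are summed with a warning; unknown ids, negative fluxes and
    diagonal entries are rejected (the model convention fixes p_ii = 0,
    so within-location flux has no place in the matrix).
    """
    df = pd.read_csv(path)
    for col in ("origin_id", "destination_id", "flux"):
        if col not in df.columns:
            raise ValidationError(f"OD file is missing column {col!r}")
    ids = np.asarray(location_ids, dtype=object)
    index = {str(v): i for i, v in enumerate(ids)}
    L = len(ids)
    mat = np.zeros((L, L), dtype=np.int64)
    if df.duplicated(subset=["origin_id", "destination_id"]).any():
        logger.warning("duplicate (origin, destination) pairs in OD file: fluxes summed")
    for origin, dest, flux in df[["origin_id", "destination_id", "flux"]].itertuples(index=False):
        o, d = str(origin), str(dest)
        if o not in index or d not in index:
            unknown = o if o not in index else d
            raise ValidationError(f"unknown location id {unknown!r} in OD file")
        if o == d:
            raise ValidationError(
                f"diagonal OD entry for {o!r}: within-location flux is excluded (p_ii = 0 convention)"
            )
        if flux < 0:
            raise ValidationError(f"negative flux {flux} for pair ({o}, {d})")
        mat[index[o], index[d]] += int(flux)
    return ODMatrix(matrix=mat, ids=ids)


def write_od(od: ODMatrix, path, location_ids=None) -> None:
    """Write an OD matrix as long-format CSV (nonzero pairs only)."""
    ids = od.ids if od.ids is not None else location_ids
    if ids is None:
        raise ValidationError("location ids required to write an OD matrix")
    rows = []
    nz = np.argwhere(od.matrix > 0)
    for i, j in nz:
        rows.append((ids[i], ids[j], int(od.matrix[i, j])))
    pd.DataFrame(rows, columns=["origin_id", "destination_id", "flux"]).to_csv(path, index=False)


def centroid_from_settlements(settlements: pd.DataFrame, region_col: str = "region", lat_col: str = "lat", lon_col: str = "lon") -> pd.DataFrame:
    """Region centroids as unweighted means of settlement coordinates.

    Averaging is done on raw lat/lon, adequate away from the
    antimeridian; regions listed with no settlements raise an error.
    """
    if settlements.empty:
        raise ValidationError("no settlements provided")
    missing = settlements[settlements[[lat_col, lon_col]].isna().any(axis=1)][region_col].unique()
    if len(missing):
        raise ValidationError(f"regions with missing settlement coordinates: {list(missing)}")
    out = (
        settlements.groupby(region_col, sort=True)[[lat_col, lon_col]].mean().reset_index()
    )
    return out


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_metadata(path, *, model: str, seed=None, metric: str | None = None, deltas=None, n_clipped: int = 0, inputs: dict | None = None, extra: dict | None = None) -> None:
    """Record everything needed to reproduce a run bit-for-bit."""
    from . import __version__

    record = {
        "package": "ineqrad",
        "version": __version__,
        "model": model,
        "metric": metric,
        "deltas": deltas,
        "seed": seed,
        "n_clipped": n_clipped,
        "inputs": {k: file_sha256(v) for k, v in (inputs or {}).items()},
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
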