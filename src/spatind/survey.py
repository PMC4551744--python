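"""Survey data model, CSV I/O and geographic -> planar coordinate handling.

Acoustic surveys record fish density (t/nmi^2) along vessel transects in
Elementary Distance Sampling Units (EDSUs) of one nautical mile.  Every EDSU
carries an *area of influence* ``s`` (nmi^2), the surface it represents in
spatial integrals; all downstream indicators weight densities by ``s``.

Positions arrive as WGS84 longitude/latitude.  Indicator mathematics runs on
planar coordinates in nautical miles, obtained by a local equirectangular
projection about a dataset origin: one minute of latitude is one nautical
mile, and longitude minutes are compressed by ``cos(lat0)``.  At survey
extents of a couple hundred miles the metric distortion is well below 1%.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SurveyDataset",
    "SurveyValidationError",
    "project_coordinates",
    "inverse_project",
    "read_survey_csv",
    "write_survey_csv",
    "load_schema",
]

#: canonical non-density columns, in file order
CORE_COLUMNS = ("survey_year", "sub_area", "transect_id", "lon", "lat", "area_influence")
DENSITY_PREFIX = "density_"


class SurveyValidationError(ValueError):
    """Raised when survey records violate the data contract."""


def _density_col(species: str) -> str:
    return DENSITY_PREFIX + species


@dataclasses.dataclass
class SurveyDataset:
    """An ordered table of EDSU records for one or more species.

    Parameters
    ----------
    data:
        One row per EDSU.  Required columns: ``survey_year``, ``sub_area``,
        ``transect_id``, ``lon``, ``lat``, ``area_influence`` and one
        ``density_<species>`` column per species.  Optional ``x``/``y``
        hold projected positions in nmi (see :func:`project_coordinates`).
    species:
        Species labels, one per density column.
    origin:
        ``(lon0, lat0)`` of the planar projection.  Defaults to the
        arithmetic mean position of the records when projecting.
    """

    data: pd.DataFrame
    species: tuple[str, ...]
    origin: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        missing += [_density_col(sp) for sp in self.species if _density_col(sp) not in df.columns]
        if missing:
            raise SurveyValidationError(f"missing mandatory column(s): {missing}")
        for sp in self.species:
            col = df[_density_col(sp)]
            if col.isna().any():
                rows = df.index[col.isna()].tolist()
                raise SurveyValidationError(f"missing density for {sp!r} at row(s) {rows}")
            bad = df.index[col < 0].tolist()
            if bad:
                raise SurveyValidationError(f"negative density for {sp!r} at row(s) {bad}")
        bad = df.index[~(df["area_influence"] > 0)].tolist()
        if bad:
            raise SurveyValidationError(f"non-positive area_influence at row(s) {bad}")
        bad = df.index[(df["lat"] < -90) | (df["lat"] > 90)].tolist()
        if bad:
            raise SurveyValidationError(f"latitude outside [-90, 90] at row(s) {bad}")
        bad = df.index[(df["lon"] < -180) | (df["lon"] > 180)].tolist()
        if bad:
            raise SurveyValidationError(f"longitude outside [-180, 180] at row(s) {bad}")
        dup = df.duplicated(subset=["survey_year", "sub_area", "transect_id", "lon", "lat"])
        if dup.any():
            raise SurveyValidationError(
                f"duplicate (year, sub_area, transect, position) at row(s) {df.index[dup].tolist()}")

    # -- accessors --------------------------------------------------------
    def density(self, species: str) -> np.ndarray:
        """Density values z (t/nmi^2) for one species, in record order."""
        if species not in self.species:
            raise KeyError(f"unknown species {species!r}; have {self.species}")
        return self.data[_density_col(species)].to_numpy(dtype=float)

    @property
    def area_influence(self) -> np.ndarray:
        return self.data["area_influence"].to_numpy(dtype=float)

    @property
    def has_projection(self) -> bool:
        return "x" in self.data.columns and "y" in self.data.columns

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Projected coordinates in nmi; projects on the fly if needed."""
        ds = self if self.has_projection else project_coordinates(self)
        return ds.data["x"].to_numpy(dtype=float), ds.data["y"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def _check_origin(origin: tuple[float, float]) -> tuple[float, float]:
    lon0, lat0 = float(origin[0]), float(origin[1])
    if abs(lat0) >= 90.0:
        raise ValueError("projection origin latitude at +/-90 degrees is degenerate")
    return lon0, lat0


def project_coordinates(dataset: SurveyDataset, origin: tuple[float, float] | None = None) -> SurveyDataset:
    """Fill planar ``x``/``y`` (nmi) via a local equirectangular projection.

    ``x = (lon - lon0) * 60 * cos(lat0)``, ``y = (lat - lat0) * 60``; one
    minute of latitude equals one nautical mile by definition.
    """
    if origin is None:
        origin = dataset.origin
    if origin is None:
        origin = (float(dataset.data["lon"].mean()), float(dataset.data["lat"].mean()))
    lon0, lat0 = _check_origin(origin)
    coslat0 = math.cos(math.radians(lat0))
    df = dataset.data.copy()
    df["x"] = (df["lon"] - lon0) * 60.0 * coslat0
    df["y"] = (df["lat"] - lat0) * 60.0
    return SurveyDataset(df, dataset.species, origin=(lon0, lat0))


def inverse_project(x: np.ndarray, y: np.ndarray, origin: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Exact inverse of :func:`project_coordinates` (lon, lat in degrees)."""
    lon0, lat0 = _check_origin(origin)
    coslat0 = math.cos(math.radians(lat0))
    lon = np.asarray(x, dtype=float) / (60.0 * coslat0) + lon0
    lat = np.asarray(y, dtype=float) / 60.0 + lat0
    return lon, lat


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def load_schema(path: str | Path) -> dict:
    """Load a column-mapping schema from a YAML or JSON file.

    The schema maps canonical field names to the user's column names, with a
    nested ``density`` mapping from species label to column name, e.g.::

        lon: LONGITUDE
        lat: LATITUDE
        density:
          anchovy: ANCHOVY_TNMI2
    """
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _column_order(species: Iterable[str], with_xy: bool) -> list[str]:
    cols = list(CORE_COLUMNS)
    if with_xy:
        cols += ["x", "y"]
    cols += [_density_col(sp) for sp in species]
    return cols


def read_survey_csv(path: str | Path, schema: Mapping | None = None,
                    species: Iterable[str] | None = None) -> SurveyDataset:
    """Read a survey CSV into a validated :class:`SurveyDataset`.

    Without a schema, columns must already use canonical names and species
    are inferred from ``density_*`` columns.  A missing density value is an
    error, never silently zero.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        rename = {}
        for canon in (*CORE_COLUMNS, "x", "y"):
            if canon in schema:
                rename[schema[canon]] = canon
        for sp, col in (schema.get("density") or {}).items():
            rename[col] = _density_col(sp)
        df = df.rename(columns=rename)
        if species is None and "density" in schema:
            species = list(schema["density"])
    if species is None:
        species = [c[len(DENSITY_PREFIX):] for c in df.columns if c.startswith(DENSITY_PREFIX)]
    if not species:
        raise SurveyValidationError("no density columns found")
    origin = None
    if "x" in df.columns and "y" in df.columns and len(df):
        # recover the projection origin the file was written with, so
        # re-reading does not silently re-project about a different point
        lat0 = float(df["lat"].iloc[0] - df["y"].iloc[0] / 60.0)
        lon0 = float(df["lon"].iloc[0] - df["x"].iloc[0] / (60.0 * math.cos(math.radians(lat0))))
        origin = (lon0, lat0)
    try:
        return SurveyDataset(df, tuple(species), origin=origin)
    except SurveyValidationError:
        raise
    except Exception as exc:  # e.g. unparseable numerics
        raise SurveyValidationError(str(exc)) from exc


def write_survey_csv(dataset: SurveyDataset, path: str | Path) -> None:
    """Write a dataset as RFC-4180 CSV with deterministic column order.

    Floats use shortest round-trip representation, so write -> read recovers
    values exactly and re-writing an unmodified dataset is byte-stable.
    """
    cols = _column_order(dataset.species, dataset.has_projection)
    dataset.data.loc[:, cols].to_csv(path, index=False, lineterminator="\r\n")
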