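"""Core spatial containers: enumeration-area frames and single-band rasters.

These are deliberately thin. An :class:`EAFrame` wraps a pandas DataFrame with
a shapely geometry column and a CRS string; a :class:`RasterGrid` is a north-up
regular grid with an affine georeference and a nodata sentinel. Serialization
uses open text formats only (GeoJSON for vectors, ESRI ASCII grid for rasters)
so every artifact in a run directory is diffable and portable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

__all__ = ["EAFrame", "RasterGrid", "CRSError", "CoverageError"]

#: CRS strings treated as geographic (degree-based); everything else is
#: assumed projected with metre units.
_GEOGRAPHIC_TOKENS = ("4326", "CRS84", "WGS84", "GEOGRAPHIC")

#: Local planar CRS used by the synthetic landscape (transverse-Mercator-style
#: metre grid; real-data counterpart would be UTM zone 30N / EPSG:32630).
LOCAL_METRIC_CRS = "LOCAL:TM-METRES"


class CRSError(ValueError):
    """Raised when an operation needs a projected CRS and gets a geographic one."""


class CoverageError(ValueError):
    """Raised when a raster does not cover a required polygon or buffer."""


def crs_is_projected(crs: str) -> bool:
    up = str(crs).upper()
    return not any(tok in up for tok in _GEOGRAPHIC_TOKENS)


@dataclass
class EAFrame:
    """One row per enumeration area (EA).

    Required columns: ``ea_id`` (unique), ``neighbourhood_id``, ``population``,
    ``urban`` (bool) and ``geometry`` (shapely polygons). An optional binary
    ``label`` column carries the deprived/non-deprived training outcome; the
    synthetic generator also stashes its ``latent`` deprivation score.
    """

    df: pd.DataFrame
    crs: str = LOCAL_METRIC_CRS

    REQUIRED = ("ea_id", "neighbourhood_id", "population", "urban", "geometry")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"EAFrame missing required columns: {missing}")
        if self.df["ea_id"].duplicated().any():
            raise ValueError("EAFrame ea_id values must be unique")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def geometry(self) -> np.ndarray:
        return self.df["geometry"].to_numpy()

    @property
    def ea_ids(self) -> pd.Series:
        return self.df["ea_id"]

    def require_projected(self, what: str = "this operation") -> None:
        if not crs_is_projected(self.crs):
            raise CRSError(
                f"{what} requires a projected (metre) CRS, got {self.crs!r}; "
                "reproject the EA polygons first"
            )

    def total_bounds(self) -> tuple[float, float, float, float]:
        b = shapely.bounds(self.geometry)
        return (
            float(b[:, 0].min()),
            float(b[:, 1].min()),
            float(b[:, 2].max()),
            float(b[:, 3].max()),
        )

    def area_km2(self) -> np.ndarray:
        self.require_projected("area computation")
        return shapely.area(self.geometry) / 1e6

    def copy(self) -> "EAFrame":
        return EAFrame(self.df.copy(), self.crs)

    # -- GeoJSON round trip ------------------------------------------------

    def to_geojson(self, path) -> None:
        feats = []
        for _, row in self.df.iterrows():
            props = {k: _jsonable(v) for k, v in row.items() if k != "geometry"}
            feats.append(
                {
                    "type": "Feature",
                    "properties": props,
                    "geometry": mapping(row["geometry"]),
                }
            )
        doc = {
            "type": "FeatureCollection",
            "crs": {"type": "name", "properties": {"name": self.crs}},
            "features": feats,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, separators=(",", ":"))

    @classmethod
    def from_geojson(cls, path, crs: Optional[str] = None) -> "EAFrame":
        with open(path) as fh:
            doc = json.load(fh)
        if crs is None:
            crs = doc.get("crs", {}).get("properties", {}).get("name", LOCAL_METRIC_CRS)
        rows = []
        for feat in doc["features"]:
            row = dict(feat["properties"])
            row["geometry"] = shape(feat["geometry"])
            rows.append(row)
        return cls(pd.DataFrame(rows), crs)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return v


@dataclass
class RasterGrid:
    """Single-band north-up raster.

    ``values[row, col]`` has its cell centre at
    ``(x_origin + (col + 0.5) * cell, y_origin - (row + 0.5) * cell)`` where
    ``(x_origin, y_origin)`` is the top-left corner. The affine transform is
    therefore bijective between pixel indices and planar coordinates.
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell: float
    crs: str = LOCAL_METRIC_CRS
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid extent."""
        nrows, ncols = self.values.shape
        return (
            self.x_origin,
            self.y_origin - nrows * self.cell,
            self.x_origin + ncols * self.cell,
            self.y_origin,
        )

    def mask(self) -> np.ndarray:
        """Boolean array, True where data is valid."""
        return self.values != self.nodata

    def cell_centers(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x_origin + (np.asarray(cols) + 0.5) * self.cell
        ys = self.y_origin - (np.asarray(rows) + 0.5) * self.cell
        return xs, ys

    def window(self, xmin: float, ymin: float, xmax: float, ymax: float):
        """Row/col slice covering the given bounding box, clipped to the grid."""
        nrows, ncols = self.values.shape
        c0 = int(np.floor((xmin - self.x_origin) / self.cell))
        c1 = int(np.ceil((xmax - self.x_origin) / self.cell))
        r0 = int(np.floor((self.y_origin - ymax) / self.cell))
        r1 = int(np.ceil((self.y_origin - ymin) / self.cell))
        return (max(r0, 0), min(r1, nrows)), (max(c0, 0), min(c1, ncols))

    def value_at(self, x: float, y: float) -> float:
        """Value of the cell containing (x, y); nodata-aware nearest fallback
        is the caller's concern."""
        col = int(np.floor((x - self.x_origin) / self.cell))
        row = int(np.floor((self.y_origin - y) / self.cell))
        nrows, ncols = self.values.shape
        row = min(max(row, 0), nrows - 1)
        col = min(max(col, 0), ncols - 1)
        return float(self.values[row, col])

    def aligned_with(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell - other.cell) <= tol
        )

    # -- ESRI ASCII grid round trip ---------------------------------------

    def to_ascii(self, path) -> None:
        nrows, ncols = self.values.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\n")
            fh.write(f"nrows {nrows}\n")
            fh.write(f"xllcorner {self.x_origin!r}\n")
            fh.write(f"yllcorner {(self.y_origin - nrows * self.cell)!r}\n")
            fh.write(f"cellsize {self.cell!r}\n")
            fh.write(f"NODATA_value {self.nodata!r}\n")
            for row in self.values:
                fh.write(" ".join(repr(float(v)) for v in row))
                fh.write("\n")

    @classmethod
    def from_ascii(cls, path, crs: str = LOCAL_METRIC_CRS) -> "RasterGrid":
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                    header[key] = float(parts[1])
                else:
                    rows.append([float(p) for p in parts])
        values = np.asarray(rows)
        if values.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError("ASCII grid data does not match declared dimensions")
        cell = header["cellsize"]
        return cls(
            values=values,
            x_origin=header["xllcorner"],
            y_origin=header["yllcorner"] + values.shape[0] * cell,
            cell=cell,
            crs=crs,
            nodata=header.get("nodata_value", -9999.0),
        )
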