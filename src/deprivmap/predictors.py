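"""EA-level predictor construction.

Turns household microdata, EA geometry/population and DEM/NDVI rasters into
the model's predictor matrix: per-group household category proportions (one
column per non-reference analysis category), mean persons-per-bedroom
(crowding), population density, zonal NDVI mean, and the EA-minus-buffer
elevation difference. Continuous columns can be standardized with a recorded,
reversible transform so the same scaling is reused at prediction time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely

from .frames import CoverageError, EAFrame, RasterGrid

__all__ = [
    "CategoryMap",
    "PredictorMatrix",
    "MappingError",
    "default_category_map",
    "aggregate_census",
    "crowding",
    "pop_density",
    "zonal_mean",
    "ndvi",
    "elevation_diff",
    "build_matrix",
    "collinearity_report",
    "PREDICTOR_COLUMNS",
    "CONTINUOUS_COLUMNS",
]


class MappingError(ValueError):
    pass


@dataclass
class CategoryMap:
    """Raw-category -> analysis-category mapping with one reference per group.

    ``groups[group]`` maps every raw census category to an analysis category;
    ``reference[group]`` names the analysis category dropped from the matrix
    (its proportion is one minus the sum of the others).
    """

    groups: dict[str, dict[str, str]]
    reference: dict[str, str]

    def __post_init__(self) -> None:
        for g, mapping in self.groups.items():
            if g not in self.reference:
                raise MappingError(f"group {g!r} has no reference category")
            if self.reference[g] not in set(mapping.values()):
                raise MappingError(
                    f"reference {self.reference[g]!r} is not an analysis category of group {g!r}"
                )

    def analysis_categories(self, group: str) -> list[str]:
        seen: list[str] = []
        for v in self.groups[group].values():
            if v not in seen:
                seen.append(v)
        return seen

    def non_reference(self, group: str) -> list[str]:
        ref = self.reference[group]
        return [c for c in self.analysis_categories(group) if c != ref]

    def to_dict(self) -> dict:
        return {"groups": self.groups, "reference": self.reference}

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryMap":
        return cls(groups=d["groups"], reference=d["reference"])


def default_category_map() -> CategoryMap:
    """Identity mapping over the synthetic generator's category vocabulary,
    reference = the non-deprived profile category of each group."""
    from .synthetic_data import CATEGORY_PROFILES

    groups = {g: {c: c for c in prof["cats"]} for g, prof in CATEGORY_PROFILES.items()}
    reference = {g: prof["cats"][0] for g, prof in CATEGORY_PROFILES.items()}
    return CategoryMap(groups=groups, reference=reference)


def _proportion_columns(cmap: CategoryMap) -> list[str]:
    cols = []
    for g in cmap.groups:
        for c in cmap.non_reference(g):
            cols.append(f"{g}_{c}")
    return cols


CONTINUOUS_COLUMNS = ["crowding", "pop_density", "ndvi_mean", "elev_diff"]
#: Default 18-column predictor layout (14 category proportions + 4 continuous).
PREDICTOR_COLUMNS = _proportion_columns(default_category_map()) + CONTINUOUS_COLUMNS


@dataclass
class PredictorMatrix:
    """Named EA-level predictors, row-indexed by ``ea_id``.

    ``standardization`` records (mean, sd) per continuous column when the
    matrix was standardized; applying a stored record to the same raw data
    reproduces the standardized matrix exactly.
    """

    data: pd.DataFrame  # index: ea_id
    continuous_cols: list[str] = field(default_factory=lambda: list(CONTINUOUS_COLUMNS))
    standardization: Optional[dict[str, tuple[float, float]]] = None
    flagged_ea_ids: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="ea_id")

    def sidecar(self, cmap: Optional[CategoryMap] = None) -> dict:
        return {
            "columns": self.columns,
            "continuous_cols": self.continuous_cols,
            "standardization": self.standardization,
            "category_map": cmap.to_dict() if cmap is not None else None,
            "flagged_ea_ids": self.flagged_ea_ids,
        }

    def write(self, csv_path, sidecar_path, cmap: Optional[CategoryMap] = None) -> None:
        self.to_csv(csv_path)
        with open(sidecar_path, "w") as fh:
            json.dump(self.sidecar(cmap), fh, indent=1, sort_keys=True)


def aggregate_census(h: pd.DataFrame, cmap: CategoryMap) -> pd.DataFrame:
    """Per-EA proportion of households in each non-reference analysis category.

    Returns a frame indexed by ea_id with one column per non-reference
    category (``{group}_{category}``) plus ``n_households``. Unknown raw
    categories raise :class:`MappingError` naming the offender.
    """
    if len(h) == 0:
        raise ValueError("household table is empty")
    counts = h.groupby("ea_id").size()
    out = pd.DataFrame({"n_households": counts})
    for group in cmap.groups:
        raw = h[group]
        unknown = set(raw.unique()) - set(cmap.groups[group])
        if unknown:
            raise MappingError(
                f"unknown raw categories in group {group!r}: {sorted(unknown)}"
            )
        analysis = raw.map(cmap.groups[group])
        tab = pd.crosstab(h["ea_id"], analysis)
        for cat in cmap.non_reference(group):
            col = tab[cat] if cat in tab.columns else pd.Series(0, index=tab.index)
            out[f"{group}_{cat}"] = (col / counts).fillna(0.0)
    return out


def crowding(h: pd.DataFrame) -> pd.Series:
    """EA mean of household_size / bedrooms (persons per bedroom)."""
    bedrooms = h["bedrooms"].to_numpy()
    if (bedrooms < 1).any():
        bad = h.loc[h["bedrooms"] < 1, "ea_id"].unique()
        raise ValueError(f"bedrooms must be >= 1; offending EAs: {list(bad)[:5]}")
    ratio = h["household_size"].to_numpy(dtype=float) / bedrooms
    return pd.Series(ratio, index=h["ea_id"].to_numpy()).groupby(level=0).mean().rename("crowding")


def pop_density(frame: EAFrame) -> pd.Series:
    """Persons per km^2 from EA population and polygon area (projected CRS only)."""
    frame.require_projected("population density")
    area = frame.area_km2()
    if (area <= 0).any():
        raise ValueError("all EA polygons must have positive area")
    dens = frame.df["population"].to_numpy(dtype=float) / area
    return pd.Series(dens, index=frame.df["ea_id"].to_numpy(), name="pop_density")


def _polygon_cell_mean(r: RasterGrid, geom) -> float:
    """Mean over raster cells whose centres fall inside ``geom`` (nodata
    excluded); falls back to the value at the polygon centroid for polygons
    smaller than one cell. Returns nan only when even the fallback hits nodata."""
    xmin, ymin, xmax, ymax = shapely.bounds(geom)
    (r0, r1), (c0, c1) = r.window(xmin, ymin, xmax, ymax)
    if r1 > r0 and c1 > c0:
        rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        xs, ys = r.cell_centers(rows.ravel(), cols.ravel())
        inside = shapely.contains_xy(geom, xs, ys)
        if inside.any():
            vals = r.values[rows.ravel()[inside], cols.ravel()[inside]]
            vals = vals[vals != r.nodata]
            if vals.size:
                return float(vals.mean())
    cx, cy = shapely.get_coordinates(shapely.centroid(geom))[0]
    v = r.value_at(cx, cy)
    return float("nan") if v == r.nodata else v


def zonal_mean(r: RasterGrid, frame: EAFrame) -> pd.Series:
    """Cell-centre-in-polygon zonal mean per EA, nodata-aware."""
    if frame.crs != r.crs:
        raise ValueError(f"CRS mismatch: frame {frame.crs!r} vs raster {r.crs!r}")
    bxmin, bymin, bxmax, bymax = r.bounds()
    out = np.empty(len(frame))
    for i, geom in enumerate(frame.geometry):
        gxmin, gymin, gxmax, gymax = shapely.bounds(geom)
        if gxmax < bxmin or gxmin > bxmax or gymax < bymin or gymin > bymax:
            raise CoverageError(
                f"EA {frame.df['ea_id'].iloc[i]!r} lies entirely outside the raster"
            )
        out[i] = _polygon_cell_mean(r, geom)
    return pd.Series(out, index=frame.df["ea_id"].to_numpy(), name="zonal_mean")


def ndvi(red: RasterGrid, nir: RasterGrid) -> RasterGrid:
    """(NIR - Red) / (NIR + Red); cells with a zero sum (or nodata input) map
    to nodata. Output values lie in [-1, 1] for non-negative reflectances."""
    if not red.aligned_with(nir):
        raise ValueError("red and nir rasters are not aligned (shape/origin/cell)")
    denom = nir.values + red.values
    valid = red.mask() & nir.mask() & (denom != 0)
    out = np.full(red.values.shape, red.nodata)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[valid] = (nir.values[valid] - red.values[valid]) / denom[valid]
    return RasterGrid(out, red.x_origin, red.y_origin, red.cell, red.crs, red.nodata)


def elevation_diff(
    dem: RasterGrid,
    frame: EAFrame,
    buffer_km: float = 5.0,
    include_self: bool = False,
) -> pd.Series:
    """EA mean elevation minus the mean over its ``buffer_km`` surroundings.

    The buffer zone is the annulus buffer(EA) minus the EA polygon itself by
    default (``include_self=True`` uses the full buffered disc). A buffer that
    extends past the raster raises :class:`CoverageError` naming the EA.
    """
    frame.require_projected("elevation differencing")
    bxmin, bymin, bxmax, bymax = dem.bounds()
    buf_m = buffer_km * 1000.0
    out = np.empty(len(frame))
    for i, geom in enumerate(frame.geometry):
        ea_id = frame.df["ea_id"].iloc[i]
        disc = geom.buffer(buf_m, quad_segs=12)
        dxmin, dymin, dxmax, dymax = shapely.bounds(disc)
        if dxmin < bxmin - dem.cell or dymin < bymin - dem.cell \
                or dxmax > bxmax + dem.cell or dymax > bymax + dem.cell:
            raise CoverageError(
                f"raster does not cover the {buffer_km} km buffer of EA {ea_id!r}"
            )
        zone = disc if include_self else disc.difference(geom)
        ea_mean = _polygon_cell_mean(dem, geom)
        buf_mean = _polygon_cell_mean(dem, zone)
        out[i] = ea_mean - buf_mean
    return pd.Series(out, index=frame.df["ea_id"].to_numpy(), name="elev_diff")


def build_matrix(
    frame: EAFrame,
    h: pd.DataFrame,
    cmap: CategoryMap,
    dem: Optional[RasterGrid] = None,
    ndvi_raster: Optional[RasterGrid] = None,
    standardize: bool = True,
    buffer_km: float = 5.0,
    predictor_list: Optional[Sequence[str]] = None,
    standardization: Optional[dict[str, tuple[float, float]]] = None,
) -> PredictorMatrix:
    """Assemble the EA-level predictor matrix.

    Joins census proportions, crowding, population density and (when rasters
    are given) NDVI zonal means and elevation differences, in frame row order.
    EAs with zero sampled households are flagged and dropped, never imputed.
    Passing a stored ``standardization`` record applies that transform instead
    of fitting a new one.
    """
    parts = [aggregate_census(h, cmap), crowding(h).to_frame()]
    parts.append(pop_density(frame).to_frame())
    if ndvi_raster is not None:
        parts.append(zonal_mean(ndvi_raster, frame).rename("ndvi_mean").to_frame())
    if dem is not None:
        parts.append(elevation_diff(dem, frame, buffer_km=buffer_km).to_frame())
    wide = pd.concat(parts, axis=1)
    wide = wide.reindex(frame.df["ea_id"].to_numpy())

    flagged = wide.index[wide["n_households"].isna()].tolist()
    wide = wide.drop(index=flagged).drop(columns=["n_households"])

    available = list(wide.columns)
    if predictor_list is not None:
        missing = [c for c in predictor_list if c not in available]
        if missing:
            raise ValueError(f"configured predictors not available: {missing}")
        wide = wide[list(predictor_list)]
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"missing values after construction in columns: {bad}")

    cont = [c for c in CONTINUOUS_COLUMNS if c in wide.columns]
    record = None
    if standardization is not None:
        record = dict(standardization)
        for c, (mu, sd) in record.items():
            if c in wide.columns:
                wide[c] = (wide[c] - mu) / sd
    elif standardize:
        record = {}
        for c in cont:
            mu = float(wide[c].mean())
            sd = float(wide[c].std(ddof=0))
            if sd == 0:
                sd = 1.0
            record[c] = (mu, sd)
            wide[c] = (wide[c] - mu) / sd

    return PredictorMatrix(
        data=wide,
        continuous_cols=cont,
        standardization=record,
        flagged_ea_ids=[str(e) for e in flagged],
    )


def collinearity_report(X: PredictorMatrix | pd.DataFrame, flag_at: float = 0.7) -> pd.DataFrame:
    """Pairwise Pearson correlations with |r| >= ``flag_at`` flagged.

    Zero-variance columns are excluded with a warning rather than producing
    undefined correlations.
    """
    df = X.data if isinstance(X, PredictorMatrix) else X
    if df.shape[1] < 2 or df.shape[0] < 3:
        raise ValueError("need at least 2 columns and 3 rows")
    sd = df.std(ddof=0)
    dead = sd.index[sd == 0].tolist()
    if dead:
        warnings.warn(f"excluding zero-variance columns from correlation report: {dead}")
        df = df.drop(columns=dead)
    corr = df.corr()
    rows = []
    cols = list(df.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = float(corr.iloc[i, j])
            rows.append(
                {"var_a": cols[i], "var_b": cols[j], "pearson_r": r, "flagged": abs(r) >= flag_at}
            )
    return pd.DataFrame(rows)
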