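"""Synthetic census landscapes for end-to-end testing without any download.

Generates a contiguous lattice of square enumeration areas (EAs) grouped into
spatially contiguous neighbourhoods, household microdata whose category
probabilities follow a two-profile mixture driven by a latent per-EA
deprivation score, smooth DEM/NDVI raster fields, and binary deprived labels
drawn from the exact logistic generative model

    logit(p_ij) = alpha + beta . x_ij + V_j,   V_j ~ Normal(0, v_sd^2)

so that ``v_sd = 0`` reproduces the no-random-effect model exactly and every
downstream stage (predictor construction, fitting, selection, prediction,
LISA) can be validated against known truths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import shapely

from .frames import EAFrame, LOCAL_METRIC_CRS, RasterGrid

__all__ = [
    "SyntheticConfig",
    "ConfigurationError",
    "LabelSample",
    "gen_landscape",
    "gen_rasters",
    "gen_households",
    "gen_labels",
    "generate_bundle",
]


class ConfigurationError(ValueError):
    pass


# Lognormal population parameters calibrated to a median of 689 persons and an
# interquartile range of [486, 940]: mu = ln(median); the IQR spans
# 2 * 0.674490 sigma on the log scale.
_POP_MU = math.log(689.0)
_POP_SIGMA = math.log(940.0 / 486.0) / (2.0 * 0.6744897501960817)

# Two-profile category mixtures per variable group. The first category of each
# group is the reference ("non-deprived") analysis category. Profiles are
# stipulated, not estimated: the mixing weight is sigmoid(latent score).
CATEGORY_PROFILES: dict[str, dict[str, list[float]]] = {
    "water": {"cats": ["improved", "unimproved"], "p0": [0.90, 0.10], "p1": [0.35, 0.65]},
    "toilet": {
        "cats": ["flush", "public", "pit", "none"],
        "p0": [0.70, 0.15, 0.10, 0.05],
        "p1": [0.10, 0.55, 0.20, 0.15],
    },
    "tenure": {"cats": ["own", "rent"], "p0": [0.70, 0.30], "p1": [0.35, 0.65]},
    "wall": {"cats": ["durable", "non_durable"], "p0": [0.85, 0.15], "p1": [0.40, 0.60]},
    "roof": {"cats": ["metal_sheet", "other_roof"], "p0": [0.80, 0.20], "p1": [0.55, 0.45]},
    "floor": {"cats": ["cement", "earth"], "p0": [0.90, 0.10], "p1": [0.50, 0.50]},
    "fuel": {"cats": ["clean", "solid"], "p0": [0.60, 0.40], "p1": [0.15, 0.85]},
    "rubbish": {
        "cats": ["collected", "public_dump", "burned"],
        "p0": [0.65, 0.25, 0.10],
        "p1": [0.15, 0.60, 0.25],
    },
    "dwelling": {
        "cats": ["separate_house", "compound", "hut", "kiosk"],
        "p0": [0.60, 0.30, 0.05, 0.05],
        "p1": [0.15, 0.50, 0.20, 0.15],
    },
}

#: Default generating coefficients, aligned with
#: :data:`deprivmap.predictors.PREDICTOR_COLUMNS` (18 entries).
DEFAULT_TRUE_BETA = np.array(
    [
        0.9,   # water_unimproved
        1.1,   # toilet_public
        0.5,   # toilet_pit
        0.4,   # toilet_none
        0.3,   # tenure_rent
        0.6,   # wall_non_durable
        0.2,   # roof_other_roof
        0.4,   # floor_earth
        0.7,   # fuel_solid
        0.5,   # rubbish_public_dump
        0.3,   # rubbish_burned
        0.4,   # dwelling_compound
        0.3,   # dwelling_hut
        0.2,   # dwelling_kiosk
        0.8,   # crowding
        0.3,   # pop_density
        -0.6,  # ndvi_mean
        -0.2,  # elev_diff
    ]
)


@dataclass
class SyntheticConfig:
    """Knobs for the synthetic landscape; ``seed`` controls every draw."""

    n_neighbourhoods: int = 4
    eas_per_neighbourhood: int = 25
    cell_size_km: float = 0.2236  # ~0.05 km^2 per EA, matching urban GAMA
    true_alpha: float = -1.0
    true_beta: np.ndarray = field(default_factory=lambda: DEFAULT_TRUE_BETA.copy())
    v_sd: float = 0.0
    raster_resolution_m: float = 100.0
    margin_km: float = 6.0
    max_buffer_km: float = 5.0
    seed: int = 0
    household_sample_frac: float = 0.10
    mean_household_size: float = 4.0
    latent_neighbourhood_sd: float = 1.0
    latent_ea_sd: float = 0.6
    constant_dem: Optional[float] = None
    constant_ndvi: Optional[float] = None
    dem_base_m: float = 60.0
    dem_relief_m: float = 30.0
    dem_noise_sd: float = 0.8
    ndvi_noise_sd: float = 0.04

    def __post_init__(self) -> None:
        self.true_beta = np.asarray(self.true_beta, dtype=float)
        if self.n_neighbourhoods < 1 or self.eas_per_neighbourhood < 1:
            raise ConfigurationError("n_neighbourhoods and eas_per_neighbourhood must be positive")
        if self.n_neighbourhoods * self.eas_per_neighbourhood < 2:
            raise ConfigurationError("need at least 2 EAs in total")
        if self.cell_size_km <= 0 or self.raster_resolution_m <= 0:
            raise ConfigurationError("cell_size_km and raster_resolution_m must be positive")
        if self.v_sd < 0:
            raise ConfigurationError("v_sd must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


def _near_square(n: int) -> tuple[int, int]:
    """Factor n into (rows, cols) as close to square as possible."""
    for r in range(int(math.isqrt(n)), 0, -1):
        if n % r == 0:
            return r, n // r
    return 1, n


def gen_landscape(cfg: SyntheticConfig) -> EAFrame:
    """Square-EA lattice partitioned into contiguous neighbourhood blocks.

    Each EA gets a unique id, its neighbourhood id, a lognormal population
    (median ~689, IQR ~[486, 940]), ``urban=True``, and a latent deprivation
    score that is spatially structured (shared neighbourhood component plus
    EA-level noise) — the same score that drives the household generator.
    """
    rng = cfg.rng(11)
    nb_rows, nb_cols = _near_square(cfg.n_neighbourhoods)
    ea_rows, ea_cols = _near_square(cfg.eas_per_neighbourhood)
    total_rows, total_cols = nb_rows * ea_rows, nb_cols * ea_cols
    cell_m = cfg.cell_size_km * 1000.0

    n = cfg.n_neighbourhoods * cfg.eas_per_neighbourhood
    nb_base = rng.normal(0.0, cfg.latent_neighbourhood_sd, size=cfg.n_neighbourhoods)
    populations = np.round(rng.lognormal(_POP_MU, _POP_SIGMA, size=n)).astype(int)
    populations = np.maximum(populations, 50)
    ea_noise = rng.normal(0.0, cfg.latent_ea_sd, size=n)

    rows = []
    idx = 0
    for r in range(total_rows):
        for c in range(total_cols):
            nb_index = (r // ea_rows) * nb_cols + (c // ea_cols)
            geom = shapely.box(c * cell_m, r * cell_m, (c + 1) * cell_m, (r + 1) * cell_m)
            rows.append(
                {
                    "ea_id": f"EA{idx:05d}",
                    "neighbourhood_id": f"NB{nb_index:04d}",
                    "population": int(populations[idx]),
                    "urban": True,
                    "latent": float(nb_base[nb_index] + ea_noise[idx]),
                    "geometry": geom,
                }
            )
            idx += 1
    return EAFrame(pd.DataFrame(rows), LOCAL_METRIC_CRS)


def _smooth_field(xs: np.ndarray, ys: np.ndarray, rng: np.random.Generator,
                  n_waves: int = 6, wavelength_km: float = 3.0) -> np.ndarray:
    """Low-frequency random cosine field on a coordinate grid, roughly unit scale."""
    field_ = np.zeros((ys.size, xs.size))
    xg, yg = np.meshgrid(xs, ys)
    for _ in range(n_waves):
        theta = rng.uniform(0, 2 * np.pi)
        wl = rng.uniform(0.5, 1.5) * wavelength_km * 1000.0
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.4, 1.0)
        field_ += amp * np.cos(2 * np.pi * (xg * np.cos(theta) + yg * np.sin(theta)) / wl + phase)
    return field_ / math.sqrt(n_waves)


def gen_rasters(frame: EAFrame, cfg: SyntheticConfig) -> tuple[RasterGrid, RasterGrid]:
    """DEM and NDVI rasters covering the EA extent plus ``margin_km`` on all sides.

    Fields are smooth (superposed low-frequency cosines) plus white noise; NDVI
    is clamped to [-1, 1]. The margin must be at least ``max_buffer_km`` so
    buffer differencing downstream never runs off the edge.
    """
    frame.require_projected("raster generation")
    if cfg.margin_km < cfg.max_buffer_km:
        raise ConfigurationError(
            f"raster margin ({cfg.margin_km} km) is smaller than the largest "
            f"downstream buffer radius ({cfg.max_buffer_km} km)"
        )
    rng = cfg.rng(22)
    xmin, ymin, xmax, ymax = frame.total_bounds()
    m = cfg.margin_km * 1000.0
    cell = float(cfg.raster_resolution_m)
    x0, y1 = xmin - m, ymax + m
    ncols = int(math.ceil((xmax + m - x0) / cell))
    nrows = int(math.ceil((y1 - (ymin - m)) / cell))
    xs = x0 + (np.arange(ncols) + 0.5) * cell
    ys = y1 - (np.arange(nrows) + 0.5) * cell

    if cfg.constant_dem is not None:
        dem_vals = np.full((nrows, ncols), float(cfg.constant_dem))
    else:
        dem_vals = (
            cfg.dem_base_m
            + cfg.dem_relief_m * _smooth_field(xs, ys, rng, wavelength_km=5.0)
            + rng.normal(0.0, cfg.dem_noise_sd, size=(nrows, ncols))
        )
    if cfg.constant_ndvi is not None:
        ndvi_vals = np.full((nrows, ncols), float(cfg.constant_ndvi))
    else:
        ndvi_vals = (
            0.25
            + 0.3 * _smooth_field(xs, ys, rng, wavelength_km=2.0)
            + rng.normal(0.0, cfg.ndvi_noise_sd, size=(nrows, ncols))
        )
    ndvi_vals = np.clip(ndvi_vals, -1.0, 1.0)

    dem = RasterGrid(dem_vals, x0, y1, cell, frame.crs)
    ndvi = RasterGrid(ndvi_vals, x0, y1, cell, frame.crs)
    return dem, ndvi


def gen_households(
    frame: EAFrame,
    cfg: SyntheticConfig,
    latent_scores: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Household microdata: ~``household_sample_frac`` of each EA's households.

    Every household carries one category per variable group plus a household
    size and a bedroom count >= 1. Within each group, categories are drawn from
    the mixture ``(1 - w) * p0 + w * p1`` with ``w = sigmoid(latent score)``,
    so EA-level proportions are logistic in the latent deprivation score.
    ``latent_scores`` overrides the frame's ``latent`` column (tests use -inf
    to force the pure non-deprived profile).
    """
    if len(frame) == 0:
        raise ConfigurationError("frame must be nonempty")
    rng = cfg.rng(33)
    latent = (
        np.asarray(latent_scores, dtype=float)
        if latent_scores is not None
        else frame.df["latent"].to_numpy(dtype=float)
    )
    if latent.shape[0] != len(frame):
        raise ConfigurationError("latent_scores must align with the frame")

    pops = frame.df["population"].to_numpy()
    n_households = np.maximum(1, np.round(pops / cfg.mean_household_size).astype(int))
    n_sampled = np.maximum(1, rng.binomial(n_households, cfg.household_sample_frac))
    total = int(n_sampled.sum())

    ea_index = np.repeat(np.arange(len(frame)), n_sampled)
    w = _expit(latent)[ea_index]  # per-household deprived-profile weight

    out = {"ea_id": frame.df["ea_id"].to_numpy()[ea_index]}
    for group, prof in CATEGORY_PROFILES.items():
        p0 = np.asarray(prof["p0"])
        p1 = np.asarray(prof["p1"])
        probs = (1.0 - w)[:, None] * p0[None, :] + w[:, None] * p1[None, :]
        cum = np.cumsum(probs, axis=1)
        u = rng.random(total)
        choice = (u[:, None] > cum).sum(axis=1)
        cats = np.asarray(prof["cats"], dtype=object)
        out[group] = cats[choice]

    size = 1 + rng.poisson(2.5 + 1.5 * w)
    bedrooms = 1 + rng.binomial(np.maximum(size - 1, 0), 0.35 * (1.0 - 0.55 * w))
    out["household_size"] = size
    out["bedrooms"] = bedrooms
    return pd.DataFrame(out)


@dataclass
class LabelSample:
    """Labels plus the generating truths, for recovery tests."""

    y: np.ndarray
    p: np.ndarray
    eta: np.ndarray
    v: pd.Series  # per-neighbourhood random effect, indexed by neighbourhood id


def gen_labels(X, frame: EAFrame, cfg: SyntheticConfig) -> LabelSample:
    """Draw deprived labels from logit(p) = alpha + beta.x + V_j.

    ``X`` may be a PredictorMatrix, DataFrame, or array, row-aligned with the
    frame. V_j ~ Normal(0, v_sd^2) per neighbourhood (exactly zero when
    ``v_sd = 0``, reproducing the no-random-effect model).
    """
    xmat = _as_matrix(X)
    if xmat.shape[0] != len(frame):
        raise ValueError("X must be row-aligned with the frame")
    if xmat.shape[1] != cfg.true_beta.shape[0]:
        raise ValueError(
            f"true_beta has {cfg.true_beta.shape[0]} entries but X has "
            f"{xmat.shape[1]} columns"
        )
    rng = cfg.rng(44)
    nb = frame.df["neighbourhood_id"]
    nb_levels = pd.Index(sorted(nb.unique()))
    if cfg.v_sd > 0:
        v_vals = rng.normal(0.0, cfg.v_sd, size=len(nb_levels))
    else:
        v_vals = np.zeros(len(nb_levels))
    v = pd.Series(v_vals, index=nb_levels)
    eta = cfg.true_alpha + xmat @ cfg.true_beta + v.loc[nb].to_numpy()
    p = _expit(eta)
    y = rng.binomial(1, p)
    return LabelSample(y=y, p=p, eta=eta, v=v)


def generate_bundle(cfg: SyntheticConfig, standardize: bool = True) -> dict:
    """Full synthetic bundle: landscape, rasters, households, predictors, labels.

    Convenience wrapper used by tests, the fixture command and the pipeline's
    optional simulate stage.
    """
    from . import predictors as P

    frame = gen_landscape(cfg)
    dem, ndvi = gen_rasters(frame, cfg)
    households = gen_households(frame, cfg)
    X = P.build_matrix(
        frame, households, P.default_category_map(), dem, ndvi,
        standardize=standardize, buffer_km=cfg.max_buffer_km,
    )
    labels = gen_labels(X, frame, cfg)
    frame.df["label"] = labels.y
    return {
        "config": cfg,
        "frame": frame,
        "dem": dem,
        "ndvi": ndvi,
        "households": households,
        "X": X,
        "labels": labels,
    }


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _is_predictor_matrix(X) -> bool:
    return isinstance(getattr(X, "data", None), pd.DataFrame)


def _as_matrix(X) -> np.ndarray:
    if _is_predictor_matrix(X):
        return X.data.to_numpy(dtype=float)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)
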