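from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import shapely

from deprivmap import predictors as PR
from deprivmap import synthetic_data as SD
from deprivmap.frames import EAFrame, RasterGrid

FIXTURE_DIR = Path(__file__).resolve().parent.parent / "fixtures" / "demo"


@pytest.fixture(scope="session")
def small_cfg() -> SD.SyntheticConfig:
    return SD.SyntheticConfig(n_neighbourhoods=4, eas_per_neighbourhood=25, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    """100-EA synthetic bundle shared across module tests (read-only)."""
    return SD.generate_bundle(small_cfg)


@pytest.fixture(scope="session")
def fixture_dir() -> Path:
    assert FIXTURE_DIR.exists(), "committed fixture bundle missing"
    return FIXTURE_DIR


def grid_frame(nrows: int, ncols: int, cell: float = 1000.0, crs: str = "LOCAL:TM-METRES") -> EAFrame:
    """Plain rectangular grid of square EAs, one neighbourhood."""
    rows = []
    k = 0
    for r in range(nrows):
        for c in range(ncols):
            rows.append(
                {
                    "ea_id": f"G{k:04d}",
                    "neighbourhood_id": "NB0",
                    "population": 100,
                    "urban": True,
                    "geometry": shapely.box(c * cell, r * cell, (c + 1) * cell, (r + 1) * cell),
                }
            )
            k += 1
    return EAFrame(pd.DataFrame(rows), crs)


def const_raster(value: float, x0=-5000.0, y1=15000.0, cell=500.0, n=40, crs="LOCAL:TM-METRES"):
    return RasterGrid(np.full((n, n), float(value)), x0, y1, cell, crs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
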