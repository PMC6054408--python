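import numpy as np
import pandas as pd
import pytest

from felidniche.rasters import Raster
from felidniche.synthetic import SyntheticConfig, place_stations


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180720)


@pytest.fixture()
def small_raster():
    rng = np.random.default_rng(7)
    return Raster(rng.standard_normal((12, 12)), cell_size=100.0, name="toy")


@pytest.fixture(scope="session")
def station_table():
    cfg = SyntheticConfig(extent_cells=64, n_stations=200, n_clusters=5)
    return place_stations(cfg, seed=11)


def brute_force_focal(values, cell_size, radius):
    """Independent double-loop oracle for the circular focal mean."""
    nr, nc = values.shape
    out = np.full((nr, nc), np.nan)
    r_cells = int(np.floor(radius / cell_size))
    for i in range(nr):
        for j in range(nc):
            acc, cnt = 0.0, 0
            for di in range(-r_cells, r_cells + 1):
                for dj in range(-r_cells, r_cells + 1):
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < nr and 0 <= jj < nc):
                        continue
                    if np.hypot(di, dj) * cell_size <= radius + 1e-9:
                        v = values[ii, jj]
                        if np.isfinite(v):
                            acc += v
                            cnt += 1
            if cnt:
                out[i, j] = acc / cnt
    return out


@pytest.fixture(scope="session")
def detection_frame():
    rows = [
        ("S1", "leopard_cat", "2012-03-01T10:00:00"),
        ("S1", "leopard_cat", "2012-03-01T10:30:00"),
        ("S1", "leopard_cat", "2012-03-01T11:10:00"),
        ("S2", "leopard_cat", "2012-03-01T10:30:00"),
        ("S1", "marbled_cat", "2012-03-01T10:30:00"),
    ]
    return pd.DataFrame(rows, columns=["station_id", "species", "timestamp"])
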