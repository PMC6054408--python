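"""Validated readers/writers for the pipeline interchange formats.

Stations and detections travel as CSV (RFC-4180 via pandas), covariates and
occurrence surfaces as single-band ASCII-grid rasters with declared nodata,
and a run is governed by one YAML config whose thresholds default to the
analysis constants (7 focal radii, p-screen 0.2, |r|-prune 0.7, >= 20
detections, estimator cutoff 75, 10,000 bootstrap replicates, 95% CI).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detections import REQUIRED_DETECTION_COLS, REQUIRED_STATION_COLS, _parse_timestamps
from .rasters import DEFAULT_SCALES_M, Raster, read_ascii_grid, write_ascii_grid


@dataclass
class RunConfig:
    station_csv: str = "stations.csv"
    detection_csv: str = "detections.csv"
    raster_dir: str = "rasters"
    output_dir: str = "outputs"
    scales: list[float] = field(default_factory=lambda: list(DEFAULT_SCALES_M))
    p_screen: float = 0.2
    r_prune: float = 0.7
    min_detections: int = 20
    estimator_cutoff: int = 75
    bootstrap_B: int = 10_000
    ci_level: float = 95.0
    seed: int = 1
    species: list[str] = field(default_factory=list)       # habitat/activity focal set
    groups: dict[str, list[str]] = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)          # overrides for `simulate`

    def validate(self) -> None:
        if not (0 < self.p_screen < 1):
            raise ValueError("p_screen must be in (0,1)")
        if not (0 < self.r_prune < 1):
            raise ValueError("r_prune must be in (0,1)")
        if self.min_detections < 0 or self.estimator_cutoff < 2:
            raise ValueError("invalid detection thresholds")
        if not (50 < self.ci_level < 100):
            raise ValueError("ci_level must be in (50,100)")
        if sorted(self.scales) != list(self.scales) or min(self.scales) <= 0:
            raise ValueError("scales must be positive and sorted ascending")

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))


def read_stations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_STATION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"station table missing required columns: {missing}")
    if df["station_id"].duplicated().any():
        dups = df.loc[df["station_id"].duplicated(), "station_id"].tolist()
        raise ValueError(f"duplicate station ids: {dups}")
    if (df["effort"] <= 0).any():
        bad = df.loc[df["effort"] <= 0, "station_id"].tolist()
        raise ValueError(f"non-positive effort at stations: {bad}")
    df["station_id"] = df["station_id"].astype(str)
    return df


def read_detections(path: str | Path, stations: pd.DataFrame | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_DETECTION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"detection table missing required columns: {missing}")
    df["station_id"] = df["station_id"].astype(str)
    _parse_timestamps(df)  # fails naming the offending row
    if stations is not None:
        unknown = sorted(set(df["station_id"]) - set(stations["station_id"]))
        if unknown:
            raise ValueError(f"detections reference unknown stations: {unknown}")
    return df


def read_raster_dir(path: str | Path) -> dict[str, Raster]:
    """Load every .asc raster in a directory, enforcing a shared grid."""
    path = Path(path)
    rasters: dict[str, Raster] = {}
    ref: Raster | None = None
    for f in sorted(path.glob("*.asc")):
        r = read_ascii_grid(f)
        if ref is None:
            ref = r
        elif (r.shape != ref.shape or r.cell_size != ref.cell_size
              or r.x0 != ref.x0 or r.y0 != ref.y0):
            raise ValueError(f"raster {f.name} is on a different grid than the others")
        rasters[r.name] = r
    return rasters


def write_raster_dir(rasters: dict[str, Raster], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, r in rasters.items():
        write_ascii_grid(r, path / f"{name}.asc")


def write_csv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, lineterminator="\r\n")
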