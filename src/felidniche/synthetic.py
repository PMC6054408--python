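"""Synthetic camera-trap landscapes, stations, detections and activity times.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised without survey data:

* spatially autocorrelated covariate rasters (Gaussian-smoothed white noise,
  kernel length = the stated autocorrelation range; categorical layers are
  0/1 indicators from thresholding a smoothed field at a quantile);
* clustered station placement (clusters play the role of study areas; the
  default of 10 clusters and 578 stations mirrors a large multi-area survey);
* species occurrence as a logistic function of covariates aggregated at
  species-specific "true" focal scales plus a trap-effort term, with
  detection counts as presence x (1 + Poisson extra);
* detection clock times drawn from von Mises mixtures for the classic diel
  archetypes (nocturnal, diurnal, crepuscular, cathemeral);
* multi-species detection matrices in which a felid's presence depends on
  candidate-prey detection counts through specified co-occurrence effects.

Every draw is a pure function of (config, seed): no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .rasters import CATEGORICAL, CONTINUOUS, Raster, focal_mean, extract_standardize

HOUR = 2.0 * np.pi / 24.0  # radians per clock hour


@dataclass
class CovariateSpec:
    name: str
    kind: str = CONTINUOUS                 # "continuous" or "categorical"
    autocorrelation_range: float = 960.0   # metres; 0 = white noise
    class_threshold: float = 0.5           # quantile for categorical layers


@dataclass
class ActivitySpec:
    """Von Mises mixture on the 24-h circle (angles in radians, midnight = 0)."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    kappas: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(k < 0 for k in self.kappas):
            raise ValueError("concentrations must be non-negative")


#: Diel archetypes: nocturnal (peak ~1:00), diurnal (~midday), crepuscular
#: (dawn 6:00 + dusk 18:00), cathemeral (nearly uniform with a weak night bias).
ACTIVITY_ARCHETYPES: dict[str, ActivitySpec] = {
    "nocturnal": ActivitySpec((0.7, 0.3), (1.0 * HOUR, 23.0 * HOUR), (2.5, 2.5)),
    "diurnal": ActivitySpec((1.0,), (12.0 * HOUR,), (3.0,)),
    "crepuscular": ActivitySpec((0.5, 0.5), (6.0 * HOUR, 18.0 * HOUR), (8.0, 8.0)),
    "cathemeral": ActivitySpec((0.6, 0.4), (23.0 * HOUR, 12.0 * HOUR), (0.8, 0.4)),
}


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic survey."""

    extent_cells: int = 128
    cell_size: float = 120.0
    covariate_specs: list[CovariateSpec] = field(default_factory=lambda: [
        CovariateSpec("tree_cover", CONTINUOUS, 960.0),
        CovariateSpec("elevation", CONTINUOUS, 1920.0),
        CovariateSpec("human_footprint", CONTINUOUS, 3840.0),
        CovariateSpec("dipterocarp_forest", "categorical", 960.0, 0.5),
    ])
    n_stations: int = 578
    n_clusters: int = 10
    cluster_dispersion: float = 900.0     # metres, sd of station scatter per cluster
    true_scales: dict[str, float] = field(default_factory=lambda: {
        "tree_cover": 960.0, "elevation": 120.0, "human_footprint": 3840.0,
        "dipterocarp_forest": 480.0,
    })
    true_beta: dict[str, float] = field(default_factory=lambda: {
        "intercept": -1.0, "effort": 0.005,
        "tree_cover": 1.0, "elevation": 0.7, "human_footprint": -0.8,
    })
    effort_mean: float = 125.0
    effort_sd: float = 40.0
    count_extra_mean: float = 2.0         # mean of the Poisson on top of presence
    activity_specs: dict[str, ActivitySpec] = field(
        default_factory=lambda: dict(ACTIVITY_ARCHETYPES))
    cooccurrence_beta: dict[tuple[str, str], float] = field(default_factory=dict)
    prey_rates: dict[str, float] = field(default_factory=dict)  # Poisson mean counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_cells < 16:
            raise ValueError("extent_cells must be >= 16")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_stations < 2:
            raise ValueError("n_stations must be >= 2")
        for spec in self.covariate_specs:
            if spec.autocorrelation_range < 0:
                raise ValueError(f"negative autocorrelation range for {spec.name!r}")
            if spec.kind.startswith("cat") and not (0.0 < spec.class_threshold < 1.0):
                raise ValueError(f"class_threshold outside (0,1) for {spec.name!r}")

    @property
    def extent_m(self) -> float:
        return self.extent_cells * self.cell_size


def _smooth_field(rng: np.random.Generator, n: int, range_m: float, cell: float) -> np.ndarray:
    field = rng.standard_normal((n, n))
    if range_m > 0:
        field = gaussian_filter(field, sigma=range_m / cell, mode="reflect")
    sd = field.std()
    return (field - field.mean()) / (sd if sd > 0 else 1.0)


def generate_covariate_stack(config: SyntheticConfig, seed: int) -> dict[str, Raster]:
    """One raster per covariate spec on the shared grid.

    Continuous layers are standardized over cells (mean 0, sd 1); categorical
    layers are 0/1 indicators covering the stated quantile fraction of cells.
    Identical (config, seed) gives a bit-identical stack.
    """
    rng = np.random.default_rng(seed)
    stack: dict[str, Raster] = {}
    for spec in config.covariate_specs:
        if spec.autocorrelation_range == 0 and spec.kind.startswith("cat"):
            pass  # white-noise categorical layers are allowed, if unusual
        field = _smooth_field(rng, config.extent_cells, spec.autocorrelation_range,
                              config.cell_size)
        if spec.kind.startswith("cat"):
            thr = np.quantile(field, 1.0 - spec.class_threshold)
            vals = (field >= thr).astype(float)
            stack[spec.name] = Raster(vals, config.cell_size, kind=CATEGORICAL,
                                      name=spec.name)
        else:
            stack[spec.name] = Raster(field, config.cell_size, kind=CONTINUOUS,
                                      name=spec.name)
    return stack


def place_stations(config: SyntheticConfig, seed: int) -> pd.DataFrame:
    """Clustered station table with effort, road and ridge flags.

    Cluster centres stand in for study areas; station coordinates scatter
    normally around their centre and are redrawn until inside the extent.
    Effort is truncated-normal trap-nights (always > 0).
    """
    rng = np.random.default_rng(seed)
    margin = 2.0 * config.cluster_dispersion
    lo, hi = margin, config.extent_m - margin
    if hi <= lo:
        lo, hi = 0.0, config.extent_m
    centres = rng.uniform(lo, hi, size=(config.n_clusters, 2))
    rows = []
    for i in range(config.n_stations):
        c = i % config.n_clusters
        for _ in range(1000):
            xy = centres[c] + rng.normal(0.0, config.cluster_dispersion, size=2)
            if 0 <= xy[0] < config.extent_m and 0 <= xy[1] < config.extent_m:
                break
        else:
            xy = rng.uniform(0.0, config.extent_m, size=2)
        effort = max(1.0, rng.normal(config.effort_mean, config.effort_sd))
        rows.append({
            "station_id": f"ST{i:04d}", "x": xy[0], "y": xy[1],
            "elevation": 300.0 + 100.0 * rng.standard_normal(),
            "effort": effort,
            "road": bool(rng.random() < 0.3),
            "ridge": bool(rng.random() < 0.25),
            "area_id": f"A{c:02d}",
        })
    return pd.DataFrame(rows)


def station_design(stack: dict[str, Raster], stations: pd.DataFrame,
                   config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Standardized station values of each true-scale covariate."""
    x = stations["x"].to_numpy()
    y = stations["y"].to_numpy()
    design = {}
    for name, scale in config.true_scales.items():
        if name not in stack:
            raise KeyError(f"true_scales refers to unknown covariate {name!r}")
        smoothed = focal_mean(stack[name], scale)
        cov = extract_standardize(smoothed, x, y, name=name, scale=scale)
        design[name] = cov.station_values
    return design


def simulate_detections(stack: dict[str, Raster], stations: pd.DataFrame,
                        config: SyntheticConfig, seed: int,
                        species: str = "felid") -> pd.DataFrame:
    """Presence and independent detection counts for one species.

    logit z = b0 + sum_k b_k * (true-scale focal covariate, standardized
    across stations) + b_effort * effort; presence ~ Bernoulli(expit(z));
    count = presence * (1 + Poisson(count_extra_mean)).
    """
    for name in config.true_beta:
        if name in ("intercept", "effort"):
            continue
        if name not in stack:
            raise KeyError(f"true_beta refers to unknown covariate {name!r}")
    rng = np.random.default_rng(seed)
    design = station_design(stack, stations, config)
    z = np.full(len(stations), config.true_beta.get("intercept", 0.0))
    z += config.true_beta.get("effort", 0.0) * stations["effort"].to_numpy()
    for name, beta in config.true_beta.items():
        if name in ("intercept", "effort"):
            continue
        z += beta * design[name]
    presence = rng.random(len(stations)) < expit(z)
    extra = rng.poisson(config.count_extra_mean, size=len(stations))
    counts = np.where(presence, 1 + extra, 0)
    return pd.DataFrame({
        "station_id": stations["station_id"].to_numpy(),
        "species": species,
        "presence": presence.astype(int),
        "count": counts,
        "prob": expit(z),
    })


def simulate_activity_times(species: str, n: int, config: SyntheticConfig,
                            seed: int) -> np.ndarray:
    """n angles in [0, 2*pi) from the species' von Mises mixture."""
    if species not in config.activity_specs:
        raise KeyError(f"no activity spec for species {species!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = config.activity_specs[species]
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(spec.weights), size=n, p=np.asarray(spec.weights))
    angles = np.empty(n)
    for j, (mu, kappa) in enumerate(zip(spec.means, spec.kappas)):
        mask = comp == j
        m = int(mask.sum())
        if m == 0:
            continue
        if kappa == 0:
            angles[mask] = rng.uniform(0.0, 2.0 * np.pi, size=m)
        else:
            angles[mask] = rng.vonmises(mu, kappa, size=m)
    return angles % (2.0 * np.pi)


def simulate_community(stations: pd.DataFrame, config: SyntheticConfig,
                       seed: int) -> pd.DataFrame:
    """Multi-species detection matrix with felid-on-prey co-occurrence effects.

    Prey counts are independent Poisson draws per station; each felid's
    presence is Bernoulli(expit(b0 + sum cooccurrence_beta * prey count +
    b_effort * effort)).  Felid-on-felid dependencies are rejected.
    """
    felids = {f for (f, _p) in config.cooccurrence_beta}
    for (f, p) in config.cooccurrence_beta:
        if p in felids:
            raise ValueError(f"cyclic felid-on-felid dependency: {f!r} -> {p!r}")
    if (stations["effort"] <= 0).any():
        raise ValueError("stations with non-positive effort")
    rng = np.random.default_rng(seed)
    n = len(stations)
    matrix = pd.DataFrame(index=pd.Index(stations["station_id"], name="station_id"))
    prey_names = list(config.prey_rates) or sorted({p for (_f, p) in config.cooccurrence_beta})
    for prey in prey_names:
        rate = config.prey_rates.get(prey, 3.0)
        matrix[prey] = rng.poisson(rate, size=n)
    effort = stations["effort"].to_numpy()
    for felid in sorted(felids):
        z = np.full(n, config.true_beta.get("intercept", -1.0))
        z += config.true_beta.get("effort", 0.0) * effort
        for (f, prey), beta in config.cooccurrence_beta.items():
            if f == felid:
                z += beta * matrix[prey].to_numpy()
        presence = rng.random(n) < expit(z)
        extra = rng.poisson(config.count_extra_mean, size=n)
        matrix[felid] = np.where(presence, 1 + extra, 0)
    return matrix


def detections_to_records(counts: pd.DataFrame, species: str,
                          config: SyntheticConfig, seed: int,
                          start: str = "2012-01-01") -> pd.DataFrame:
    """Expand per-station counts into timestamped detection records.

    Each detection gets a uniformly drawn survey day and a clock time drawn
    from the species' activity mixture (archetype fallback: cathemeral).
    """
    rng = np.random.default_rng(seed)
    spec_key = species if species in config.activity_specs else "cathemeral"
    total = int(counts["count"].sum())
    if total == 0:
        return pd.DataFrame(columns=["station_id", "species", "timestamp"])
    angles = simulate_activity_times(spec_key, total, config,
                                     seed=int(rng.integers(0, 2**31 - 1)))
    days = rng.integers(0, 365, size=total)
    seconds = (angles / (2.0 * np.pi) * 86400.0).astype(int)
    base = pd.Timestamp(start)
    rows = []
    i = 0
    for sid, cnt in zip(counts["station_id"], counts["count"]):
        for _ in range(int(cnt)):
            ts = base + pd.Timedelta(days=int(days[i]), seconds=int(seconds[i]))
            rows.append({"station_id": sid, "species": species,
                         "timestamp": ts.isoformat()})
            i += 1
    return pd.DataFrame(rows)
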