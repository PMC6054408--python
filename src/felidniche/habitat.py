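"""Per-species habitat pipeline, occurrence surfaces and co-occurrence models.

The habitat pipeline runs, in order: focal scaling of every covariate at the
seven analysis radii -> station extraction and standardization -> univariate
scale scans -> p > 0.2 screening -> |r| > 0.7 collinearity pruning ->
all-subsets ensemble -> full model averaging.  Trap effort and the intercept
are forced into every model.

The averaged model maps to a probability-of-occurrence surface through
p = e^z / (1 + e^z), with covariates standardized by the *station* constants
(so surfaces extrapolate on the training scale) and effort fixed at a scalar
(default: mean station effort).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import glm
from .glm import (AllSubsetsLogistic, FittedModel, ModelEnsemble, ScaleScan,
                  all_subsets, fit_logistic, model_average, prune_collinear,
                  scale_scan, screen_variables)
from .rasters import (DEFAULT_SCALES_M, Raster, ScaledCovariate,
                      extract_standardize, focal_mean)

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    BaseEstimator = object


@dataclass
class OccurrenceSurface:
    """Probability-of-occurrence raster with its model provenance."""

    raster: Raster
    species: str
    terms: list[str]
    scales: dict[str, float]
    coef: dict[str, float]


@dataclass
class SurfaceComparison:
    species_a: str
    species_b: str
    pearson_r: float            # NaN when a surface is constant
    mean_abs_diff: float


@dataclass
class HabitatPipelineResult:
    species: str
    scans: list[ScaleScan]
    screened: list[ScaleScan]
    retained: list[str]
    ensemble: ModelEnsemble
    covariates: dict[str, ScaledCovariate]   # best-scale, standardized
    effort: np.ndarray
    y: np.ndarray

    def summary(self) -> pd.DataFrame:
        """Ensemble summary in report layout: variable, scale, beta, SE, z, importance, p."""
        scale_of = {sc.variable: sc.best_scale for sc in self.scans}
        rows = []
        for term, avg in self.ensemble.averaged.items():
            rows.append({
                "variable": term,
                "optimal_scale_m": scale_of.get(term, np.nan),
                "beta": avg.coef, "adjusted_se": avg.adjusted_se,
                "z_value": avg.zvalue, "aic_importance": avg.importance,
                "p_value": avg.pvalue,
            })
        return pd.DataFrame(rows)


class MultiScaleHabitatModel(BaseEstimator):
    """Scale-optimized, model-averaged logistic occurrence model.

    A scikit-learn style estimator over (rasters, stations): ``fit`` runs the
    full scale-scan / screen / prune / all-subsets chain and exposes the
    averaged model; ``predict_surface`` maps it back over the landscape.

    Parameters
    ----------
    scales : focal radii in metres (default: the 7 analysis radii 120..7680).
    p_screen : univariate screening threshold (variables with p > p_screen drop).
    r_prune : collinearity threshold on |Pearson r|.
    criterion : information criterion for ensemble weights ("aicc" or "aic").
    """

    def __init__(self, scales: tuple[float, ...] = DEFAULT_SCALES_M,
                 p_screen: float = 0.2, r_prune: float = 0.7,
                 criterion: str = "aicc"):
        self.scales = scales
        self.p_screen = p_screen
        self.r_prune = r_prune
        self.criterion = criterion

    def fit(self, rasters: dict[str, Raster], stations: pd.DataFrame, y: np.ndarray):
        y = np.asarray(y, dtype=float).ravel()
        x = stations["x"].to_numpy(dtype=float)
        ycoord = stations["y"].to_numpy(dtype=float)
        effort = stations["effort"].to_numpy(dtype=float)
        base = np.column_stack([np.ones_like(effort), effort])

        scans: list[ScaleScan] = []
        values: dict[str, dict[float, ScaledCovariate]] = {}
        for name, raster in rasters.items():
            by_scale: dict[float, ScaledCovariate] = {}
            for s in self.scales:
                cov = extract_standardize(focal_mean(raster, s), x, ycoord,
                                          name=name, scale=s)
                if not cov.degenerate:
                    by_scale[s] = cov
            if not by_scale:
                warnings.warn(f"covariate {name!r} degenerate at every scale; excluded")
                continue
            values[name] = by_scale
            scans.append(scale_scan(y, name,
                                    {s: c.station_values for s, c in by_scale.items()},
                                    base))

        screened = screen_variables(scans, self.p_screen)
        cols = {sc.variable: values[sc.variable][sc.best_scale].station_values
                for sc in screened}
        aics = {sc.variable: sc.best_aic for sc in screened}
        retained = prune_collinear(cols, aics, self.r_prune) if cols else []
        if not retained:
            warnings.warn("all variables screened out; forced-terms-only model")
        free = {name: cols[name] for name in retained}
        forced = {"(Intercept)": np.ones_like(effort), "effort": effort}
        ensemble = all_subsets(y, free, forced, criterion=self.criterion)

        self.result_ = HabitatPipelineResult(
            species="", scans=scans, screened=screened, retained=retained,
            ensemble=ensemble,
            covariates={sc.variable: values[sc.variable][sc.best_scale]
                        for sc in screened},
            effort=effort, y=y)
        self.ensemble_ = ensemble
        self.scans_ = scans
        self.retained_ = retained
        return self

    def station_probabilities(self) -> np.ndarray:
        """Averaged-model probabilities at the fitting stations (their own effort)."""
        res = self.result_
        avg = res.ensemble.averaged
        z = np.full(res.effort.size, avg["(Intercept)"].coef)
        z += avg["effort"].coef * res.effort
        for name in res.retained:
            z += avg[name].coef * res.covariates[name].station_values
        return expit(z)

    def predict_surface(self, rasters: dict[str, Raster], species: str = "",
                        effort_value: float | None = None) -> OccurrenceSurface:
        res = self.result_
        return predict_surface(res.ensemble,
                               {name: rasters[name] for name in res.retained},
                               {name: res.covariates[name] for name in res.retained},
                               {name: res.covariates[name].scale for name in res.retained},
                               effort_value if effort_value is not None
                               else float(np.mean(res.effort)),
                               species=species)


def run_habitat_pipeline(species: str, rasters: dict[str, Raster],
                         stations: pd.DataFrame, matrix: pd.DataFrame,
                         scales: tuple[float, ...] = DEFAULT_SCALES_M,
                         p_screen: float = 0.2, r_prune: float = 0.7,
                         criterion: str = "aicc") -> HabitatPipelineResult:
    """Full habitat chain for one species of a detection matrix."""
    if species not in matrix.columns:
        raise KeyError(f"species {species!r} not in detection matrix")
    counts = matrix[species].reindex(stations["station_id"]).to_numpy()
    y = (counts > 0).astype(float)
    model = MultiScaleHabitatModel(scales, p_screen, r_prune, criterion)
    model.fit(rasters, stations, y)
    model.result_.species = species
    return model.result_


def predict_surface(ensemble: ModelEnsemble, rasters: dict[str, Raster],
                    standardizers: dict[str, ScaledCovariate],
                    scales: dict[str, float], effort_value: float,
                    species: str = "") -> OccurrenceSurface:
    """Map the averaged model over the landscape: p = e^z / (1 + e^z).

    ``rasters`` holds the raw covariates (focal means are taken at each
    term's optimal scale); each term is standardized with its *station*
    mean/sd before applying the averaged coefficient.  Nodata propagates.
    """
    avg = ensemble.averaged
    missing = [t for t in ensemble.free_terms if t not in rasters]
    if missing:
        raise KeyError(f"missing rasters for ensemble terms: {missing}")
    ref = next(iter(rasters.values())) if rasters else None
    if ref is None:
        raise ValueError("intercept-only surfaces need at least one raster for the grid")
    z = np.full(ref.shape, avg["(Intercept)"].coef)
    z += avg["effort"].coef * effort_value if "effort" in avg else 0.0
    for term in ensemble.free_terms:
        std = standardizers[term]
        smoothed = focal_mean(rasters[term], scales[term])
        if std.sd <= 0:
            continue
        z = z + avg[term].coef * (smoothed.values - std.mean) / std.sd
    prob = expit(z)
    prob = np.where(np.isfinite(z), prob, np.nan)
    out = Raster(prob, ref.cell_size, ref.x0, ref.y0, name=f"p_occurrence_{species}")
    coef = {t: avg[t].coef for t in ensemble.all_terms}
    return OccurrenceSurface(out, species, ensemble.all_terms, dict(scales), coef)


def compare_surfaces(a: OccurrenceSurface, b: OccurrenceSurface) -> SurfaceComparison:
    """Pearson r and mean |a - b| over jointly finite cells."""
    va, vb = a.raster.values, b.raster.values
    if va.shape != vb.shape:
        raise ValueError("surfaces must share a grid")
    ok = np.isfinite(va) & np.isfinite(vb)
    x, y = va[ok], vb[ok]
    mad = float(np.mean(np.abs(x - y)))
    if np.std(x) < 1e-15 or np.std(y) < 1e-15:
        r = np.nan  # correlation undefined for a constant surface
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return SurfaceComparison(a.species, b.species, r, mad)


def surface_comparison_matrix(surfaces: list[OccurrenceSurface]) -> pd.DataFrame:
    """Pairwise table: correlations in the lower triangle, mean absolute
    differences in the upper triangle."""
    names = [s.species for s in surfaces]
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(surfaces):
        for j, b in enumerate(surfaces):
            if i == j:
                continue
            cmp_ = compare_surfaces(a, b)
            out.iloc[i, j] = cmp_.mean_abs_diff if j > i else cmp_.pearson_r
    return out


def univariate_association(y: np.ndarray, flag: np.ndarray) -> FittedModel:
    """Logistic fit of occurrence on a 0/1 station attribute (road / ridgeline)."""
    flag = np.asarray(flag, dtype=float).ravel()
    if len(np.unique(flag)) < 2:
        raise ValueError("flag has a single level; association undefined")
    y = np.asarray(y, dtype=float).ravel()
    X = np.column_stack([np.ones_like(flag), flag])
    return fit_logistic(y, X, terms=["(Intercept)", "flag"])


def prey_cooccurrence_model(felid: str, matrix: pd.DataFrame,
                            effort: np.ndarray, min_detections: int = 20,
                            cap: int = glm.MAX_FREE_TERMS,
                            criterion: str = "aicc") -> ModelEnsemble:
    """All-subsets ensemble of felid occurrence on candidate-prey counts.

    Response: felid detected / not detected per station.  Predictors: raw
    independent detection counts of every candidate passing the
    >= ``min_detections`` filter, plus forced effort.  When more candidates
    pass than the all-subsets cap allows, they are pre-screened to the cap by
    univariate AICc rank (the cap and the pre-screen are recorded on the
    returned ensemble's ``prescreened_from`` attribute).
    """
    from .detections import filter_min_detections

    if felid not in matrix.columns:
        raise KeyError(f"felid {felid!r} not in matrix")
    effort = np.asarray(effort, dtype=float).ravel()
    y = (matrix[felid].to_numpy() > 0).astype(float)
    candidates = [sp for sp in filter_min_detections(matrix, min_detections)
                  if sp != felid]
    base = np.column_stack([np.ones_like(effort), effort])
    n_available = len(candidates)
    if n_available > cap:
        ranked = []
        for sp in candidates:
            fit = fit_logistic(y, np.column_stack([base, matrix[sp].to_numpy(dtype=float)]))
            ranked.append((fit.aicc if fit.converged else np.inf, sp))
        ranked.sort(key=lambda t: t[0])
        candidates = [sp for _, sp in ranked[:cap]]
    free = {sp: matrix[sp].to_numpy(dtype=float) for sp in candidates}
    forced = {"(Intercept)": np.ones_like(effort), "effort": effort}
    ensemble = all_subsets(y, free, forced, criterion=criterion)
    ensemble.prescreened_from = n_available  # type: ignore[attr-defined]
    return ensemble


def cooccurrence_summary(ensemble: ModelEnsemble, felid: str) -> pd.DataFrame:
    """Report layout: AICc importance, beta, adjusted SE, z, p per term."""
    rows = []
    for term, avg in ensemble.averaged.items():
        rows.append({"felid": felid, "term": term,
                     "aicc_importance": avg.importance, "beta": avg.coef,
                     "adjusted_se": avg.adjusted_se, "z_score": avg.zvalue,
                     "p_value": avg.pvalue})
    df = pd.DataFrame(rows)
    order = df["term"].ne("(Intercept)")
    return pd.concat([df[~order], df[order].sort_values("p_value")],
                     ignore_index=True)
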