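"""Logistic regression core and multi-model inference machinery.

Implements the model-building chain used throughout the occurrence analyses:

1. univariate *scale scans* — refit one covariate at each focal radius and
   keep the radius with the lowest AIC;
2. screening of weakly related variables (univariate p > 0.2 removed);
3. collinearity pruning (|Pearson r| > 0.7 pairs resolved by keeping the
   lower-AIC member);
4. all-subsets enumeration of the remaining terms with Akaike (AICc) weights;
5. full model averaging: coefficients averaged over all subsets with absent
   terms contributing zero, unconditional (model-selection-inclusive)
   standard errors, and per-term relative importance (sum of weights of the
   models containing the term).

The maximum-likelihood fitter is iteratively reweighted least squares with
Wald standard errors from the inverse observed information.  Perfectly
separated fits (coefficients diverging beyond |beta| > 50 on the
standardized scale) are flagged non-converged and dropped from ensembles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit

MAX_FREE_TERMS = 15
SEPARATION_BOUND = 50.0


@dataclass
class FittedModel:
    """A single maximum-likelihood logistic fit."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    k: int
    converged: bool = True

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def aicc(self) -> float:
        if self.n > self.k + 1:
            return self.aic + 2 * self.k * (self.k + 1) / (self.n - self.k - 1)
        return np.inf

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se > 0, np.abs(self.coef) / self.se, np.inf)

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * stats.norm.sf(self.zvalues)


def _loglik_bernoulli(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def fit_logistic(y: np.ndarray, X: np.ndarray, terms: list[str] | None = None,
                 max_iter: int = 100, score_tol: float = 1e-8,
                 loglik_rtol: float = 1e-10) -> FittedModel:
    """IRLS maximum-likelihood logistic fit.

    ``X`` must already contain the intercept column.  Convergence when the
    maximum absolute score drops below ``score_tol`` or the relative change
    in log-likelihood falls below ``loglik_rtol``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("response must be binary 0/1")
    if terms is None:
        terms = [f"x{j}" for j in range(k)]

    beta = np.zeros(k)
    ll_old = _loglik_bernoulli(y, X @ beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        ll = _loglik_bernoulli(y, X @ beta)
        if np.max(np.abs(score)) < score_tol or abs(ll - ll_old) <= loglik_rtol * (abs(ll_old) + 1e-12):
            converged = True
            ll_old = ll
            break
        ll_old = ll

    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.inf)
        converged = False
    loglik = _loglik_bernoulli(y, X @ beta)
    if np.any(np.abs(beta) > SEPARATION_BOUND) or loglik > -1e-4:
        # coefficients diverging, or a perfectly classified binary response:
        # the hallmark of complete separation
        converged = False
    return FittedModel(terms=list(terms), coef=beta, se=se,
                       loglik=loglik, n=n, k=k, converged=converged)


# ---------------------------------------------------------------------------
# Univariate scale optimization and variable screening


@dataclass
class ScaleScan:
    """AIC profile of one covariate across the analysis scales."""

    variable: str
    scales: list[float]
    aic: list[float]                 # inf where the fit did not converge
    coef: list[float]
    pvalue: list[float]
    best_scale: float
    best_index: int

    @property
    def best_pvalue(self) -> float:
        return self.pvalue[self.best_index]

    @property
    def best_aic(self) -> float:
        return self.aic[self.best_index]

    @property
    def best_coef(self) -> float:
        return self.coef[self.best_index]


def scale_scan(y: np.ndarray, variable: str, values_by_scale: dict[float, np.ndarray],
               base: np.ndarray) -> ScaleScan:
    """Fit base + covariate(scale) at each scale; lowest AIC wins, ties to the
    smallest radius.  Non-converged scales are excluded from the minimum."""
    scales = sorted(values_by_scale)
    aics, coefs, ps = [], [], []
    slope_col = base.shape[1]
    for s in scales:
        X = np.column_stack([base, values_by_scale[s]])
        fit = fit_logistic(y, X)
        if fit.converged:
            aics.append(fit.aic)
            coefs.append(float(fit.coef[slope_col]))
            ps.append(float(fit.pvalues[slope_col]))
        else:
            aics.append(np.inf)
            coefs.append(np.nan)
            ps.append(np.nan)
    if not np.any(np.isfinite(aics)):
        raise ValueError(f"no scale converged for variable {variable!r}")
    best = int(np.argmin(aics))  # argmin takes the first (smallest radius) on ties
    return ScaleScan(variable, scales, aics, coefs, ps, scales[best], best)


def screen_variables(scans: list[ScaleScan], p_threshold: float = 0.2) -> list[ScaleScan]:
    """Keep variables whose best-scale univariate slope has p <= threshold."""
    return [sc for sc in scans if sc.best_pvalue <= p_threshold]


def prune_collinear(columns: dict[str, np.ndarray], aic: dict[str, float],
                    r_threshold: float = 0.7) -> list[str]:
    """Resolve |Pearson r| > threshold pairs by dropping the higher-AIC member.

    Pairs are processed in descending |r|; a variable already dropped cannot
    cause further drops.
    """
    names = list(columns)
    if len(names) <= 1:
        return names
    mat = np.column_stack([columns[n] for n in names])
    r = np.corrcoef(mat, rowvar=False)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(r[i, j]) > r_threshold:
                pairs.append((abs(r[i, j]), i, j))
    pairs.sort(key=lambda t: -t[0])
    dropped: set[int] = set()
    for _, i, j in pairs:
        if i in dropped or j in dropped:
            continue
        # drop the higher-AIC member; ties drop the later-listed variable
        loser = j if aic[names[j]] >= aic[names[i]] else i
        dropped.add(loser)
    return [n for idx, n in enumerate(names) if idx not in dropped]


# ---------------------------------------------------------------------------
# All-subsets ensembles and model averaging


@dataclass
class AveragedTerm:
    term: str
    coef: float
    adjusted_se: float
    importance: float
    zvalue: float
    pvalue: float


@dataclass
class ModelEnsemble:
    """All-subsets logistic fits with Akaike weights and full model averages."""

    forced_terms: list[str]
    free_terms: list[str]
    masks: list[tuple[int, ...]]     # indices into free_terms per model
    models: list[FittedModel]
    criterion: str                   # "aicc" or "aic"
    delta: np.ndarray
    weights: np.ndarray
    averaged: dict[str, AveragedTerm] = field(default_factory=dict)

    @property
    def all_terms(self) -> list[str]:
        return self.forced_terms + self.free_terms


def all_subsets(y: np.ndarray, free: dict[str, np.ndarray],
                forced: dict[str, np.ndarray], criterion: str = "aicc") -> ModelEnsemble:
    """Fit all 2^p subsets of the free terms, each containing the forced terms.

    Akaike weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2) from the
    chosen criterion (AICc by default).  Non-converged fits are dropped
    before weight normalization.
    """
    free_terms = list(free)
    if len(free_terms) > MAX_FREE_TERMS:
        raise ValueError(
            f"{len(free_terms)} free terms exceed the cap of {MAX_FREE_TERMS}; "
            "pre-screen candidates (e.g. by univariate AICc rank) first"
        )
    forced_terms = list(forced)
    y = np.asarray(y, dtype=float).ravel()
    base = np.column_stack([forced[t] for t in forced_terms]) if forced_terms \
        else np.empty((y.size, 0))
    masks, models = [], []
    for r in range(len(free_terms) + 1):
        for combo in itertools.combinations(range(len(free_terms)), r):
            X = np.column_stack([base] + [free[free_terms[i]] for i in combo]) \
                if combo else base
            fit = fit_logistic(y, X, terms=forced_terms + [free_terms[i] for i in combo])
            if fit.converged:
                masks.append(combo)
                models.append(fit)
    if not models:
        raise ValueError("no subset model converged")
    crit = np.array([m.aicc if criterion == "aicc" else m.aic for m in models])
    delta = crit - crit.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    ens = ModelEnsemble(forced_terms, free_terms, masks, models, criterion, delta, w)
    ens.averaged = model_average(ens)
    return ens


def model_average(ensemble: ModelEnsemble) -> dict[str, AveragedTerm]:
    """Full (zero-substitution) model averaging with unconditional SEs.

    beta_bar = sum_i w_i beta_i with beta_i = 0 where the term is absent;
    unconditional variance = sum_i w_i [SE_i^2 + (beta_i - beta_bar)^2]
    (absent terms contribute SE 0, beta 0); importance = sum of weights of
    models containing the term; z = |beta_bar| / SE with a two-sided normal p.
    """
    out: dict[str, AveragedTerm] = {}
    for term in ensemble.all_terms:
        betas = np.zeros(len(ensemble.models))
        ses = np.zeros(len(ensemble.models))
        present = np.zeros(len(ensemble.models), dtype=bool)
        for m, fit in enumerate(ensemble.models):
            if term in fit.terms:
                idx = fit.terms.index(term)
                betas[m] = fit.coef[idx]
                ses[m] = fit.se[idx]
                present[m] = True
        w = ensemble.weights
        beta_bar = float(np.sum(w * betas))
        var = float(np.sum(w * (ses ** 2 + (betas - beta_bar) ** 2)))
        se = np.sqrt(var)
        importance = float(np.sum(w[present]))
        z = abs(beta_bar) / se if se > 0 else np.inf
        p = float(2 * stats.norm.sf(z))
        out[term] = AveragedTerm(term, beta_bar, se, importance, z, p)
    return out


# ---------------------------------------------------------------------------
# sklearn-style estimator facade

try:  # sklearn is optional at import time; the estimator needs it only for mixins
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        def get_params(self, deep=True):
            return {k: v for k, v in self.__dict__.items() if not k.endswith("_")}

        def set_params(self, **params):
            for k, v in params.items():
                setattr(self, k, v)
            return self


class AllSubsetsLogistic(BaseEstimator):
    """All-subsets logistic regression with Akaike-weight model averaging.

    A scikit-learn style estimator: ``fit(X, y)`` enumerates all subsets of
    the columns of ``X`` (plus an always-included intercept and any forced
    columns), and exposes the averaged inference as fitted attributes.

    Parameters
    ----------
    criterion : {"aicc", "aic"}
        Information criterion for the Akaike weights.
    forced : list of int
        Column indices of X forced into every model (e.g. survey effort).
    feature_names : list of str, optional
        Names for the columns of X.

    Attributes
    ----------
    ensemble_ : ModelEnsemble
    coef_ : ndarray of averaged coefficients (one per column of X)
    intercept_ : float
    adjusted_se_ : ndarray of unconditional SEs
    importance_ : ndarray of relative variable importances
    pvalues_ : ndarray
    """

    def __init__(self, criterion: str = "aicc", forced: list[int] | None = None,
                 feature_names: list[str] | None = None):
        self.criterion = criterion
        self.forced = forced
        self.feature_names = feature_names

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y have incompatible shapes")
        names = self.feature_names or [f"x{j}" for j in range(X.shape[1])]
        forced_idx = list(self.forced or [])
        forced = {"(Intercept)": np.ones(y.size)}
        for j in forced_idx:
            forced[names[j]] = X[:, j]
        free = {names[j]: X[:, j] for j in range(X.shape[1]) if j not in forced_idx}
        self.ensemble_ = all_subsets(y, free, forced, criterion=self.criterion)
        avg = self.ensemble_.averaged
        self.intercept_ = avg["(Intercept)"].coef
        self.coef_ = np.array([avg[n].coef for n in names])
        self.adjusted_se_ = np.array([avg[n].adjusted_se for n in names])
        self.importance_ = np.array([avg[n].importance for n in names])
        self.zvalues_ = np.array([avg[n].zvalue for n in names])
        self.pvalues_ = np.array([avg[n].pvalue for n in names])
        self.feature_names_in_ = np.array(names, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)
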