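"""Backcasting amenity counts from spatially aggregated population.

Early map coverage of points of interest is incomplete, so instead of trusting
historical amenity counts directly, a per-amenity regression is trained on a
well-covered reference year and used to predict counts for other years. The
covariates are the number of residents within 1 km and 5-50 km (5 km steps) of
each locality centroid; the target is ``log1p(count)``. Five model families
compete — linear regression, support-vector regression, gradient boosting,
k-nearest neighbours and a power law — and the family with the best test R^2
wins (ties broken by the fixed family order).

The power-law family regresses ``log1p(count)`` on ``ln(population within
1 km)``, the nearest-radius analog of locality population; the other four use
``log1p`` of all eleven radii features. Predictions are mapped back through
``expm1`` and floored at zero; they stay real-valued until export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .features import FeatureTable
from .radiation import DistanceMatrix, LocalityTable, ValidationError

logger = logging.getLogger("radflow")

DEFAULT_RADII_KM = (1.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0)
FAMILY_ORDER = ("linear", "svm", "gbm", "knn", "powerlaw")

#: small fixed hyperparameter grids per family (config-editable)
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "linear": [{}],
    "svm": [{"C": 1.0}, {"C": 10.0}],
    "gbm": [{"max_depth": 2, "n_estimators": 100}, {"max_depth": 3, "n_estimators": 100}],
    "knn": [{"n_neighbors": 3}, {"n_neighbors": 5}],
    "powerlaw": [{}],
}


@dataclass
class RadiiFeatureMatrix:
    """Locality x radius matrix of total population within each radius."""

    ids: np.ndarray
    radii: tuple[float, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.radii)):
            raise ValidationError("radii feature matrix shape mismatch")


def population_within_radii(
    localities: LocalityTable,
    distances: DistanceMatrix,
    year: int | None = None,
    radii: tuple[float, ...] = DEFAULT_RADII_KM,
    populations: np.ndarray | None = None,
) -> RadiiFeatureMatrix:
    """Total population within each radius of every centroid (self included).

    Inclusion is by centroid: locality k counts toward (i, r) iff d_ik <= r.
    Either a census ``year`` or an explicit ``populations`` vector is given.
    """
    if any(r <= 0 for r in radii):
        raise ValidationError(f"radii must be positive, got {radii}")
    if populations is None:
        if year is None:
            raise ValidationError("give either year or populations")
        populations = localities.population(year)
    pop = np.asarray(populations, dtype=float)
    d = distances.values
    out = np.empty((len(pop), len(radii)))
    for j, r in enumerate(radii):
        out[:, j] = ((d <= r) * pop[None, :]).sum(axis=1)
    return RadiiFeatureMatrix(localities.ids, tuple(float(r) for r in radii), out)


@dataclass
class PowerLawFit:
    amplitude: float
    exponent: float
    r_squared: float


def power_law_fit(x: np.ndarray, y: np.ndarray, log_mode: str = "log1p") -> PowerLawFit:
    """Least-squares power law ``y ~ a * x^beta`` on logarithmic scales.

    ``log_mode='log1p'`` (default) regresses ``log1p(y)`` on ``ln(x)``,
    matching the target transform used for count data; ``log_mode='raw'``
    regresses ``ln(y)`` on ``ln(x)``, the textbook log-log line (requires
    y > 0 and recovers a and beta exactly for noiseless power laws).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValidationError("power_law_fit needs at least 3 points")
    if (x <= 0).any():
        raise ValidationError("power_law_fit requires strictly positive x")
    if log_mode == "raw":
        if (y <= 0).any():
            raise ValidationError("raw log mode requires strictly positive y")
        t = np.log(y)
    elif log_mode == "log1p":
        if (y < 0).any():
            raise ValidationError("negative y")
        t = np.log1p(y)
    else:
        raise ValidationError(f"unknown log_mode {log_mode!r}")
    lx = np.log(x)
    beta, intercept = np.polyfit(lx, t, 1)
    pred = intercept + beta * lx
    ss_res = float(((t - pred) ** 2).sum())
    ss_tot = float(((t - t.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return PowerLawFit(float(np.exp(intercept)), float(beta), r2)


class _PowerLawRegressor:
    """Power-law family in the common (log-target) estimator interface."""

    def __init__(self) -> None:
        self.intercept_ = 0.0
        self.slope_ = 0.0

    @staticmethod
    def _covariate(x_radii: np.ndarray) -> np.ndarray:
        # population within the innermost radius, the closest analog of
        # locality population
        return np.log(np.maximum(x_radii[:, 0], 1.0))

    def fit(self, x_radii: np.ndarray, t: np.ndarray) -> "_PowerLawRegressor":
        lx = self._covariate(x_radii)
        self.slope_, self.intercept_ = np.polyfit(lx, t, 1)
        return self

    def predict(self, x_radii: np.ndarray) -> np.ndarray:
        return self.intercept_ + self.slope_ * self._covariate(x_radii)


def _make_estimator(family: str, params: dict, seed: int):
    if family == "linear":
        return LinearRegression(**params)
    if family == "svm":
        return make_pipeline(StandardScaler(), SVR(kernel="rbf", **params))
    if family == "gbm":
        return GradientBoostingRegressor(random_state=seed, **params)
    if family == "knn":
        return KNeighborsRegressor(**params)
    if family == "powerlaw":
        return _PowerLawRegressor()
    raise ValidationError(f"unknown model family {family!r}")


@dataclass
class BackcastModel:
    """Selected regression for one amenity type (log1p-count target)."""

    amenity: str
    family: str
    hyperparameters: dict
    test_r2: float
    estimator: object
    split_seed: int
    candidate_scores: dict[str, float] = field(default_factory=dict)

    def predict_counts(self, radii_features: RadiiFeatureMatrix) -> np.ndarray:
        x = np.log1p(radii_features.values)
        pred = self.estimator.predict(x if self.family != "powerlaw" else radii_features.values)
        return np.maximum(np.expm1(pred), 0.0)


@dataclass
class SplitConfig:
    test_fraction: float = 0.2
    seed: int = 0


def fit_backcast_models(
    radii_features: RadiiFeatureMatrix,
    amenity_counts: FeatureTable,
    families: tuple[str, ...] = FAMILY_ORDER,
    split: SplitConfig | None = None,
    grids: dict[str, list[dict]] | None = None,
) -> dict[str, BackcastModel]:
    """Fit all families per amenity and keep the best by test R^2.

    Within each family the small hyperparameter grid is also scored on the
    test split; the overall winner is the best (family, hyperparameters)
    combination, ties resolved by the fixed family order.
    """
    if not families:
        raise ValidationError("empty model family list")
    unknown = [f for f in families if f not in FAMILY_ORDER]
    if unknown:
        raise ValidationError(f"unknown families {unknown}; choose from {FAMILY_ORDER}")
    if not np.array_equal(radii_features.ids, amenity_counts.locality_ids):
        raise ValidationError("radii features and amenity counts have different localities")
    split = split or SplitConfig()
    grids = {**DEFAULT_GRIDS, **(grids or {})}
    x_raw = radii_features.values
    x_log = np.log1p(x_raw)
    idx = np.arange(len(radii_features.ids))
    train, test = train_test_split(idx, test_size=split.test_fraction,
                                   random_state=split.seed)
    models: dict[str, BackcastModel] = {}
    for name in amenity_counts.feature_names:
        t = np.log1p(amenity_counts.column(name))
        best: BackcastModel | None = None
        scores: dict[str, float] = {}
        for family in families:
            for params in grids[family]:
                est = _make_estimator(family, params, seed=split.seed)
                xf = x_raw if family == "powerlaw" else x_log
                est.fit(xf[train], t[train])
                if np.allclose(t[test], t[test].mean()):
                    # constant test target: R^2 undefined; score exactness
                    r2 = 1.0 if np.allclose(est.predict(xf[test]), t[test]) else 0.0
                else:
                    r2 = float(r2_score(t[test], est.predict(xf[test])))
                key = f"{family}:{params}" if len(grids[family]) > 1 else family
                scores[key] = max(scores.get(key, -np.inf), r2)
                if best is None or r2 > best.test_r2:
                    best = BackcastModel(name, family, dict(params), r2, est, split.seed)
        best.candidate_scores = scores
        models[name] = best
        logger.info("backcast %s: %s (test R^2 = %.4f)", name, best.family, best.test_r2)
    return models


def predict_amenity_counts(
    models: dict[str, BackcastModel],
    radii_features: RadiiFeatureMatrix,
) -> FeatureTable:
    """Predicted per-amenity counts for the given radii features."""
    if not models:
        raise ValidationError("no fitted backcast models")
    names = list(models)
    cols = [models[n].predict_counts(radii_features) for n in names]
    return FeatureTable(radii_features.ids, names, np.column_stack(cols))
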