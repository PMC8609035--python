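"""Iterative annual population forecasting from a calibrated model.

The model is calibrated on a multi-year census interval (three years in the
reference setting), so its raw population change is a per-interval quantity;
each annual step divides it by the calibration span. Every step re-projects
the amenity features from the previous year's populations through the fitted
backcast models, normalizes them with the statistics frozen at calibration
time, evaluates the population-balance equation with the previous year's
birth and death rates, and updates populations (floored at zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .amenities import (DEFAULT_RADII_KM, BackcastModel, population_within_radii,
                        predict_amenity_counts)
from .calibration import GRMParameters, _Engine, CalibrationData
from .features import (FeatureTable, NormalizedFeatureTable, apply_normalization,
                       POPULATION_FEATURES)
from .radiation import DistanceMatrix, LocalityTable, ValidationError

logger = logging.getLogger("radflow")


def annualize(raw_delta: np.ndarray, calibration_span_years: int = 3) -> np.ndarray:
    """Convert a per-calibration-interval change to an annual one."""
    if calibration_span_years < 1:
        raise ValidationError("calibration span must be >= 1 year")
    return np.asarray(raw_delta, dtype=float) / calibration_span_years


@dataclass
class ForecastTrajectory:
    """Year-indexed per-locality population forecasts with provenance."""

    ids: np.ndarray
    populations: dict[int, np.ndarray]
    provenance: dict = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        return sorted(self.populations)

    def final(self) -> np.ndarray:
        return self.populations[self.years[-1]]


class FeatureProjector:
    """Rebuild the model's feature table for arbitrary population vectors.

    ``population`` and ``population_density`` are recomputed from the current
    populations and the fixed land areas; every other feature name must have a
    fitted backcast model, evaluated on population-within-radii features that
    are themselves recomputed from the current populations.
    """

    def __init__(self, localities: LocalityTable, distances: DistanceMatrix,
                 feature_names: list[str],
                 amenity_models: dict[str, BackcastModel] | None = None,
                 radii: tuple[float, ...] = DEFAULT_RADII_KM):
        self.localities = localities
        self.distances = distances
        self.feature_names = list(feature_names)
        self.models = amenity_models or {}
        self.radii = radii
        missing = [n for n in self.feature_names
                   if n not in POPULATION_FEATURES and n not in self.models]
        if missing:
            raise ValidationError(f"no fitted amenity model for features {missing}")

    def table_for(self, populations: np.ndarray) -> FeatureTable:
        amenity_names = [n for n in self.feature_names if n not in POPULATION_FEATURES]
        predicted = None
        if amenity_names:
            radii_feats = population_within_radii(self.localities, self.distances,
                                                  radii=self.radii, populations=populations)
            predicted = predict_amenity_counts(
                {n: self.models[n] for n in amenity_names}, radii_feats)
        cols = []
        for name in self.feature_names:
            if name == "population":
                cols.append(np.asarray(populations, dtype=float))
            elif name == "population_density":
                cols.append(np.asarray(populations, dtype=float) / self.localities.land_area)
            else:
                cols.append(predicted.column(name))
        return FeatureTable(self.localities.ids, self.feature_names, np.column_stack(cols))


def forecast(
    params: GRMParameters,
    localities: LocalityTable,
    base_year: int,
    horizon_years: int,
    vital_rates_by_year: dict[int, tuple[float, float]],
    normalization: NormalizedFeatureTable,
    projector: FeatureProjector,
    distances: DistanceMatrix,
    calibration_span_years: int = 3,
    compound_rates: bool = True,
) -> ForecastTrajectory:
    """Iterate annual forecasts from ``base_year`` for ``horizon_years``.

    The forecast for year ``y`` uses year ``y-1`` populations, amenity counts
    projected from them, and the vital rates recorded for year ``y-1``
    (``vital_rates_by_year[y-1] = (birth_rate, death_rate)``).
    """
    if horizon_years < 1:
        raise ValidationError("horizon must be >= 1 year")
    pop = localities.population(base_year).astype(float)
    trajectory: dict[int, np.ndarray] = {}
    n_floored_total = 0
    for y in range(base_year + 1, base_year + horizon_years + 1):
        prev = y - 1
        if prev not in vital_rates_by_year:
            raise ValidationError(f"no vital rates for year {prev}")
        b, d = vital_rates_by_year[prev]
        table = projector.table_for(pop)
        norm = apply_normalization(normalization, table)
        work = localities.with_population(prev, pop).with_population(
            prev + calibration_span_years, pop)  # target column only carries shape
        data = CalibrationData(work, norm, distances, prev,
                               prev + calibration_span_years, b, d,
                               compound_rates=compound_rates)
        eng = _Engine(data)
        m, _ = eng.masses(params.weights)
        *_, delta_hat = eng.forward(m, params.alpha_for(eng.n))
        new_pop = pop + annualize(delta_hat, calibration_span_years)
        n_floored = int((new_pop < 0).sum())
        if n_floored:
            n_floored_total += n_floored
            logger.warning("year %d: floored %d negative populations to 0", y, n_floored)
        pop = np.maximum(new_pop, 0.0)
        trajectory[y] = pop.copy()
    return ForecastTrajectory(localities.ids, trajectory, {
        "base_year": base_year,
        "horizon_years": horizon_years,
        "calibration_span_years": calibration_span_years,
        "feature_names": list(params.feature_names),
        "normalization": params.normalization,
        "seed": params.seed,
        "n_floored": n_floored_total,
    })
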