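"""Radiation-model primitives: geometry, intervening mass and flow equations.

The radiation model predicts the expected migrant flow from locality *i* to
locality *j* as

    <T_ij> = T_i * m_i * m_j / ((m_i + s_ij) * (m_i + m_j + s_ij)),

where ``T_i`` is the total number of out-migrants of *i*, ``m`` is the
attractiveness mass of each locality (census population in the classic model,
a trainable urbanization index in the generalized model) and ``s_ij`` is the
total mass strictly closer to *i* than *j* is — the "intervening opportunities"
inside the circle centred at *i* and touching *j*, excluding both endpoints.

Everything here is pure numpy on dense matrices; distances are computed once
and reused for every mass vector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("radflow")

EARTH_RADIUS_KM = 6371.0
#: floor applied to non-positive masses before the flow equation
MASS_FLOOR = 1e-9


class ValidationError(ValueError):
    """Raised when an input table or argument violates a documented invariant."""


# ---------------------------------------------------------------------------
# Locality table
# ---------------------------------------------------------------------------


@dataclass
class LocalityTable:
    """Per-locality geography and census populations.

    Parameters
    ----------
    ids
        Unique locality identifiers (order defines matrix order everywhere).
    names
        Human-readable names, aligned with ``ids``.
    latitude, longitude
        Centroid coordinates in decimal degrees.
    land_area
        Land area in km^2, strictly positive.
    populations
        Mapping census year -> per-locality population vector. Populations are
        real-valued internally; rounding to integers happens only on export.
    """

    ids: np.ndarray
    names: np.ndarray
    latitude: np.ndarray
    longitude: np.ndarray
    land_area: np.ndarray
    populations: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.names = np.asarray(self.names)
        self.latitude = np.asarray(self.latitude, dtype=float)
        self.longitude = np.asarray(self.longitude, dtype=float)
        self.land_area = np.asarray(self.land_area, dtype=float)
        self.populations = {int(y): np.asarray(p, dtype=float) for y, p in self.populations.items()}
        self.validate()

    def validate(self) -> None:
        n = len(self.ids)
        if len(np.unique(self.ids)) != n:
            ids, counts = np.unique(self.ids, return_counts=True)
            dup = ids[counts > 1]
            raise ValidationError(f"duplicate locality ids: {list(dup[:5])}")
        for arr, what in ((self.names, "names"), (self.latitude, "latitude"),
                          (self.longitude, "longitude"), (self.land_area, "land_area")):
            if len(arr) != n:
                raise ValidationError(f"{what} has length {len(arr)}, expected {n}")
        bad_lat = (self.latitude < -90) | (self.latitude > 90)
        if bad_lat.any():
            raise ValidationError(
                f"latitude out of [-90, 90] for localities {list(self.ids[bad_lat][:5])}")
        bad_lon = (self.longitude < -180) | (self.longitude > 180)
        if bad_lon.any():
            raise ValidationError(
                f"longitude out of [-180, 180] for localities {list(self.ids[bad_lon][:5])}")
        if (self.land_area <= 0).any():
            bad = self.ids[self.land_area <= 0]
            raise ValidationError(f"non-positive land area for localities {list(bad[:5])}")
        for year, pop in self.populations.items():
            if len(pop) != n:
                raise ValidationError(f"population vector for {year} has length {len(pop)}")
            if (pop < 0).any():
                raise ValidationError(f"negative population in census year {year}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def years(self) -> list[int]:
        return sorted(self.populations)

    def population(self, year: int) -> np.ndarray:
        if year not in self.populations:
            raise ValidationError(f"no census column for year {year}; have {self.years}")
        return self.populations[year]

    def with_population(self, year: int, values: np.ndarray) -> "LocalityTable":
        """Return a copy with an added/replaced census column."""
        pops = dict(self.populations)
        pops[int(year)] = np.asarray(values, dtype=float)
        return LocalityTable(self.ids, self.names, self.latitude, self.longitude,
                             self.land_area, pops)


@dataclass
class DistanceMatrix:
    """Symmetric great-circle distance matrix (km) with a zero diagonal."""

    ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.values.shape} != ({n}, {n})")


@dataclass
class InterveningMass:
    """Origin x destination matrix of mass strictly closer to the origin.

    ``values[i, j]`` is the total mass of localities k (k != i, j) with
    d_ik < d_ij — strict inequality, so ties on the circle boundary are
    excluded and the nearest destination of every origin sees zero mass.
    """

    ids: np.ndarray
    values: np.ndarray


@dataclass
class FlowEstimate:
    """Origin x destination expected migrant counts with zero diagonal."""

    ids: np.ndarray
    values: np.ndarray
    mass_type: str = "population"

    def total_outflow(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def total_inflow(self) -> np.ndarray:
        return self.values.sum(axis=0)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def haversine_matrix(localities: LocalityTable) -> DistanceMatrix:
    """Pairwise haversine distances between locality centroids.

    Spherical Earth with radius 6371.0 km; no ellipsoid correction.
    """
    lat = np.radians(localities.latitude)
    lon = np.radians(localities.longitude)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(localities.ids, d)


def intervening_mass(mass: np.ndarray, distances: DistanceMatrix) -> InterveningMass:
    """Total mass strictly inside the circle centred at each origin.

    ``s_ij = sum_{k != i,j : d_ik < d_ij} mass_k``. The boundary is open:
    localities exactly at distance ``d_ij`` are excluded, which preserves the
    telescoping row-sum identity of the flow equation and gives ``s = 0`` for
    every origin's nearest destination when distances are distinct.
    """
    mass = np.asarray(mass, dtype=float)
    if (mass < 0).any():
        raise ValidationError("intervening_mass: negative mass values")
    d = distances.values
    n = len(mass)
    if len(mass) != d.shape[0]:
        raise ValidationError(f"mass length {len(mass)} != distance matrix size {d.shape[0]}")
    s = np.empty((n, n))
    for i in range(n):
        order = np.argsort(d[i], kind="stable")
        sd = d[i][order]
        # W[t] = total mass at distance strictly below threshold t (incl. origin)
        csum = np.concatenate(([0.0], np.cumsum(mass[order])))
        pos = np.searchsorted(sd, d[i], side="left")
        w = csum[pos]
        # the origin itself sits at distance 0 and is inside every circle of
        # positive radius; subtract it back out
        s[i] = w - np.where(d[i] > 0, mass[i], 0.0)
    np.fill_diagonal(s, 0.0)
    return InterveningMass(distances.ids, s)


def radiation_flows(
    total_migrants: np.ndarray,
    mass: np.ndarray,
    intervening: InterveningMass,
    mass_type: str = "population",
) -> FlowEstimate:
    """Expected origin->destination flows under the radiation formula.

    ``total_migrants`` is T_i, the number of out-migrants of each origin over
    the model timestep. ``mass`` is population for the classic model or the
    urbanization index for the generalized one (non-positive indices must be
    floored before calling; see :func:`floor_mass`).
    """
    t = np.asarray(total_migrants, dtype=float)
    m = np.asarray(mass, dtype=float)
    if (t < 0).any():
        raise ValidationError("radiation_flows: negative total migrants")
    if not (m > 0).any():
        raise ValidationError("radiation_flows: all-zero mass vector")
    s = intervening.values
    a = m[:, None] + s
    b = a + m[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = (m[:, None] * m[None, :]) / (a * b)
    np.fill_diagonal(kernel, 0.0)
    flows = np.nan_to_num(t[:, None] * kernel, nan=0.0, posinf=0.0, neginf=0.0)
    np.fill_diagonal(flows, 0.0)
    return FlowEstimate(intervening.ids, flows, mass_type=mass_type)


def floor_mass(mass: np.ndarray, floor: float = MASS_FLOOR) -> np.ndarray:
    """Clamp non-positive masses to a tiny positive floor.

    Trained feature weights may drive some urbanization indices to zero or
    below, but the flow equation needs positive masses. A warning reports how
    many localities were floored.
    """
    mass = np.asarray(mass, dtype=float)
    n_floored = int((mass < floor).sum())
    if n_floored:
        logger.warning("floored %d non-positive masses to %g", n_floored, floor)
        warnings.warn(f"floored {n_floored} non-positive masses to {floor}",
                      RuntimeWarning, stacklevel=2)
    return np.maximum(mass, floor)


def baseline_forecast(populations: np.ndarray, national_growth_rate: float, years: int) -> np.ndarray:
    """National-scaling baseline: every locality grows at the national rate.

    Implies uniform birth, death and migration rates across localities.
    """
    if national_growth_rate <= -1:
        raise ValidationError("growth rate must exceed -1")
    return np.asarray(populations, dtype=float) * (1.0 + national_growth_rate) ** years
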