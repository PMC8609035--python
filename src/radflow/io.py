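"""CSV/JSON readers and writers plus run configuration.

All tabular artifacts are plain CSV (RFC-4180, '.' decimal separator) and all
configuration/parameters are JSON, so every output diffs cleanly and can be
consumed outside Python. Populations and amenity counts are real-valued
in memory and rounded only here, on export, when ``round_counts`` is set.

Locality CSV schema:
    id,name,latitude,longitude,land_area_km2,pop_<year>[,pop_<year>...]
Feature CSV schema:
    locality_id,<feature>[,<feature>...]
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import GRMParameters, SGDConfig
from .features import FeatureTable, NormalizedFeatureTable
from .forecasting import ForecastTrajectory
from .radiation import FlowEstimate, LocalityTable, ValidationError

_POP_COL = re.compile(r"^pop_(\d{4})$")
LOCALITY_COLUMNS = ("id", "name", "latitude", "longitude", "land_area_km2")


def read_locality_csv(path: str | Path) -> LocalityTable:
    """Parse and validate a locality table; census years come from pop_<year> columns."""
    df = pd.read_csv(path, dtype={"id": str, "name": str}, encoding="utf-8")
    missing = [c for c in LOCALITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    pop_cols = {int(m.group(1)): c for c in df.columns if (m := _POP_COL.match(c))}
    if not pop_cols:
        raise ValidationError(f"{path}: no pop_<year> census columns found")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValidationError(f"{path}: duplicate locality id {dup!r}")
    for col in ("latitude", "longitude", "land_area_km2", *pop_cols.values()):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.argmax((bad | df[col].isna()).to_numpy()))
            raise ValidationError(f"{path}: non-numeric or missing value at row {row}, column {col!r}")
    return LocalityTable(
        df["id"].to_numpy(), df["name"].to_numpy(),
        df["latitude"].to_numpy(float), df["longitude"].to_numpy(float),
        df["land_area_km2"].to_numpy(float),
        {year: df[col].to_numpy(float) for year, col in pop_cols.items()},
    )


def write_locality_csv(table: LocalityTable, path: str | Path,
                       round_counts: bool = True) -> None:
    data = {"id": table.ids, "name": table.names, "latitude": table.latitude,
            "longitude": table.longitude, "land_area_km2": table.land_area}
    for year in table.years:
        pop = table.populations[year]
        data[f"pop_{year}"] = np.round(pop).astype(np.int64) if round_counts else pop
    pd.DataFrame(data).to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, dtype={"locality_id": str}, encoding="utf-8")
    if "locality_id" not in df.columns:
        raise ValidationError(f"{path}: missing locality_id column")
    names = [c for c in df.columns if c != "locality_id"]
    return FeatureTable(df["locality_id"].to_numpy(), names, df[names].to_numpy(float))


def write_feature_csv(table: FeatureTable, path: str | Path) -> None:
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df.insert(0, "locality_id", table.locality_ids)
    df.to_csv(path, index=False)


def write_normalized_csv(norm: NormalizedFeatureTable, path: str | Path) -> None:
    """Normalized values as CSV plus a one-line JSON sidecar of frozen stats."""
    write_feature_csv(FeatureTable(norm.locality_ids, norm.feature_names, norm.values), path)
    sidecar = Path(path).with_suffix(".stats.json")
    sidecar.write_text(json.dumps({"method": norm.method, "stats": norm.stats},
                                  sort_keys=True) + "\n", encoding="utf-8")


def read_normalized_csv(path: str | Path) -> NormalizedFeatureTable:
    table = read_feature_csv(path)
    sidecar = json.loads(Path(path).with_suffix(".stats.json").read_text(encoding="utf-8"))
    return NormalizedFeatureTable(table.locality_ids, table.feature_names, table.values,
                                  sidecar["method"], sidecar["stats"])


def write_flows_csv(flows: FlowEstimate, path: str | Path) -> None:
    """Long-form origin_id,destination_id,flow with the zero diagonal dropped."""
    n = len(flows.ids)
    origin = np.repeat(flows.ids, n)
    dest = np.tile(flows.ids, n)
    vals = flows.values.ravel()
    keep = origin != dest
    pd.DataFrame({"origin_id": origin[keep], "destination_id": dest[keep],
                  "flow": vals[keep]}).to_csv(path, index=False)


def write_trajectory_csv(traj: ForecastTrajectory, path: str | Path,
                         round_counts: bool = True) -> None:
    rows = []
    for year in traj.years:
        pop = traj.populations[year]
        rows.append(pd.DataFrame({
            "year": year, "locality_id": traj.ids,
            "population": np.round(pop).astype(np.int64) if round_counts else pop}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> ForecastTrajectory:
    df = pd.read_csv(path, dtype={"locality_id": str})
    years = sorted(df["year"].unique())
    ids = df.loc[df["year"] == years[0], "locality_id"].to_numpy()
    pops = {}
    for y in years:
        sub = df[df["year"] == y].set_index("locality_id").loc[ids]
        pops[int(y)] = sub["population"].to_numpy(float)
    return ForecastTrajectory(ids, pops)


def write_params_json(params: GRMParameters, path: str | Path,
                      extra: dict | None = None) -> None:
    d = json.loads(params.to_json())
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_params_json(path: str | Path) -> GRMParameters:
    return GRMParameters.from_json(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

FEATURE_SETS = ("population", "pop_density", "amenities", "poi_count",
                "pop_density_amenities", "pop_amenities", "all")


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run (JSON round-trippable)."""

    feature_set: str = "all"
    normalization: str = "logistic_z"
    seed: int = 0
    sgd: dict = dataclasses.field(default_factory=dict)
    scenario: dict = dataclasses.field(default_factory=dict)
    locality_csv: str | None = None
    feature_csv: str | None = None
    birth_rate: float = 0.0225
    death_rate: float = 0.0055
    n_realizations: int = 10
    horizon_years: int = 3
    output_dir: str = "."

    def sgd_config(self, seed: int | None = None) -> SGDConfig:
        kwargs = dict(self.sgd)
        kwargs.setdefault("seed", self.seed if seed is None else seed)
        return SGDConfig(**kwargs)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        d = json.loads(text)
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode("utf-8")).hexdigest()[:16]


def resolve_feature_set(name: str, table: FeatureTable) -> FeatureTable:
    """Materialize a named feature set from a full feature table.

    ``poi_count`` sums all amenity columns into a single feature; the other
    names select columns. An explicit comma-separated list is also accepted.
    """
    amenity = [n for n in table.feature_names
               if n not in ("population", "population_density")]
    if name == "population":
        return table.select(["population"])
    if name == "pop_density":
        return table.select(["population_density"])
    if name == "amenities":
        return table.select(amenity)
    if name == "poi_count":
        total = np.sum([table.column(a) for a in amenity], axis=0)
        return FeatureTable(table.locality_ids, ["poi_count"], total[:, None])
    if name == "pop_density_amenities":
        return table.select(["population_density", *amenity])
    if name == "pop_amenities":
        return table.select(["population", *amenity])
    if name == "all":
        return table
    if "," in name:
        return table.select([s.strip() for s in name.split(",")])
    raise ValidationError(f"unknown feature set {name!r}; choose from {FEATURE_SETS} "
                          "or give a comma-separated column list")
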