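"""Locality feature tables, normalization and the urbanization index.

The urbanization index of locality *i* is the weighted sum

    U_i = sum_k w_k f_ik

over normalized locality features (population, population density in
persons/km^2 and per-type amenity counts). Because raw features live on wildly
different scales, each feature is normalized independently by one of four
methods before entering the index:

``minmax``
    log1p then affine rescale of the feature to [0, 1].
``adjusted_z``
    log1p, z-score, shift right by one standard deviation, clip at zero.
``logistic_z``
    z-score passed through the standard logistic, giving values in (0, 1).
``percentile``
    relative rank of the locality, ties averaged, scaled to [0, 1].

Normalization statistics are frozen when first computed and can be re-applied
to new feature tables (projected amenity counts during forecasting), so the
trained weights always act on the calibration scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.cluster import AgglomerativeClustering

from .radiation import ValidationError

logger = logging.getLogger("radflow")

NORMALIZATION_METHODS = ("minmax", "adjusted_z", "logistic_z", "percentile", "none")

#: features that describe population rather than amenities; they pass through
#: feature reduction untouched
POPULATION_FEATURES = ("population", "population_density")


@dataclass
class FeatureTable:
    """Locality x feature matrix of non-negative raw values."""

    locality_ids: np.ndarray
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.locality_ids = np.asarray(self.locality_ids)
        self.feature_names = list(self.feature_names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.locality_ids), len(self.feature_names)):
            raise ValidationError(
                f"feature matrix shape {self.values.shape} != "
                f"({len(self.locality_ids)}, {len(self.feature_names)})")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("duplicate feature names")
        if not np.isfinite(self.values).all():
            raise ValidationError("feature table contains NaN/inf")
        if (self.values < 0).any():
            raise ValidationError("feature table contains negative values")

    def column(self, name: str) -> np.ndarray:
        try:
            return self.values[:, self.feature_names.index(name)]
        except ValueError:
            raise ValidationError(f"no feature named {name!r}; have {self.feature_names}") from None

    def select(self, names: list[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.locality_ids, list(names), self.values[:, idx])


@dataclass
class NormalizedFeatureTable:
    """Feature table after per-feature normalization, with frozen statistics.

    ``stats`` maps feature name -> the statistics of its normalizer, exactly
    as needed to re-apply the same transform to new raw values.
    """

    locality_ids: np.ndarray
    feature_names: list[str]
    values: np.ndarray
    method: str
    stats: dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Per-feature normalizers. Each returns (normalized values, stats dict); the
# paired _apply_* re-applies frozen stats to new raw values.
# ---------------------------------------------------------------------------


def _warn_constant(stats_kind: str) -> None:
    warnings.warn(f"constant feature under {stats_kind} normalization; "
                  "output degenerate by design", RuntimeWarning, stacklevel=3)


def normalize_minmax_log(values: np.ndarray) -> tuple[np.ndarray, dict]:
    """log1p then min-max rescale to [0, 1]; constant features map to zero."""
    x = _check_feature(values)
    xp = np.log1p(x)
    lo, hi = float(xp.min()), float(xp.max())
    stats = {"log_min": lo, "log_max": hi}
    if hi == lo:
        _warn_constant("minmax")
        return np.zeros_like(xp), stats
    return (xp - lo) / (hi - lo), stats


def _apply_minmax(stats: dict, values: np.ndarray) -> np.ndarray:
    lo, hi = stats["log_min"], stats["log_max"]
    if hi == lo:
        return np.zeros(len(values))
    return (np.log1p(np.asarray(values, dtype=float)) - lo) / (hi - lo)


def normalize_adjusted_zscore(values: np.ndarray, shift: str = "sigma") -> tuple[np.ndarray, dict]:
    """log1p, z-score translated to the right, clipped at 0.

    The translation is ``+ sigma`` of the log-transformed values by default;
    ``shift='one'`` instead adds 1 (one standard deviation of the z-score
    itself), which clips exactly the values more than one sigma below the
    mean. Population (not sample) moments are used. A zero-variance feature
    yields all zeros with a warning.
    """
    if shift not in ("sigma", "one"):
        raise ValidationError(f"unknown shift {shift!r}; use 'sigma' or 'one'")
    x = _check_feature(values, min_size=1)
    xp = np.log1p(x)
    mean, sd = float(xp.mean()), float(xp.std())
    stats = {"log_mean": mean, "log_sd": sd, "shift": shift}
    if sd == 0.0:
        _warn_constant("adjusted_z")
        return np.zeros_like(xp), stats
    adj = (xp - mean) / sd + (sd if shift == "sigma" else 1.0)
    return np.maximum(adj, 0.0), stats


def _apply_adjusted_z(stats: dict, values: np.ndarray) -> np.ndarray:
    mean, sd = stats["log_mean"], stats["log_sd"]
    if sd == 0.0:
        return np.zeros(len(values))
    offset = sd if stats.get("shift", "sigma") == "sigma" else 1.0
    adj = (np.log1p(np.asarray(values, dtype=float)) - mean) / sd + offset
    return np.maximum(adj, 0.0)


def normalize_logistic_zscore(values: np.ndarray, on_log: bool = True) -> tuple[np.ndarray, dict]:
    """Standard logistic of the z-score, giving values in (0, 1).

    By default the z-score is taken on log1p-transformed values, consistent
    with the other magnitude-based normalizers and the heavy right tails of
    amenity counts; ``on_log=False`` computes it on the raw scale. A
    zero-variance feature yields all 0.5 with a warning.
    """
    x = _check_feature(values)
    t = np.log1p(x) if on_log else x
    mean, sd = float(t.mean()), float(t.std())
    stats = {"mean": mean, "sd": sd, "on_log": bool(on_log)}
    if sd == 0.0:
        _warn_constant("logistic_z")
        return np.full_like(t, 0.5), stats
    return expit((t - mean) / sd), stats


def _apply_logistic_z(stats: dict, values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    t = np.log1p(x) if stats["on_log"] else x
    if stats["sd"] == 0.0:
        return np.full(len(x), 0.5)
    return expit((t - stats["mean"]) / stats["sd"])


def normalize_percentile(values: np.ndarray) -> tuple[np.ndarray, dict]:
    """Relative rank (ties averaged) scaled to [0, 1]: (r - 1)/(n - 1)."""
    x = _check_feature(values)
    r = rankdata(x, method="average")
    n = len(x)
    stats = {"sorted_values": np.sort(x).tolist()}
    return (r - 1.0) / (n - 1.0), stats


def _apply_percentile(stats: dict, values: np.ndarray) -> np.ndarray:
    ref = np.asarray(stats["sorted_values"], dtype=float)
    x = np.asarray(values, dtype=float)
    n = len(ref)
    below = np.searchsorted(ref, x, side="left")
    upto = np.searchsorted(ref, x, side="right")
    # average rank of x among the frozen calibration sample
    r = below + (upto - below + 1) / 2.0
    return (r - 1.0) / (n - 1.0)


def _check_feature(values: np.ndarray, min_size: int = 2) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValidationError("normalizers take one feature column at a time")
    if len(x) < min_size:
        raise ValidationError(f"need at least {min_size} localities, got {len(x)}")
    if (x < 0).any():
        raise ValidationError("negative feature values")
    return x


_NORMALIZERS = {
    "minmax": (normalize_minmax_log, _apply_minmax),
    "adjusted_z": (normalize_adjusted_zscore, _apply_adjusted_z),
    "logistic_z": (normalize_logistic_zscore, _apply_logistic_z),
    "percentile": (normalize_percentile, _apply_percentile),
}


def normalize_table(table: FeatureTable, method: str, **kwargs) -> NormalizedFeatureTable:
    """Normalize every feature column with the chosen method.

    ``method='none'`` passes raw values through unchanged (used by the classic
    radiation-model configuration where the mass is raw population).
    """
    if method == "none":
        return NormalizedFeatureTable(table.locality_ids, list(table.feature_names),
                                      table.values.copy(), "none",
                                      {name: {} for name in table.feature_names})
    if method not in _NORMALIZERS:
        raise ValidationError(f"unknown normalization method {method!r}; "
                              f"choose from {NORMALIZATION_METHODS}")
    fit, _ = _NORMALIZERS[method]
    out = np.empty_like(table.values)
    stats: dict[str, dict] = {}
    for k, name in enumerate(table.feature_names):
        out[:, k], stats[name] = fit(table.values[:, k], **kwargs)
    return NormalizedFeatureTable(table.locality_ids, list(table.feature_names),
                                  out, method, stats)


def apply_normalization(norm: NormalizedFeatureTable, table: FeatureTable) -> NormalizedFeatureTable:
    """Re-apply frozen normalization statistics to a new raw feature table."""
    if list(table.feature_names) != list(norm.feature_names):
        raise ValidationError(
            f"feature mismatch: stats for {norm.feature_names}, table has {table.feature_names}")
    if norm.method == "none":
        return NormalizedFeatureTable(table.locality_ids, list(table.feature_names),
                                      table.values.copy(), "none", dict(norm.stats))
    _, apply = _NORMALIZERS[norm.method]
    out = np.empty_like(table.values)
    for k, name in enumerate(table.feature_names):
        out[:, k] = apply(norm.stats[name], table.values[:, k])
    return NormalizedFeatureTable(table.locality_ids, list(table.feature_names),
                                  out, norm.method, dict(norm.stats))


def urbanization_index(normalized: NormalizedFeatureTable, weights) -> np.ndarray:
    """U_i = sum_k w_k f_ik over the normalized features.

    ``weights`` may be a mapping feature name -> weight or a vector aligned
    with ``normalized.feature_names``.
    """
    if isinstance(weights, dict):
        missing = [n for n in normalized.feature_names if n not in weights]
        if missing:
            raise ValidationError(f"missing weights for features: {missing}")
        w = np.array([weights[n] for n in normalized.feature_names], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(normalized.feature_names),):
            raise ValidationError(
                f"weight vector length {w.shape} does not match "
                f"{len(normalized.feature_names)} features {normalized.feature_names}")
    return normalized.values @ w


# ---------------------------------------------------------------------------
# Feature grouping / reduction
# ---------------------------------------------------------------------------


@dataclass
class FeatureGrouping:
    """Assignment of amenity features to groups, with optional representatives."""

    mode: str
    groups: dict[str, str]  # feature name -> group label
    representatives: dict[str, str] = field(default_factory=dict)  # group -> feature

    def __post_init__(self) -> None:
        for g, rep in self.representatives.items():
            if self.groups.get(rep) != g:
                raise ValidationError(f"representative {rep!r} is not a member of group {g!r}")

    def group_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for feat, g in self.groups.items():
            out.setdefault(g, []).append(feat)
        return out


def ward_group_features(table: FeatureTable, n_groups: int,
                        exclude: tuple[str, ...] = POPULATION_FEATURES) -> FeatureGrouping:
    """Cluster amenity features by Ward's agglomerative method.

    Each feature is a vector of locality values, standardized to zero mean and
    unit variance; Ward linkage on Euclidean distances between those vectors
    groups features with similar spatial profiles. Population-type features
    are excluded from the clustering.
    """
    if n_groups < 1:
        raise ValidationError("n_groups must be >= 1")
    names = [n for n in table.feature_names if n not in exclude]
    if n_groups > len(names):
        raise ValidationError(f"n_groups={n_groups} exceeds {len(names)} groupable features")
    cols = np.stack([table.column(n) for n in names])  # feature x locality
    sd = cols.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (cols - cols.mean(axis=1, keepdims=True)) / sd
    if n_groups == len(names):
        labels = np.arange(len(names))
    else:
        labels = AgglomerativeClustering(n_clusters=n_groups, linkage="ward").fit_predict(z)
    groups = {name: f"group_{lab}" for name, lab in zip(names, labels)}
    # representative = member with the largest variance of log1p values
    reps: dict[str, str] = {}
    for g, members in FeatureGrouping("filtered", groups).group_members().items():
        variances = [np.log1p(table.column(m)).var() for m in members]
        reps[g] = members[int(np.argmax(variances))]
    return FeatureGrouping("clustered", groups, reps)


def reduce_features(table: FeatureTable, grouping: FeatureGrouping, mode: str) -> FeatureTable:
    """Reduce amenity features by group.

    ``primary`` and ``merged`` sum the member counts of each group into one
    column; ``filtered`` keeps only the representative feature of each group.
    Population-type features pass through untouched.
    """
    if mode not in ("primary", "merged", "filtered"):
        raise ValidationError(f"unknown reduction mode {mode!r}")
    amenity_names = [n for n in table.feature_names if n not in POPULATION_FEATURES]
    uncovered = [n for n in amenity_names if n not in grouping.groups]
    if uncovered:
        raise ValidationError(f"grouping does not cover amenity features: {uncovered}")
    passthrough = [n for n in table.feature_names if n in POPULATION_FEATURES]
    names: list[str] = list(passthrough)
    cols: list[np.ndarray] = [table.column(n) for n in passthrough]
    members = grouping.group_members()
    for g in sorted(members):
        if mode == "filtered":
            rep = grouping.representatives.get(g)
            if rep is None:
                raise ValidationError(f"no representative for group {g!r} in filtered mode")
            names.append(rep)
            cols.append(table.column(rep))
        else:
            names.append(g)
            cols.append(np.sum([table.column(m) for m in members[g]], axis=0))
    return FeatureTable(table.locality_ids, names, np.column_stack(cols))


def build_feature_table(localities, year: int, amenity_counts: FeatureTable | None = None) -> FeatureTable:
    """Assemble population, density and (optionally) amenity columns."""
    pop = localities.population(year)
    names = ["population", "population_density"]
    cols = [pop, pop / localities.land_area]
    if amenity_counts is not None:
        if not np.array_equal(amenity_counts.locality_ids, localities.ids):
            raise ValidationError("amenity table locality ids do not match locality table")
        names += list(amenity_counts.feature_names)
        cols += [amenity_counts.values[:, k] for k in range(len(amenity_counts.feature_names))]
    return FeatureTable(localities.ids, names, np.column_stack(cols))
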