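"""Forecast scoring, model comparison across realizations, feature importance.

The ranking metric is the mean absolute percentage error (MAPE) of forecast
locality populations against the census, chosen over MSE because locality
sizes are fat-tailed. Model configurations are compared over independent
training realizations with one-way ANOVA plus pairwise Welch t-tests (no
multiplicity correction), and fitted weight vectors are summarised as signed
relative weights ``w_k / sum_j |w_j|``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calibration import GRMParameters
from .radiation import ValidationError


def mape(forecast: np.ndarray, actual: np.ndarray) -> float:
    """Mean absolute percentage error, in percent."""
    f = np.asarray(forecast, dtype=float)
    a = np.asarray(actual, dtype=float)
    if f.shape != a.shape:
        raise ValidationError(f"shape mismatch: forecast {f.shape} vs actual {a.shape}")
    if (a <= 0).any():
        raise ValidationError("MAPE undefined: actual populations must be positive")
    return float(np.mean(np.abs(f - a) / a) * 100.0)


def relative_improvement(mape_reference: float, mape_model: float) -> float:
    """(reference - model) / reference, in percent; negative when worse."""
    if mape_reference <= 0:
        raise ValidationError("reference MAPE must be positive")
    return (mape_reference - mape_model) / mape_reference * 100.0


@dataclass
class ModelComparison:
    model_names: list[str]
    mape_samples: dict[str, list[float]]
    anova_f: float
    anova_p: float
    pairwise_t: dict[tuple[str, str], tuple[float, float]]
    reference: str | None = None
    relative_improvements: dict[str, float] = field(default_factory=dict)

    def mean_mape(self) -> dict[str, float]:
        return {m: float(np.mean(v)) for m, v in self.mape_samples.items()}

    def report(self) -> str:
        lines = ["model comparison (MAPE %, mean +/- sd over realizations)"]
        for m in self.model_names:
            v = np.asarray(self.mape_samples[m])
            line = f"  {m}: {v.mean():.4f} +/- {v.std():.4f} (n={len(v)})"
            if m in self.relative_improvements:
                line += f"  [{self.relative_improvements[m]:+.2f}% vs {self.reference}]"
            lines.append(line)
        lines.append(f"  one-way ANOVA: F={self.anova_f:.4f}, p={self.anova_p:.4g}")
        for (a, b), (t, p) in self.pairwise_t.items():
            lines.append(f"  Welch t-test {a} vs {b}: t={t:.3f}, p={p:.4g}")
        return "\n".join(lines)


def compare_models(mape_samples: dict[str, list[float]],
                   reference: str | None = None) -> ModelComparison:
    """One-way ANOVA across models plus pairwise Welch t-tests.

    ``reference`` names the model against which relative improvements are
    reported (commonly the classic radiation model).
    """
    names = list(mape_samples)
    if len(names) < 2:
        raise ValidationError("need at least 2 models to compare")
    groups = [np.asarray(mape_samples[m], dtype=float) for m in names]
    for m, g in zip(names, groups):
        if len(g) < 2:
            raise ValidationError(f"model {m!r} has fewer than 2 realizations")
        if (g < 0).any():
            raise ValidationError(f"negative MAPE for model {m!r}")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        f_stat, p_val = 0.0, 1.0  # identical groups: no between-group variance
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.f_oneway(*groups)
        f_stat, p_val = float(res.statistic), float(res.pvalue)
    pairwise = {}
    for (ma, ga), (mb, gb) in itertools.combinations(zip(names, groups), 2):
        t = stats.ttest_ind(ga, gb, equal_var=False)
        pairwise[(ma, mb)] = (float(t.statistic), float(t.pvalue))
    rel = {}
    if reference is not None:
        if reference not in mape_samples:
            raise ValidationError(f"reference model {reference!r} not among {names}")
        ref_mean = float(np.mean(mape_samples[reference]))
        rel = {m: relative_improvement(ref_mean, float(np.mean(mape_samples[m])))
               for m in names}
    return ModelComparison(names, {m: list(map(float, mape_samples[m])) for m in names},
                           f_stat, p_val, pairwise, reference, rel)


@dataclass
class FeatureImportance:
    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    per_realization: np.ndarray  # realization x feature signed relative weights

    def ranking(self) -> list[str]:
        """Features ordered by decreasing mean relative weight."""
        order = np.argsort(-self.mean)
        return [self.feature_names[i] for i in order]


def feature_importance(fitted: list[GRMParameters]) -> FeatureImportance:
    """Signed relative weights ``w_k / sum_j |w_j|`` across realizations.

    Realizations with an all-zero weight vector are skipped with a warning;
    the absolute relative weights of each retained realization sum to one.
    """
    if not fitted:
        raise ValidationError("no fitted parameter sets")
    names = list(fitted[0].feature_names)
    rows = []
    for i, params in enumerate(fitted):
        if list(params.feature_names) != names:
            raise ValidationError(f"realization {i} has a different feature set")
        total = np.abs(params.weights).sum()
        if total == 0:
            warnings.warn(f"realization {i}: all-zero weight vector skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        rows.append(params.weights / total)
    if not rows:
        raise ValidationError("every realization had an all-zero weight vector")
    mat = np.asarray(rows)
    return FeatureImportance(names, mat.mean(axis=0), mat.std(axis=0), mat)
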