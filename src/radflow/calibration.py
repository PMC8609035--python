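"""Calibration of the generalized radiation model by gradient descent.

Trainable parameters are the feature weights ``w_k`` of the urbanization
index and the per-locality migrant fractions ``alpha_i`` (the out-migrant
total of locality i over a census timestep is ``T_i = alpha_i * p_i``).
``alpha`` is kept strictly inside (0, 1) by storing unconstrained
pre-activations mapped through the standard logistic; the weights are free
reals. The objective is the mean squared error between the observed
inter-census population change ``dp_i`` and the model's

    dp_hat_i = g * p_i + sum_r <T_ri> - sum_r <T_ir>,

where ``g`` aggregates the birth and death rates over the timestep and the
flows follow the radiation formula with mass = urbanization index.

Gradients are exact and computed in closed form (including the path through
the intervening-mass term ``v_ij``); the per-origin distance orderings are
fixed, so one loss+gradient evaluation is O(n^2). The gradient of the tiny
positive floor applied to non-positive indices is treated as zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit, logit

from .features import NormalizedFeatureTable
from .radiation import (DistanceMatrix, FlowEstimate, LocalityTable,
                        ValidationError, MASS_FLOOR)

logger = logging.getLogger("radflow")


@dataclass
class GRMParameters:
    """Fitted model state: feature weights and migrant-fraction pre-activations.

    ``alpha_pre`` holds the unconstrained values; the migrant fractions are
    ``alpha = expit(alpha_pre)`` and therefore always strictly in (0, 1).
    A scalar ``alpha_pre`` means one shared fraction for every locality.
    """

    feature_names: list[str]
    weights: np.ndarray
    alpha_pre: np.ndarray
    normalization: str = "logistic_z"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.alpha_pre = np.asarray(self.alpha_pre, dtype=float)
        if self.weights.shape != (len(self.feature_names),):
            raise ValidationError(
                f"{len(self.weights)} weights for {len(self.feature_names)} features")
        if not np.isfinite(self.weights).all():
            raise ValidationError("non-finite weights")

    @property
    def alpha(self) -> np.ndarray:
        return expit(self.alpha_pre)

    def alpha_for(self, n: int) -> np.ndarray:
        a = self.alpha
        return np.full(n, float(a)) if a.ndim == 0 else a

    def to_json(self) -> str:
        return json.dumps({
            "feature_names": self.feature_names,
            "weights": self.weights.tolist(),
            "alpha_pre": np.asarray(self.alpha_pre).tolist(),
            "normalization": self.normalization,
            "seed": self.seed,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GRMParameters":
        d = json.loads(text)
        return cls(d["feature_names"], np.asarray(d["weights"]),
                   np.asarray(d["alpha_pre"]), d.get("normalization", "logistic_z"),
                   d.get("seed"))


@dataclass
class CalibrationData:
    """Everything needed to evaluate the calibration loss.

    The feature table must already be normalized with the statistics that will
    later be frozen for forecasting.
    """

    localities: LocalityTable
    features: NormalizedFeatureTable
    distances: DistanceMatrix
    base_year: int
    target_year: int
    birth_rate: float
    death_rate: float
    compound_rates: bool = True

    def __post_init__(self) -> None:
        if self.target_year <= self.base_year:
            raise ValidationError("target year must follow base year")
        for year in (self.base_year, self.target_year):
            if year not in self.localities.populations:
                raise ValidationError(f"census column for {year} missing")
        if self.birth_rate is None or self.death_rate is None:
            raise ValidationError("vital rates (birth, death) are required")

    @property
    def timestep(self) -> int:
        return self.target_year - self.base_year

    @property
    def growth(self) -> float:
        """Net vital-rate growth aggregated over the timestep."""
        net = self.birth_rate - self.death_rate
        if self.compound_rates:
            return (1.0 + net) ** self.timestep - 1.0
        return net * self.timestep

    @property
    def observed_delta(self) -> np.ndarray:
        return (self.localities.population(self.target_year)
                - self.localities.population(self.base_year))


@dataclass
class SGDConfig:
    """Optimization schedule for :func:`fit`.

    ``optimizer`` is ``"sgd"`` (constant learning rate, the default) or
    ``"adam"``; ``batch_size=None`` uses full-batch gradients over localities.
    """

    learning_rate: float = 1e-3
    epochs: int = 2000
    batch_size: int | None = None
    seed: int = 0
    init_weight_scale: float = 0.1
    init_alpha: float = 0.05
    optimizer: str = "sgd"
    tol: float = 0.0
    freeze_weights: bool = False
    shared_alpha: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning rate must be positive")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.optimizer not in ("sgd", "adam"):
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")


# ---------------------------------------------------------------------------
# Forward / backward engine
# ---------------------------------------------------------------------------


class _Engine:
    """Precomputed geometry for repeated loss/gradient evaluations.

    Distance orderings never change during a fit, so the per-origin sort, the
    position of every destination in that order and the tie-aware prefix
    bounds are computed once; each evaluation is then pure vectorized numpy.
    """

    def __init__(self, data: CalibrationData):
        self.data = data
        d = data.distances.values
        n = d.shape[0]
        self.n = n
        self.p = data.localities.population(data.base_year)
        self.f = data.features.values
        self.delta_obs = data.observed_delta
        self.growth = data.growth
        self.orders = np.argsort(d, axis=1, kind="stable")
        sd = np.take_along_axis(d, self.orders, axis=1)
        # first_pos[i, j]: count of localities strictly closer to i than j
        # right_pos[i, j]: count at distance <= d_ij (tie-aware, both fixed)
        self.first_pos = np.empty((n, n), dtype=np.intp)
        self.right_pos = np.empty((n, n), dtype=np.intp)
        for i in range(n):
            self.first_pos[i] = np.searchsorted(sd[i], d[i], side="left")
            self.right_pos[i] = np.searchsorted(sd[i], d[i], side="right")
        self.positive_d = d > 0

    def masses(self, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u = self.f @ w
        active = u > MASS_FLOOR
        return np.maximum(u, MASS_FLOOR), active

    def intervening(self, m: np.ndarray) -> np.ndarray:
        cums = np.concatenate([np.zeros((self.n, 1)), np.cumsum(m[self.orders], axis=1)], axis=1)
        v = np.take_along_axis(cums, self.first_pos, axis=1)
        v -= np.where(self.positive_d, m[:, None], 0.0)
        np.fill_diagonal(v, 0.0)
        return v

    def forward(self, m: np.ndarray, alpha: np.ndarray):
        v = self.intervening(m)
        a = m[:, None] + v
        b = a + m[None, :]
        kernel = (m[:, None] * m[None, :]) / (a * b)
        np.fill_diagonal(kernel, 0.0)
        tout = alpha * self.p
        flows = tout[:, None] * kernel
        delta_hat = self.growth * self.p + flows.sum(axis=0) - flows.sum(axis=1)
        return flows, kernel, a, b, v, tout, delta_hat

    def loss_and_grad(self, w: np.ndarray, alpha_pre: np.ndarray,
                      batch: np.ndarray | None = None):
        """Return (loss, grad_w, grad_alpha_pre) at the given parameters.

        ``batch`` restricts the squared residuals entering the mean to a
        subset of localities; the flow computation is always global.
        """
        m, active = self.masses(w)
        alpha_vec = expit(alpha_pre)
        if alpha_vec.ndim == 0:
            alpha_vec = np.full(self.n, float(alpha_vec))
        flows, kernel, a, b, v, tout, delta_hat = self.forward(m, alpha_vec)

        e = delta_hat - self.delta_obs
        if batch is None:
            loss = float(np.mean(e ** 2))
            r_coef = 2.0 * e / self.n
        else:
            loss = float(np.mean(e[batch] ** 2))
            mask = np.zeros(self.n)
            mask[batch] = 1.0
            r_coef = 2.0 * e * mask / len(batch)
        # dL/dT_ij: +1 into destination j, -1 out of origin i
        r = r_coef[None, :] - r_coef[:, None]
        np.fill_diagonal(r, 0.0)

        # migrant fractions
        grad_tout = (r * kernel).sum(axis=1)
        alpha_sig = expit(alpha_pre)
        if np.asarray(alpha_pre).ndim == 0:
            grad_alpha_pre = np.asarray(
                (grad_tout * self.p).sum() * alpha_sig * (1.0 - alpha_sig))
        else:
            grad_alpha_pre = grad_tout * self.p * alpha_sig * (1.0 - alpha_sig)

        # masses: direct origin / destination terms
        ab = a * b
        rt = r * tout[:, None]
        d_origin = (rt * (m[None, :] * (ab - m[:, None] * (a + b)) / ab ** 2)).sum(axis=1)
        d_dest = (rt * (m[:, None] * (b - m[None, :]) / (a * b ** 2))).sum(axis=0)
        # path through the intervening mass v_ij: c_ij = dL/dv_ij, scattered to
        # every k strictly closer to i than j (tie-aware, excluding i itself)
        c = -rt * (m[:, None] * m[None, :] * (a + b)) / ab ** 2
        np.fill_diagonal(c, 0.0)
        c_sorted = np.take_along_axis(c, self.orders, axis=1)
        cumc = np.concatenate([np.zeros((self.n, 1)), np.cumsum(c_sorted, axis=1)], axis=1)
        total_c = cumc[:, -1:]
        scatter = total_c - np.take_along_axis(cumc, self.right_pos, axis=1)
        np.fill_diagonal(scatter, 0.0)
        d_via_v = scatter.sum(axis=0)

        grad_m = d_origin + d_dest + d_via_v
        grad_w = self.f[active].T @ grad_m[active]
        return loss, grad_w, grad_alpha_pre


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def predicted_delta(params: GRMParameters, data: CalibrationData) -> np.ndarray:
    """Model population change dp_hat over the calibration timestep."""
    _check_alignment(params, data)
    eng = _Engine(data)
    m, _ = eng.masses(params.weights)
    alpha = params.alpha_for(eng.n)
    *_, delta_hat = eng.forward(m, alpha)
    return delta_hat


def model_flows(params: GRMParameters, data: CalibrationData) -> FlowEstimate:
    """Expected origin->destination flows at the given parameters."""
    _check_alignment(params, data)
    eng = _Engine(data)
    m, _ = eng.masses(params.weights)
    flows, *_ = eng.forward(m, params.alpha_for(eng.n))
    mass_type = ("population" if params.feature_names == ["population"]
                 and params.normalization == "none" else "urbanization_index")
    return FlowEstimate(data.localities.ids, flows, mass_type=mass_type)


def loss(params: GRMParameters, data: CalibrationData) -> float:
    """Mean squared error between observed and predicted population change."""
    resid = predicted_delta(params, data) - data.observed_delta
    return float(np.mean(resid ** 2))


def loss_and_gradient(params: GRMParameters, data: CalibrationData):
    """Loss plus exact gradients w.r.t. weights and alpha pre-activations."""
    _check_alignment(params, data)
    eng = _Engine(data)
    return eng.loss_and_grad(params.weights, params.alpha_pre)


def _check_alignment(params: GRMParameters, data: CalibrationData) -> None:
    if list(params.feature_names) != list(data.features.feature_names):
        raise ValidationError(
            f"parameter features {params.feature_names} do not match "
            f"data features {data.features.feature_names}")


@dataclass
class FitResult:
    params: GRMParameters
    loss_history: list[float] = field(default_factory=list)
    config: SGDConfig | None = None

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1]


def fit(data: CalibrationData, config: SGDConfig,
        init: GRMParameters | None = None) -> FitResult:
    """Fit weights and migrant fractions by gradient descent.

    Initialization: weights half-normal |N(0, init_weight_scale)| (or frozen
    at 1 when ``freeze_weights``, the classic-radiation configuration), alpha
    at ``init_alpha`` plus small seeded jitter on the pre-activation scale.
    Positive starting weights guarantee a positive urbanization index
    somewhere — a zero-mean draw can start with every index below the mass
    floor, where the weight gradient vanishes identically and training never
    escapes. Weights remain free to turn negative during training. The loss
    history holds the full-data loss once per epoch.
    """
    eng = _Engine(data)
    rng = np.random.default_rng(config.seed)
    k = len(data.features.feature_names)
    if init is not None:
        w = init.weights.copy()
        a_pre = np.asarray(init.alpha_pre, dtype=float).copy()
    else:
        w = (np.ones(k) if config.freeze_weights
             else np.abs(rng.normal(0.0, config.init_weight_scale, k)))
        base = float(logit(config.init_alpha))
        if config.shared_alpha:
            a_pre = np.asarray(base + 0.01 * rng.normal())
        else:
            a_pre = base + 0.01 * rng.normal(size=eng.n)

    mw = vw = np.zeros_like(w)
    ma = va = np.zeros_like(a_pre)
    adam_t = 0
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    history: list[float] = []
    n = eng.n

    for epoch in range(config.epochs):
        if config.batch_size is None or config.batch_size >= n:
            batches = [None]
        else:
            perm = rng.permutation(n)
            batches = [perm[i:i + config.batch_size] for i in range(0, n, config.batch_size)]
        for batch in batches:
            cur_loss, gw, ga = eng.loss_and_grad(w, a_pre, batch)
            if not np.isfinite(cur_loss):
                raise ValidationError(
                    f"non-finite loss at epoch {epoch}; reduce the learning rate")
            if config.freeze_weights:
                gw = np.zeros_like(gw)
            if config.optimizer == "adam":
                adam_t += 1
                mw = beta1 * mw + (1 - beta1) * gw
                vw = beta2 * vw + (1 - beta2) * gw ** 2
                ma = beta1 * ma + (1 - beta1) * ga
                va = beta2 * va + (1 - beta2) * ga ** 2
                corr1, corr2 = 1 - beta1 ** adam_t, 1 - beta2 ** adam_t
                w = w - config.learning_rate * (mw / corr1) / (np.sqrt(vw / corr2) + eps_adam)
                a_pre = a_pre - config.learning_rate * (ma / corr1) / (np.sqrt(va / corr2) + eps_adam)
            else:
                w = w - config.learning_rate * gw
                a_pre = a_pre - config.learning_rate * ga
        full_loss, *_ = eng.loss_and_grad(w, a_pre)
        history.append(full_loss)
        if config.tol > 0 and epoch > 0 and abs(history[-2] - full_loss) <= config.tol:
            break

    params = GRMParameters(list(data.features.feature_names), w, a_pre,
                           normalization=data.features.method, seed=config.seed)
    return FitResult(params, history, config)


def run_realizations(data: CalibrationData, config: SGDConfig,
                     n_realizations: int = 100) -> list[FitResult]:
    """Independent fits with seeds ``config.seed + 0 .. n-1``.

    Realizations differ only in their initialization stream; each result's
    parameters retain the realization seed for reproducibility.
    """
    if n_realizations < 1:
        raise ValidationError("n_realizations must be >= 1")
    results = []
    for r in range(n_realizations):
        cfg = SGDConfig(**{**asdict(config), "seed": config.seed + r})
        try:
            results.append(fit(data, cfg))
        except Exception as exc:
            raise RuntimeError(f"realization {r} (seed {cfg.seed}) failed: {exc}") from exc
    return results
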