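"""One-hidden-layer regression network trained by Levenberg-Marquardt.

Architecture: input -> tanh hidden layer (default 10 units) -> linear output,
with per-variable min-max scaling of inputs and target to [-1, 1] fitted on
the training split.  Training is damped Gauss-Newton on the full batch:

    delta_w = (J^T J + mu I)^{-1} J^T e

where J is the Jacobian of the scaled per-sample errors.  A step is accepted
only if the training MSE decreases (then mu shrinks); otherwise mu grows and
the step is retried.  Early stopping returns the weights at the best
validation epoch.  The training protocol runs many random restarts and keeps
the run with the lowest validation MSE.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# data splitting

@dataclass
class SplitAssignment:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.val_idx = np.asarray(self.val_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.train_idx), len(self.val_idx), len(self.test_idx)

    def labels(self, n: int) -> np.ndarray:
        lab = np.empty(n, dtype=object)
        lab[self.train_idx] = "train"
        lab[self.val_idx] = "val"
        lab[self.test_idx] = "test"
        return lab


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    raw = [f * n for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainder first
    for i in order[:short]:
        base[i] += 1
    return base


def make_split(n: int, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
               seed: int = 0, group_ids: np.ndarray | None = None) -> SplitAssignment:
    """Random train/val/test split with largest-remainder size allocation.

    With ``group_ids`` (e.g. patient ids) the allocation is done over groups,
    so all fractions of one patient land in the same set; sizes then realize
    the fractions over groups, not rows.
    """
    if n < 3:
        raise ValueError("need at least 3 rows to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    if group_ids is None:
        perm = rng.permutation(n)
        n_tr, n_va, n_te = _largest_remainder(n, fractions)
        parts = (perm[:n_tr], perm[n_tr:n_tr + n_va], perm[n_tr + n_va:])
    else:
        group_ids = np.asarray(group_ids)
        groups = np.unique(group_ids)
        gperm = rng.permutation(len(groups))
        g_tr, g_va, g_te = _largest_remainder(len(groups), fractions)
        sets = (groups[gperm[:g_tr]], groups[gperm[g_tr:g_tr + g_va]],
                groups[gperm[g_tr + g_va:]])
        parts = tuple(np.flatnonzero(np.isin(group_ids, s)) for s in sets)
    if any(len(p) == 0 for p in parts):
        raise ValueError("split produced an empty set; n too small for the fractions")
    return SplitAssignment(*parts)


# ---------------------------------------------------------------------------
# scaling

@dataclass
class MinMaxScaler:
    """Per-variable affine map sending the training (min, max) to (-1, +1).

    Constant variables map to 0 (with a warning); no clipping is applied
    outside the training range.
    """

    data_min: np.ndarray
    data_max: np.ndarray

    def __post_init__(self) -> None:
        self.data_min = np.atleast_1d(np.asarray(self.data_min, dtype=float))
        self.data_max = np.atleast_1d(np.asarray(self.data_max, dtype=float))

    @property
    def _span(self) -> np.ndarray:
        return self.data_max - self.data_min

    @classmethod
    def fit(cls, values: np.ndarray) -> "MinMaxScaler":
        values = np.atleast_2d(np.asarray(values, dtype=float))
        sc = cls(values.min(axis=0), values.max(axis=0))
        if np.any(sc._span == 0):
            logger.warning("constant variable(s) at indices %s map to 0 under scaling",
                           np.flatnonzero(sc._span == 0).tolist())
        return sc

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        span = self._span
        out = np.zeros_like(values, dtype=float)
        nz = span != 0
        out[..., nz] = -1.0 + 2.0 * (values[..., nz] - self.data_min[nz]) / span[nz]
        return out

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        scaled = np.asarray(scaled, dtype=float)
        return self.data_min + (scaled + 1.0) / 2.0 * self._span


def fit_scalers(train_features: np.ndarray, train_targets: np.ndarray
                ) -> tuple[MinMaxScaler, MinMaxScaler]:
    if len(np.atleast_2d(train_features)) == 0:
        raise ValueError("empty training block")
    return MinMaxScaler.fit(train_features), MinMaxScaler.fit(train_targets.reshape(-1, 1))


# ---------------------------------------------------------------------------
# model

@dataclass
class NetworkModel:
    """Weights, biases and scalers of the 3-layer (input/hidden/output) net."""

    hidden_weights: np.ndarray  # (h, d)
    hidden_bias: np.ndarray  # (h,)
    output_weights: np.ndarray  # (h,)
    output_bias: float
    input_scaler: MinMaxScaler
    target_scaler: MinMaxScaler

    def __post_init__(self) -> None:
        self.hidden_weights = np.asarray(self.hidden_weights, dtype=float)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float).ravel()
        self.output_bias = float(self.output_bias)
        h, d = self.hidden_weights.shape
        if self.hidden_bias.shape != (h,) or self.output_weights.shape != (h,):
            raise ValueError("inconsistent network dimensions")

    @property
    def hidden_size(self) -> int:
        return self.hidden_weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.hidden_weights.shape[1]

    @property
    def n_params(self) -> int:
        h, d = self.hidden_weights.shape
        return h * d + h + h + 1

    # flat parameter vector ordering: W1 (row-major), b1, W2, b2
    def get_params(self) -> np.ndarray:
        return np.concatenate([self.hidden_weights.ravel(), self.hidden_bias,
                               self.output_weights, [self.output_bias]])

    def set_params(self, theta: np.ndarray) -> None:
        h, d = self.hidden_weights.shape
        theta = np.asarray(theta, dtype=float)
        self.hidden_weights = theta[: h * d].reshape(h, d)
        self.hidden_bias = theta[h * d: h * d + h]
        self.output_weights = theta[h * d + h: h * d + 2 * h]
        self.output_bias = float(theta[-1])

    def to_dict(self) -> dict:
        return {
            "hidden_weights": self.hidden_weights.tolist(),
            "hidden_bias": self.hidden_bias.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_bias": self.output_bias,
            "input_scaler": {"min": self.input_scaler.data_min.tolist(),
                             "max": self.input_scaler.data_max.tolist()},
            "target_scaler": {"min": self.target_scaler.data_min.tolist(),
                              "max": self.target_scaler.data_max.tolist()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        return cls(
            hidden_weights=np.array(d["hidden_weights"]),
            hidden_bias=np.array(d["hidden_bias"]),
            output_weights=np.array(d["output_weights"]),
            output_bias=d["output_bias"],
            input_scaler=MinMaxScaler(d["input_scaler"]["min"], d["input_scaler"]["max"]),
            target_scaler=MinMaxScaler(d["target_scaler"]["min"], d["target_scaler"]["max"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "NetworkModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def init_model(n_inputs: int, hidden_size: int, rng: np.random.Generator,
               input_scaler: MinMaxScaler, target_scaler: MinMaxScaler,
               output_bias0: float = 0.0) -> NetworkModel:
    """Small uniform(-0.5, 0.5) weights scaled by fan-in.

    The output bias starts at ``output_bias0`` — callers pass the scaled
    train-target mean so the initial prediction is centred and no offset
    survives validation-based early stopping.
    """
    w1 = rng.uniform(-0.5, 0.5, size=(hidden_size, n_inputs)) / np.sqrt(n_inputs)
    b1 = rng.uniform(-0.5, 0.5, size=hidden_size)
    w2 = rng.uniform(-0.5, 0.5, size=hidden_size) / np.sqrt(hidden_size)
    return NetworkModel(w1, b1, w2, output_bias0, input_scaler, target_scaler)


def _forward_scaled(model: NetworkModel, xs: np.ndarray) -> np.ndarray:
    """Scaled-space prediction for already-scaled inputs (n, d) -> (n,)."""
    a = np.tanh(xs @ model.hidden_weights.T + model.hidden_bias)
    return a @ model.output_weights + model.output_bias


def forward(model: NetworkModel, features: np.ndarray) -> np.ndarray:
    """Predict targets in original units for raw feature rows."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != model.n_inputs:
        raise ValueError(
            f"feature length {features.shape[1]} does not match model input size {model.n_inputs}"
        )
    ys = _forward_scaled(model, model.input_scaler.transform(features))
    return model.target_scaler.inverse(ys.reshape(-1, 1)).ravel()


def jacobian(model: NetworkModel, xs: np.ndarray) -> np.ndarray:
    """Jacobian of scaled predictions w.r.t. the flat parameter vector.

    Rows are samples; column ordering matches ``NetworkModel.get_params``.
    """
    xs = np.atleast_2d(xs)
    n, d = xs.shape
    h = model.hidden_size
    z = xs @ model.hidden_weights.T + model.hidden_bias  # (n, h)
    a = np.tanh(z)
    da = 1.0 - a**2
    J = np.empty((n, model.n_params))
    # d f / d W1_{jk} = W2_j * (1 - a_j^2) * x_k
    J[:, : h * d] = ((model.output_weights * da)[:, :, None] * xs[:, None, :]).reshape(n, h * d)
    J[:, h * d: h * d + h] = model.output_weights * da
    J[:, h * d + h: h * d + 2 * h] = a
    J[:, -1] = 1.0
    return J


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainingConfig:
    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    max_epochs: int = 1000
    max_val_fail: int = 6
    min_grad: float = 1e-7
    n_restarts: int = 100
    hidden_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu0 <= 0 or not (self.mu_inc > 1 > self.mu_dec > 0):
            raise ValueError("require mu0 > 0 and mu_inc > 1 > mu_dec > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1
    best_val_mse: float = np.inf

    @property
    def train_mse_per_epoch(self) -> list[float]:
        return [e["train_mse"] for e in self.epochs]


def _mse(model: NetworkModel, xs: np.ndarray, ys: np.ndarray) -> float:
    e = ys - _forward_scaled(model, xs)
    return float(np.mean(e**2))


def lm_train(model: NetworkModel, train_x: np.ndarray, train_y: np.ndarray,
             val_x: np.ndarray | None, val_y: np.ndarray | None,
             config: TrainingConfig) -> tuple[NetworkModel, TrainingHistory]:
    """Levenberg-Marquardt batch training with validation early stopping.

    Inputs are raw feature/target rows; they are scaled through the model's
    scalers internally.  Stops on max_epochs, mu exceeding mu_max, gradient
    norm below min_grad, or ``max_val_fail`` consecutive accepted epochs of
    rising validation MSE; returns the weights at the best validation epoch
    (final weights when no validation set is given).
    """
    if len(train_x) == 0:
        raise ValueError("training set is empty")
    xs = model.input_scaler.transform(np.atleast_2d(train_x))
    ys = model.target_scaler.transform(np.asarray(train_y, dtype=float).reshape(-1, 1)).ravel()
    has_val = val_x is not None and len(val_x) > 0
    if has_val:
        vxs = model.input_scaler.transform(np.atleast_2d(val_x))
        vys = model.target_scaler.transform(np.asarray(val_y, dtype=float).reshape(-1, 1)).ravel()

    hist = TrainingHistory()
    mu = config.mu0
    theta = model.get_params()
    e = ys - _forward_scaled(model, xs)
    mse = float(np.mean(e**2))
    best_theta = theta.copy()
    if has_val:
        hist.best_val_mse = float(np.mean((vys - _forward_scaled(model, vxs)) ** 2))
        hist.best_epoch = 0
    val_fail = 0

    for epoch in range(1, config.max_epochs + 1):
        J = jacobian(model, xs)
        g = J.T @ e
        gnorm = float(np.linalg.norm(2.0 * g / len(ys)))
        if gnorm < config.min_grad:
            hist.stop_reason = "min_grad"
            break
        JTJ = J.T @ J
        accepted = False
        while mu <= config.mu_max:
            try:
                delta = np.linalg.solve(JTJ + mu * np.eye(len(theta)), g)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError(
                    f"singular normal matrix at epoch {epoch}, mu={mu:g}"
                ) from exc
            model.set_params(theta + delta)
            e_new = ys - _forward_scaled(model, xs)
            mse_new = float(np.mean(e_new**2))
            if mse_new < mse:
                accepted = True
                theta = theta + delta
                e, mse = e_new, mse_new
                mu = max(mu * config.mu_dec, np.finfo(float).tiny)
                break
            mu *= config.mu_inc
        if not accepted:
            model.set_params(theta)
            hist.stop_reason = "mu_max"
            break

        rec = {"epoch": epoch, "train_mse": mse, "mu": mu, "grad_norm": gnorm}
        if has_val:
            val_mse = float(np.mean((vys - _forward_scaled(model, vxs)) ** 2))
            rec["val_mse"] = val_mse
            if val_mse < hist.best_val_mse:
                hist.best_val_mse = val_mse
                hist.best_epoch = epoch
                best_theta = theta.copy()
                val_fail = 0
            else:
                val_fail += 1
                if val_fail >= config.max_val_fail:
                    hist.epochs.append(rec)
                    hist.stop_reason = "val_fail"
                    break
        else:
            best_theta = theta.copy()
        hist.epochs.append(rec)
        logger.debug("epoch %d: train MSE %.3e, mu %.1e", epoch, mse, mu)
    else:
        hist.stop_reason = hist.stop_reason or "max_epochs"
    if not hist.stop_reason:
        hist.stop_reason = "max_epochs"

    model.set_params(best_theta if has_val else theta)
    if not has_val:
        hist.best_val_mse = mse
        hist.best_epoch = len(hist.epochs)
    # At a full least-squares optimum the output-bias gradient forces the
    # training residual mean to zero; early stopping halts before that
    # stationarity condition, leaving a small offset.  Recentre the output
    # bias on the training residuals (training data only).
    model.output_bias += float(np.mean(ys - _forward_scaled(model, xs)))
    return model, hist


def train_with_restarts(features: np.ndarray, targets: np.ndarray,
                        split: SplitAssignment, config: TrainingConfig
                        ) -> tuple[NetworkModel, "pd.DataFrame"]:
    """Best-of-n-restarts LM training, selected by validation MSE.

    Each restart draws fresh small random initial weights from a seeded
    stream; the returned summary has one row per restart with (restart seed,
    train MSE, validation MSE, accepted epochs, stop reason).
    """
    import pandas as pd

    features = np.atleast_2d(np.asarray(features, dtype=float))
    targets = np.asarray(targets, dtype=float)
    tr_x, tr_y = features[split.train_idx], targets[split.train_idx]
    va_x, va_y = features[split.val_idx], targets[split.val_idx]
    in_sc, tg_sc = fit_scalers(tr_x, tr_y)

    y0 = float(tg_sc.transform(tr_y.reshape(-1, 1)).mean())
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_restarts)
    best_model, best_val = None, np.inf
    rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        model = init_model(features.shape[1], config.hidden_size, rng, in_sc, tg_sc,
                           output_bias0=y0)
        try:
            model, hist = lm_train(model, tr_x, tr_y, va_x, va_y, config)
        except RuntimeError as exc:
            rows.append({"restart": i, "train_mse": np.nan, "val_mse": np.nan,
                         "epochs": 0, "stop_reason": f"failed: {exc}"})
            continue
        train_mse = _mse(model, model.input_scaler.transform(tr_x),
                         model.target_scaler.transform(tr_y.reshape(-1, 1)).ravel())
        rows.append({"restart": i, "train_mse": train_mse,
                     "val_mse": hist.best_val_mse, "epochs": len(hist.epochs),
                     "stop_reason": hist.stop_reason})
        if hist.best_val_mse < best_val:
            best_val = hist.best_val_mse
            best_model = model
    if best_model is None:
        raise RuntimeError("all restarts failed")
    return best_model, pd.DataFrame(rows)


def predict(model: NetworkModel, decomposition, hrctv_volume_cc: float,
            d90_gy: float | None = None):
    """Predict D2cm3/D90 from a sub-organ decomposition (+ absolute D2cm3 if
    the plan's D90 is given)."""
    from ringdose.rings import MAX_RINGS

    padded = np.zeros(MAX_RINGS)
    padded[: decomposition.n_rings] = decomposition.normalized_volumes
    feats = np.concatenate([padded, [hrctv_volume_cc]])
    ratio = float(forward(model, feats)[0])
    if d90_gy is None:
        return ratio
    return ratio, ratio * d90_gy
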