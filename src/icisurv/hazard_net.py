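"""Discrete-time logistic-hazard survival network.

The model is a single-hidden-layer perceptron mapping an encoded, scaled
feature vector to one conditional event probability (hazard) per time bin:

    x -> affine -> batch-norm -> ReLU -> dropout -> affine -> sigmoid -> h

Survival is assembled as the cumulative product S_k = prod_{j<=k} (1 - h_j),
one step per time bin.  Training minimizes the right-censored discrete-time
hazard negative log-likelihood

    L = -(1/N) sum_i [ sum_{j<k_i} log(1-h_ij)
                       + d_i log h_{i,k_i} + (1-d_i) log(1-h_{i,k_i}) ]

(equivalent to binary cross-entropy over person-period expanded targets up
to and including the label bin) by Adam with early stopping on validation
loss.  Everything is implemented in NumPy with analytic gradients; the same
machinery exposes input-space gradients in evaluation mode, which the
importance module uses for integrated gradients.

Default hyperparameters: hidden width = floor((n_features + n_bins) / 2),
dropout 0.2, learning rate 0.07, batch size 50 (capped at the training-set
size), batch normalization on, at most 512 epochs, patience 10.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import TimeGrid

__all__ = [
    "NetworkConfig",
    "LogisticHazardNet",
    "DiscreteSurvivalPrediction",
    "logistic_hazard_loss",
    "build_network",
    "train",
    "predict_survival",
    "save_checkpoint",
    "load_checkpoint",
    "random_search_hyperparameters",
]

_CLIP = 1e-7  # hazard clipping before logs, for numerical safety


@dataclass
class NetworkConfig:
    n_features: int = 31
    n_bins: int = 20
    hidden_nodes: int | None = None
    dropout: float = 0.2
    learning_rate: float = 0.07
    batch_size: int = 50
    max_epochs: int = 512
    patience: int = 10
    seed: int = 0
    batch_norm: bool = True
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.hidden_nodes is None:
            # arithmetic mean of input and output widths, rounded down
            self.hidden_nodes = (self.n_features + self.n_bins) // 2
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


def logistic_hazard_loss(hazards: np.ndarray, bins: np.ndarray, events: np.ndarray) -> float:
    """Mean right-censored discrete-hazard negative log-likelihood."""
    h = np.clip(np.asarray(hazards, float), _CLIP, 1.0 - _CLIP)
    bins = np.asarray(bins, int)
    events = np.asarray(events, int)
    n, n_bins = h.shape
    j = np.arange(n_bins)[None, :]
    mask = (j <= bins[:, None]).astype(float)
    y = np.zeros_like(h)
    y[np.arange(n), bins] = events
    ll = y * np.log(h) + (1.0 - y) * np.log(1.0 - h)
    return float(-(mask * ll).sum() / n)


class LogisticHazardNet:
    """Single-hidden-layer logistic-hazard MLP with manual backprop."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f, hdim, nb = config.n_features, config.hidden_nodes, config.n_bins
        k1 = 1.0 / np.sqrt(f)
        k2 = 1.0 / np.sqrt(hdim)
        self.params = {
            "W1": rng.uniform(-k1, k1, size=(f, hdim)),
            "b1": rng.uniform(-k1, k1, size=hdim),
            "gamma": np.ones(hdim),
            "beta": np.zeros(hdim),
            "W2": rng.uniform(-k2, k2, size=(hdim, nb)),
            "b2": rng.uniform(-k2, k2, size=nb),
        }
        self.running_mean = np.zeros(hdim)
        self.running_var = np.ones(hdim)
        self._bn_momentum = 0.1
        self._bn_eps = 1e-5
        self._rng = rng  # dropout / shuffling stream
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------- forward --

    def forward(self, X: np.ndarray, training: bool = False):
        """Hazards plus the cache needed for backprop."""
        p = self.params
        u = X @ p["W1"] + p["b1"]
        if self.config.batch_norm:
            if training:
                m = u.mean(axis=0)
                v = u.var(axis=0)
                self.running_mean = (1 - self._bn_momentum) * self.running_mean + self._bn_momentum * m
                self.running_var = (1 - self._bn_momentum) * self.running_var + self._bn_momentum * v
            else:
                m, v = self.running_mean, self.running_var
            invstd = 1.0 / np.sqrt(v + self._bn_eps)
            xhat = (u - m) * invstd
            a = p["gamma"] * xhat + p["beta"]
        else:
            invstd = xhat = None
            a = u
        r = np.maximum(a, 0.0)
        if training and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            dmask = (self._rng.random(r.shape) < keep) / keep
            r = r * dmask
        else:
            dmask = None
        z = r @ p["W2"] + p["b2"]
        h = 1.0 / (1.0 + np.exp(-z))
        cache = {"X": X, "u": u, "xhat": xhat, "invstd": invstd, "a": a, "r": r,
                 "dmask": dmask, "z": z, "h": h, "training": training}
        return h, cache

    def predict_hazards(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.config.n_features:
            raise ValueError(
                f"feature count mismatch: model expects {self.config.n_features}, got {X.shape[1]}"
            )
        h, _ = self.forward(X, training=False)
        return h

    # ------------------------------------------------------------ backward --

    def _grads(self, cache, bins: np.ndarray, events: np.ndarray):
        p = self.params
        h = cache["h"]
        n, n_bins = h.shape
        j = np.arange(n_bins)[None, :]
        mask = (j <= bins[:, None]).astype(float)
        y = np.zeros_like(h)
        y[np.arange(n), bins] = events
        dz = mask * (h - y) / n
        grads = {
            "W2": cache["r"].T @ dz,
            "b2": dz.sum(axis=0),
        }
        dr = dz @ p["W2"].T
        if cache["dmask"] is not None:
            dr = dr * cache["dmask"]
        da = dr * (cache["a"] > 0)
        if self.config.batch_norm:
            xhat, invstd = cache["xhat"], cache["invstd"]
            grads["gamma"] = (da * xhat).sum(axis=0)
            grads["beta"] = da.sum(axis=0)
            dxhat = da * p["gamma"]
            du = (invstd / n) * (
                n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
            )
        else:
            grads["gamma"] = np.zeros_like(p["gamma"])
            grads["beta"] = np.zeros_like(p["beta"])
            du = da
        grads["W1"] = cache["X"].T @ du
        grads["b1"] = du.sum(axis=0)
        return grads

    def _adam_step(self, grads) -> None:
        c = self.config
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = c.adam_beta1 * self._adam_m[k] + (1 - c.adam_beta1) * g
            self._adam_v[k] = c.adam_beta2 * self._adam_v[k] + (1 - c.adam_beta2) * g * g
            mhat = self._adam_m[k] / (1 - c.adam_beta1 ** t)
            vhat = self._adam_v[k] / (1 - c.adam_beta2 ** t)
            self.params[k] = self.params[k] - c.learning_rate * mhat / (np.sqrt(vhat) + c.adam_eps)

    # --------------------------------------------------------- input grads --

    def logits_eval(self, X: np.ndarray) -> np.ndarray:
        """Pre-sigmoid per-bin logits in evaluation mode."""
        p = self.params
        u = X @ p["W1"] + p["b1"]
        if self.config.batch_norm:
            invstd = 1.0 / np.sqrt(self.running_var + self._bn_eps)
            a = p["gamma"] * (u - self.running_mean) * invstd + p["beta"]
        else:
            a = u
        r = np.maximum(a, 0.0)
        return r @ p["W2"] + p["b2"]

    def input_jacobian_eval(self, X: np.ndarray) -> np.ndarray:
        """d logit_j / d x_f per sample, shape (n, n_bins, n_features).

        In evaluation mode (dropout off, batch-norm frozen on running
        statistics) the network is piecewise linear, so the Jacobian is
        exact: W2^T . diag(relu') . diag(gamma*invstd) . W1^T.
        """
        p = self.params
        u = X @ p["W1"] + p["b1"]
        if self.config.batch_norm:
            invstd = 1.0 / np.sqrt(self.running_var + self._bn_eps)
            scale = p["gamma"] * invstd
            a = scale * (u - self.running_mean) + p["beta"]
        else:
            scale = np.ones(u.shape[1])
            a = u
        act = (a > 0).astype(float) * scale  # (n, hidden)
        # J[n, j, f] = sum_h W2[h, j] * act[n, h] * W1[f, h]
        return np.einsum("hj,nh,fh->njf", p["W2"], act, p["W1"], optimize=True)

    # ------------------------------------------------------------- state ----

    def state_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "params": {k: v.tolist() for k, v in self.params.items()},
            "running_mean": self.running_mean.tolist(),
            "running_var": self.running_var.tolist(),
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "LogisticHazardNet":
        model = cls(NetworkConfig(**state["config"]))
        model.params = {k: np.array(v, dtype=float) for k, v in state["params"].items()}
        model.running_mean = np.array(state["running_mean"], dtype=float)
        model.running_var = np.array(state["running_var"], dtype=float)
        return model


def build_network(config: NetworkConfig) -> LogisticHazardNet:
    """Construct a seeded logistic-hazard network."""
    return LogisticHazardNet(config)


def _loss_on(model: LogisticHazardNet, X, bins, events) -> float:
    h, _ = model.forward(X, training=False)
    return logistic_hazard_loss(h, bins, events)


def train(
    model: LogisticHazardNet,
    X_train: np.ndarray,
    bins_train: np.ndarray,
    events_train: np.ndarray,
    X_val: np.ndarray,
    bins_val: np.ndarray,
    events_val: np.ndarray,
) -> dict:
    """Adam training with per-epoch validation and early stopping.

    Stops when validation loss has not improved for ``patience`` epochs or at
    ``max_epochs``; the weights (and batch-norm running statistics) from the
    best validation epoch are restored.  Returns the training log.
    """
    c = model.config
    n = X_train.shape[0]
    batch = min(c.batch_size, n)
    log: dict = {"train_loss": [], "val_loss": [], "best_epoch": -1}
    best_val = np.inf
    best_state = None
    stale = 0
    for epoch in range(c.max_epochs):
        order = model._rng.permutation(n)
        starts = list(range(0, n, batch))
        for si, s in enumerate(starts):
            idx = order[s : s + batch]
            if idx.size < 2 and si > 0:
                continue  # merge a trailing singleton into nothing; skip it
            h, cache = model.forward(X_train[idx], training=True)
            grads = model._grads(cache, bins_train[idx], events_train[idx])
            model._adam_step(grads)
        tr = _loss_on(model, X_train, bins_train, events_train)
        vl = _loss_on(model, X_val, bins_val, events_val)
        if not (np.isfinite(tr) and np.isfinite(vl)):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: train loss {tr}, val loss {vl}"
            )
        log["train_loss"].append(tr)
        log["val_loss"].append(vl)
        if vl < best_val - 1e-12:
            best_val = vl
            best_state = copy.deepcopy(
                (model.params, model.running_mean, model.running_var)
            )
            log["best_epoch"] = epoch
            stale = 0
        else:
            stale += 1
            if stale > c.patience:
                break
    if best_state is not None:
        model.params, model.running_mean, model.running_var = copy.deepcopy(best_state)
    log["best_val_loss"] = best_val
    return log


@dataclass
class DiscreteSurvivalPrediction:
    """Per-bin hazards and the step survival curve on a shared grid."""

    grid: TimeGrid
    hazards: np.ndarray
    survival: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.survival = np.cumprod(1.0 - self.hazards, axis=1)

    @property
    def n_patients(self) -> int:
        return self.hazards.shape[0]

    def survival_at(self, times: np.ndarray) -> np.ndarray:
        """S(t|x) evaluated as a step function, shape (n_patients, n_times).

        S(0) = 1; for t in the (left-open, right-closed] bin j the value is
        the survival through bin j; beyond the grid the last value is held.
        """
        t = np.atleast_1d(np.asarray(times, float))
        e = self.grid.edges
        k = np.searchsorted(e, t, side="left") - 1
        k = np.clip(k, -1, self.grid.n_bins - 1)
        out = np.empty((self.n_patients, t.size))
        for ci, kk in enumerate(k):
            out[:, ci] = 1.0 if kk < 0 else self.survival[:, kk]
        return out

    def to_long_frame(self, patient_ids) -> "pd.DataFrame":
        import pandas as pd

        rows = []
        times = np.concatenate([[0.0], self.grid.edges[1:]])
        surv = np.concatenate([np.ones((self.n_patients, 1)), self.survival], axis=1)
        for i, pid in enumerate(patient_ids):
            for t, s in zip(times, surv[i]):
                rows.append({"patient_id": pid, "time_days": t, "survival_probability": s})
        return pd.DataFrame(rows)


def predict_survival(model: LogisticHazardNet, X: np.ndarray, grid: TimeGrid) -> DiscreteSurvivalPrediction:
    """Predicted hazards and step survival curves for encoded, scaled X."""
    h = model.predict_hazards(X)
    return DiscreteSurvivalPrediction(grid=grid, hazards=h)


# ----------------------------------------------------------- persistence ----


def save_checkpoint(path, model: LogisticHazardNet, extra: dict | None = None) -> None:
    """Self-describing JSON checkpoint (weights, config, and any sidecar
    state such as scaler statistics, grid edges and feature schema)."""
    payload = {"model": model.state_dict(), "extra": extra or {}}
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path) -> tuple[LogisticHazardNet, dict]:
    payload = json.loads(Path(path).read_text())
    return LogisticHazardNet.from_state_dict(payload["model"]), payload["extra"]


# --------------------------------------------------------- random search ----


def random_search_hyperparameters(
    evaluate,
    space: dict,
    budget: int,
    seed: int = 0,
) -> tuple[dict, list[dict]]:
    """Randomized hyperparameter search minimizing a CV metric.

    ``evaluate(config_overrides) -> float`` scores one sampled configuration
    (typically mean integrated IPCW Brier across folds); ``space`` maps
    hyperparameter name to either a list (uniform choice) or a (low, high)
    tuple (uniform draw).  Returns the best overrides and the trial table.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    trials = []
    best = None
    for _ in range(budget):
        cand: dict = {}
        for name, spec in space.items():
            if isinstance(spec, (list, tuple)) and not (
                isinstance(spec, tuple) and len(spec) == 2 and all(
                    isinstance(v, (int, float)) and not isinstance(v, bool) for v in spec
                )
            ):
                cand[name] = spec[int(rng.integers(len(spec)))]
            else:
                lo, hi = spec
                val = float(rng.uniform(lo, hi))
                cand[name] = int(round(val)) if isinstance(lo, int) and isinstance(hi, int) else val
        score = float(evaluate(cand))
        trials.append({**cand, "score": score})
        if best is None or score < best[1]:
            best = (cand, score)
    return best[0], trials
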