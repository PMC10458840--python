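"""Behaviour classifiers: random forest and supervised self-organizing map.

One model is trained per modelling technique and mounting location. The
random forest is the standard classification ensemble (500 trees,
``floor(sqrt(p))`` candidate features per split by default) over the 32
identifier variables; trees are scale-invariant so features are used raw.

The supervised SOM is a Kohonen map with two fused codebook layers per
map unit: a 32-vector feature codebook and a one-hot class codebook.
During training the winning unit minimises a weighted sum of per-layer
squared distances, each layer divided by a running mean of its distances
so the two layers stay commensurable; the winner and its neighbours
(Gaussian kernel on the grid, radius decaying linearly from 2/3 of the
map diagonal to 1) move toward the sample in both layers with a learning
rate decaying linearly over the run. Each of the ``rlen`` passes presents
every training sample once in seeded random order. Features are z-scored
on training statistics (learned on the training set only). At prediction
time the winner is found by the feature layer alone and the label is the
argmax of its class codebook.

Both techniques are fully deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from numba import njit
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_NAMES

ARCHIVE_VERSION = 1


def schema_hash(feature_names: Sequence[str]) -> str:
    return hashlib.sha256("\n".join(feature_names).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class RFParams:
    """Random-forest settings (defaults: 500 trees, mtry = floor(sqrt(p)))."""

    n_trees: int = 500
    mtry: Optional[int] = None  # None -> floor(sqrt(p))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class SOMParams:
    """Supervised-SOM settings (8 x 6 hexagonal map, rlen = 100)."""

    grid_rows: int = 8
    grid_cols: int = 6
    topology: str = "hexagonal"
    rlen: int = 100
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    radius_start: Optional[float] = None  # None -> 2/3 of map diagonal
    class_layer_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid sizes must be >= 1")
        if self.rlen < 1:
            raise ValueError("rlen must be >= 1")
        if not (self.alpha_start >= self.alpha_end > 0):
            raise ValueError("need alpha_start >= alpha_end > 0")
        if not 0.0 <= self.class_layer_weight < 1.0:
            raise ValueError("class_layer_weight must be in [0, 1)")
        if self.topology not in ("hexagonal", "rectangular"):
            raise ValueError(f"unknown topology {self.topology!r}")


def _grid_coords(params: SOMParams) -> np.ndarray:
    rows, cols = params.grid_rows, params.grid_cols
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    r = r.ravel().astype(float)
    c = c.ravel().astype(float)
    if params.topology == "hexagonal":
        x = c + 0.5 * (r % 2)
        y = r * (math.sqrt(3.0) / 2.0)
    else:
        x, y = c, r
    return np.column_stack([x, y])


@njit(cache=True)
def _som_fit(X, Y, cb_x, cb_y, coords, orders, alphas, radii, w_class,
             scale_eta, history):  # pragma: no cover - numba kernel
    n, p = X.shape
    u, k = cb_y.shape
    rlen = orders.shape[0]
    sx = 1.0
    sy = 1.0
    first = True
    step = 0
    dx = np.empty(u)
    dy = np.empty(u)
    for it in range(rlen):
        pass_dist = 0.0
        for jj in range(n):
            i = orders[it, jj]
            mx = 0.0
            my = 0.0
            for m in range(u):
                acc = 0.0
                for f in range(p):
                    d = X[i, f] - cb_x[m, f]
                    acc += d * d
                dx[m] = acc
                mx += acc
                acc = 0.0
                for f in range(k):
                    d = Y[i, f] - cb_y[m, f]
                    acc += d * d
                dy[m] = acc
                my += acc
            mx /= u
            my /= u
            if first:
                sx = mx if mx > 0.0 else 1.0
                sy = my if my > 0.0 else 1.0
                first = False
            else:
                if mx > 0.0:
                    sx = (1.0 - scale_eta) * sx + scale_eta * mx
                if my > 0.0:
                    sy = (1.0 - scale_eta) * sy + scale_eta * my
            best = 0
            best_d = 1e300
            for m in range(u):
                d = (1.0 - w_class) * dx[m] / sx + w_class * dy[m] / sy
                if d < best_d:
                    best_d = d
                    best = m
            pass_dist += dx[best]
            alpha = alphas[step]
            sigma = radii[step]
            step += 1
            two_s2 = 2.0 * sigma * sigma
            for m in range(u):
                gx = coords[m, 0] - coords[best, 0]
                gy = coords[m, 1] - coords[best, 1]
                h = alpha * np.exp(-(gx * gx + gy * gy) / two_s2)
                if h < 1e-6:
                    continue
                for f in range(p):
                    cb_x[m, f] += h * (X[i, f] - cb_x[m, f])
                for f in range(k):
                    cb_y[m, f] += h * (Y[i, f] - cb_y[m, f])
        history[it] = pass_dist / n
    return sx, sy


class _SOMState:
    """Fitted supervised-SOM state (codebooks + standardisation)."""

    def __init__(self, params: SOMParams, classes: tuple[str, ...],
                 mean: np.ndarray, sd: np.ndarray, cb_x: np.ndarray,
                 cb_y: np.ndarray, history: np.ndarray):
        self.params = params
        self.classes = classes
        self.mean = mean
        self.sd = sd
        self.codebook_features = cb_x
        self.codebook_classes = cb_y
        self.history = history  # mean winner feature distance per pass

    def predict_codes(self, X: np.ndarray, chunk: int = 65536) -> np.ndarray:
        Z = (X - self.mean) / self.sd
        cb = self.codebook_features
        cb_sq = (cb * cb).sum(axis=1)
        winners = np.empty(Z.shape[0], dtype=np.int64)
        # winner by the feature layer only; chunked so day-long traces fit
        for lo in range(0, Z.shape[0], chunk):
            z = Z[lo:lo + chunk]
            d = (z * z).sum(axis=1)[:, None] - 2.0 * (z @ cb.T) + cb_sq[None, :]
            winners[lo:lo + chunk] = d.argmin(axis=1)
        return self.codebook_classes[winners].argmax(axis=1)


@dataclass
class TrainedModel:
    """A fitted classifier plus the metadata needed to refuse misuse."""

    technique: str  # "RF" | "SOM"
    mount: str
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    state: object
    metadata: dict = field(default_factory=dict)

    @property
    def schema(self) -> str:
        return schema_hash(self.feature_names)

    def _matrix(self, features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in features.columns]
            if missing:
                raise ValueError(
                    f"feature schema mismatch: missing columns {missing}")
            return features[list(self.feature_names)].to_numpy(dtype=float)
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature schema mismatch: expected {len(self.feature_names)} "
                f"columns, got shape {X.shape}")
        return X

    def predict(self, features) -> np.ndarray:
        """One label per epoch row."""
        X = self._matrix(features)
        if self.technique == "RF":
            return self.state.predict(X)
        codes = self.state.predict_codes(X)
        return np.array(self.classes, dtype=object)[codes]


def _check_train(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    X = data[list(FEATURE_NAMES)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("training features contain non-finite values")
    y = data["label"].to_numpy(dtype=object)
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    return X, y, classes


def _mount_of(data: pd.DataFrame) -> str:
    mounts = data["mount"].unique() if "mount" in data.columns else ["collar"]
    return str(mounts[0]) if len(mounts) == 1 else "mixed"


def train_random_forest(train: pd.DataFrame,
                        params: RFParams = RFParams()) -> TrainedModel:
    """Fit a 500-tree random forest on the 32 identifier variables."""
    X, y, classes = _check_train(train)
    mtry = params.mtry if params.mtry is not None else int(math.isqrt(X.shape[1]))
    if not 1 <= mtry <= X.shape[1]:
        raise ValueError(f"mtry must be in [1, {X.shape[1]}]")
    rf = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features=mtry,
        random_state=params.seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return TrainedModel(
        "RF", _mount_of(train), classes, tuple(FEATURE_NAMES), rf,
        metadata={"params": params, "class_counts":
                  pd.Series(y).value_counts().to_dict()},
    )


def train_supervised_som(train: pd.DataFrame,
                         params: SOMParams = SOMParams()) -> TrainedModel:
    """Fit the supervised Kohonen map described in the module docstring."""
    X, y, classes = _check_train(train)
    n, p = X.shape
    units = params.grid_rows * params.grid_cols
    if units > 10 * n:
        import logging
        logging.getLogger(__name__).warning(
            "map has %d units for only %d training rows; the map will be "
            "under-populated", units, n)

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    Z = (X - mean) / sd

    k = len(classes)
    class_index = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((n, k))
    Y[np.arange(n), [class_index[c] for c in y]] = 1.0

    rng = np.random.default_rng(params.seed)
    cb_x = Z[rng.choice(n, size=units, replace=n < units)].copy()
    cb_y = np.full((units, k), 1.0 / k)

    coords = _grid_coords(params)
    if params.radius_start is None:
        span = coords.max(axis=0) - coords.min(axis=0)
        radius_start = max(float(np.hypot(*span)) * 2.0 / 3.0, 1.0)
    else:
        radius_start = float(params.radius_start)

    steps = params.rlen * n
    alphas = np.linspace(params.alpha_start, params.alpha_end, steps)
    radii = np.linspace(radius_start, 1.0, steps)
    orders = np.empty((params.rlen, n), dtype=np.int64)
    for it in range(params.rlen):
        orders[it] = rng.permutation(n)

    history = np.zeros(params.rlen)
    _som_fit(Z, Y, cb_x, cb_y, coords, orders, alphas, radii,
             params.class_layer_weight, 1.0e-3, history)

    state = _SOMState(params, classes, mean, sd, cb_x, cb_y, history)
    return TrainedModel(
        "SOM", _mount_of(train), classes, tuple(FEATURE_NAMES), state,
        metadata={"params": params, "class_counts":
                  pd.Series(y).value_counts().to_dict()},
    )


def predict_labels(model: TrainedModel, features) -> np.ndarray:
    """Predict one behaviour label per epoch (schema-checked)."""
    return model.predict(features)


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model as a versioned archive."""
    joblib.dump({"version": ARCHIVE_VERSION, "model": model}, path)


def load_model(path) -> TrainedModel:
    """Load a model archive, refusing cross-version loads."""
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("version") != ARCHIVE_VERSION:
        raise ValueError(
            f"{path}: unsupported model archive version "
            f"{payload.get('version') if isinstance(payload, dict) else '?'}")
    return payload["model"]
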