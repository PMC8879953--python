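"""Level-1 posture recognition from one-second accelerometer windows.

The primary classifier is a stacked recurrent network: two LSTM layers of 64
units each, reading a normalized ``(50, 3)`` window timestep by timestep,
followed by a softmax layer over the posture classes (3 for the head sensor,
6 for the body sensor).  Head and body networks are independent and
parallel.  Training uses categorical cross-entropy with the Adam optimizer
(beta1 = 0.9, beta2 = 0.999, learning rate 0.0025), batch size 25, 50
epochs, and stratified 5-fold cross-validation for reporting.

The network is implemented directly on numpy (forward pass, full
backpropagation through time, Adam) — the input windows are tiny, so CPU
training takes seconds to minutes.  Statistical-feature baselines (SVM,
naive Bayes, decision tree on per-axis min/max/mean/std) are provided for
comparison via scikit-learn.

All randomness is seeded; training is reproducible bit-for-bit on one
platform for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .events import BODY_POSTURES, HEAD_POSTURES, Posture, PostureEvent, Sensor

__all__ = [
    "HEAD_CLASSES",
    "BODY_CLASSES",
    "ClassifierConfig",
    "TrainingConfig",
    "StackedLSTMClassifier",
    "build_model",
    "train",
    "predict",
    "predict_batch",
    "extract_features",
    "train_baseline",
    "save_model",
    "load_model",
]

#: Fixed class-enumeration order (also the argmax tie-break order).
HEAD_CLASSES = (Posture.UP, Posture.DOWN, Posture.BARK)
BODY_CLASSES = (
    Posture.WALK,
    Posture.LIE,
    Posture.SIT,
    Posture.STAND,
    Posture.DIG,
    Posture.JUMP,
)


def classes_for_sensor(sensor: Sensor):
    return HEAD_CLASSES if Sensor(sensor) is Sensor.HEAD else BODY_CLASSES


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture of one posture network."""

    sensor: Sensor
    classes: tuple = ()
    recurrent_layers: int = 2
    units_per_layer: int = 64
    timesteps: int = 50
    features: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "sensor", Sensor(self.sensor))
        if not self.classes:
            object.__setattr__(self, "classes", classes_for_sensor(self.sensor))
        classes = tuple(Posture(c) for c in self.classes)
        object.__setattr__(self, "classes", classes)
        valid = HEAD_POSTURES if self.sensor is Sensor.HEAD else BODY_POSTURES
        for c in classes:
            if c not in valid:
                raise ValueError(f"class {c.value!r} invalid for sensor {self.sensor.value!r}")
        if self.recurrent_layers < 1 or self.units_per_layer < 1:
            raise ValueError("need at least one layer and one unit")
        if self.timesteps < 1 or self.features < 1:
            raise ValueError("invalid input shape")
        if len(classes) < 2:
            raise ValueError("need at least two classes")

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyperparameters (loss is categorical cross-entropy)."""

    learning_rate: float = 0.0025
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 25
    epochs: int = 50
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.beta1, self.beta2, self.epsilon) <= 0:
            raise ValueError("all rates must be positive")
        if self.folds < 2:
            raise ValueError("need at least two folds")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class StackedLSTMClassifier:
    """Stacked LSTM + softmax posture classifier on numpy.

    Gate layout per layer is ``[input, forget, cell, output]`` in one fused
    weight matrix; the forget-gate bias is initialized to 1.  Weights use
    Glorot-uniform initialization from a seeded generator.
    """

    def __init__(self, config: ClassifierConfig):
        self.config = config
        self.params: dict = {}
        self._adam_m: dict = {}
        self._adam_v: dict = {}
        self._adam_t = 0
        self.fitted = False

    # -- parameters --------------------------------------------------------

    def initialize(self, rng: np.random.Generator) -> None:
        cfg = self.config
        H = cfg.units_per_layer
        self.params = {}
        in_dim = cfg.features
        for layer in range(cfg.recurrent_layers):
            def glorot(fan_in, fan_out):
                limit = np.sqrt(6.0 / (fan_in + fan_out))
                return rng.uniform(-limit, limit, size=(fan_in, fan_out))

            self.params[f"Wx{layer}"] = glorot(in_dim, 4 * H)
            self.params[f"Wh{layer}"] = glorot(H, 4 * H)
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias
            self.params[f"b{layer}"] = b
            in_dim = H
        limit = np.sqrt(6.0 / (H + cfg.n_classes))
        self.params["Wy"] = rng.uniform(-limit, limit, size=(H, cfg.n_classes))
        self.params["by"] = np.zeros(cfg.n_classes)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward / backward ------------------------------------------------

    def _forward(self, X, want_cache: bool = False):
        cfg = self.config
        B, T, _ = X.shape
        H = cfg.units_per_layer
        layer_input = X
        caches = []
        for layer in range(cfg.recurrent_layers):
            Wx, Wh, b = (
                self.params[f"Wx{layer}"],
                self.params[f"Wh{layer}"],
                self.params[f"b{layer}"],
            )
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            hs = np.empty((B, T, H))
            steps = []
            for t in range(T):
                x_t = layer_input[:, t, :]
                z = x_t @ Wx + h @ Wh + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H : 2 * H])
                g = np.tanh(z[:, 2 * H : 3 * H])
                o = _sigmoid(z[:, 3 * H :])
                c_prev, h_prev = c, h
                c = f * c_prev + i * g
                tanh_c = np.tanh(c)
                h = o * tanh_c
                hs[:, t, :] = h
                if want_cache:
                    steps.append((x_t, h_prev, c_prev, i, f, g, o, tanh_c))
            caches.append((layer_input, hs, steps))
            layer_input = hs
        logits = layer_input[:, -1, :] @ self.params["Wy"] + self.params["by"]
        probs = _softmax(logits)
        return (probs, caches) if want_cache else probs

    def _backward(self, probs, y_onehot, caches):
        cfg = self.config
        H = cfg.units_per_layer
        B, T = caches[0][0].shape[0], caches[0][0].shape[1]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dlogits = (probs - y_onehot) / B
        top_hs = caches[-1][1]
        grads["Wy"] = top_hs[:, -1, :].T @ dlogits
        grads["by"] = dlogits.sum(axis=0)
        dh_seq = np.zeros((B, T, H))
        dh_seq[:, -1, :] = dlogits @ self.params["Wy"].T
        for layer in range(cfg.recurrent_layers - 1, -1, -1):
            layer_input, _, steps = caches[layer]
            Wx = self.params[f"Wx{layer}"]
            Wh = self.params[f"Wh{layer}"]
            dWx = np.zeros_like(Wx)
            dWh = np.zeros_like(Wh)
            db = np.zeros_like(self.params[f"b{layer}"])
            dx_seq = np.zeros_like(layer_input)
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                x_t, h_prev, c_prev, i, f, g, o, tanh_c = steps[t]
                dh = dh_seq[:, t, :] + dh_next
                do = dh * tanh_c
                dc = dc_next + dh * o * (1.0 - tanh_c**2)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dc_next = dc * f
                dz = np.concatenate(
                    [
                        di * i * (1.0 - i),
                        df * f * (1.0 - f),
                        dg * (1.0 - g**2),
                        do * o * (1.0 - o),
                    ],
                    axis=1,
                )
                dWx += x_t.T @ dz
                dWh += h_prev.T @ dz
                db += dz.sum(axis=0)
                dx_seq[:, t, :] = dz @ Wx.T
                dh_next = dz @ Wh.T
            grads[f"Wx{layer}"] = dWx
            grads[f"Wh{layer}"] = dWh
            grads[f"b{layer}"] = db
            dh_seq = dx_seq
        return grads

    def _adam_step(self, grads, tc: TrainingConfig) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = tc.beta1 * self._adam_m[k] + (1 - tc.beta1) * g
            v = self._adam_v[k] = tc.beta2 * self._adam_v[k] + (1 - tc.beta2) * g**2
            m_hat = m / (1 - tc.beta1**t)
            v_hat = v / (1 - tc.beta2**t)
            self.params[k] -= tc.learning_rate * m_hat / (np.sqrt(v_hat) + tc.epsilon)

    # -- public API --------------------------------------------------------

    def encode_labels(self, labels) -> np.ndarray:
        index = {c: k for k, c in enumerate(self.config.classes)}
        try:
            return np.array([index[Posture(l)] for l in labels], dtype=int)
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in configured classes") from exc

    def fit(self, X, labels, training_config: "TrainingConfig | None" = None):
        tc = training_config if training_config is not None else TrainingConfig()
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1:] != (self.config.timesteps, self.config.features):
            raise ValueError(
                f"expected (n, {self.config.timesteps}, {self.config.features}) "
                f"input, got {X.shape}"
            )
        y = self.encode_labels(labels)
        present = set(np.unique(y))
        missing = [c.value for k, c in enumerate(self.config.classes) if k not in present]
        if missing:
            raise ValueError(f"classes absent from training data: {missing}")
        rng = np.random.default_rng(tc.seed)
        self.initialize(rng)
        n = len(X)
        onehot = np.eye(self.config.n_classes)[y]
        for _epoch in range(tc.epochs):
            order = rng.permutation(n)
            for start in range(0, n, tc.batch_size):
                idx = order[start : start + tc.batch_size]
                probs, caches = self._forward(X[idx], want_cache=True)
                grads = self._backward(probs, onehot[idx], caches)
                self._adam_step(grads, tc)
        self.fitted = True
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        return self._forward(X)

    def predict_labels(self, X):
        probs = self.predict_proba(X)
        # np.argmax picks the lowest index on ties, matching the fixed order
        return [self.config.classes[k] for k in probs.argmax(axis=1)]


def build_model(config: ClassifierConfig) -> StackedLSTMClassifier:
    """Construct an untrained stacked-LSTM posture classifier."""
    return StackedLSTMClassifier(config)


def train(
    model: StackedLSTMClassifier,
    tensors,
    labels,
    training_config: "TrainingConfig | None" = None,
    cross_validate: bool = True,
):
    """Fit the classifier; optionally report stratified per-fold metrics.

    Returns ``(model, fold_reports)`` where each fold report is a
    :class:`~caniscope.evaluation.MetricsReport` computed on that fold's
    held-out windows.  The returned model is refitted on all data.
    """
    from .evaluation import confusion_from_labels, precision_recall_f1

    tc = training_config if training_config is not None else TrainingConfig()
    X = np.asarray(tensors, dtype=float)
    y = model.encode_labels(labels)
    present = set(np.unique(y))
    missing = [c.value for k, c in enumerate(model.config.classes) if k not in present]
    if missing:
        raise ValueError(f"classes absent from training data: {missing}")

    fold_reports = []
    if cross_validate:
        skf = StratifiedKFold(n_splits=tc.folds, shuffle=True, random_state=tc.seed)
        for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            fold_model = build_model(model.config)
            fold_tc = replace(tc, seed=tc.seed + fold + 1)
            fold_model.fit(X[train_idx], [labels[i] for i in train_idx], fold_tc)
            pred = fold_model.predict_labels(X[test_idx])
            truth = [Posture(labels[i]) for i in test_idx]
            counts = confusion_from_labels(
                [p.value for p in truth],
                [p.value for p in pred],
                classes=[c.value for c in model.config.classes],
            )
            fold_reports.append(precision_recall_f1(counts))
    model.fit(X, labels, tc)
    return model, fold_reports


def predict(model: StackedLSTMClassifier, window, subject_id: str, t: float):
    """Classify one normalized window into a posture event.

    Values outside [0, 1] are clipped (with a warning); the event's posture
    is the argmax of the softmax distribution, ties broken by the fixed
    class-enumeration order.  Returns ``(PostureEvent, distribution dict)``.
    """
    window = np.asarray(window, dtype=float)
    if np.any(window < 0.0) or np.any(window > 1.0):
        import warnings

        warnings.warn("window values outside [0, 1]; clipping — was it normalized?")
        window = np.clip(window, 0.0, 1.0)
    probs = model.predict_proba(window)[0]
    k = int(probs.argmax())
    event = PostureEvent(
        subject_id=subject_id,
        sensor_id=model.config.sensor,
        posture=model.config.classes[k],
        t=t,
    )
    distribution = {c.value: float(p) for c, p in zip(model.config.classes, probs)}
    return event, distribution


def predict_batch(model: StackedLSTMClassifier, tensor, start_times, subject_id: str):
    """Classify a batch of windows into a list of posture events."""
    labels = model.predict_labels(tensor)
    return [
        PostureEvent(subject_id=subject_id, sensor_id=model.config.sensor, posture=p, t=float(t))
        for p, t in zip(labels, start_times)
    ]


# ---------------------------------------------------------------------------
# Statistical-feature baselines
# ---------------------------------------------------------------------------

def extract_features(window) -> np.ndarray:
    """Per-axis min, max, mean, std (population) in axis-major order (12 values)."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != 3:
        raise ValueError(f"expected a (timesteps, 3) window, got {window.shape}")
    feats = []
    for axis in range(3):
        v = window[:, axis]
        feats.extend([v.min(), v.max(), v.mean(), v.std()])
    return np.array(feats)


_BASELINES = {
    "svm": lambda seed: SVC(kernel="rbf", random_state=seed),
    "naive_bayes": lambda seed: GaussianNB(),
    "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
}


def train_baseline(features, labels, kind: str = "svm", seed: int = 0):
    """Fit a statistical-feature baseline classifier (svm/naive_bayes/decision_tree)."""
    if kind not in _BASELINES:
        raise ValueError(f"unknown baseline {kind!r}; choose from {sorted(_BASELINES)}")
    X = np.asarray(features, dtype=float)
    y = np.asarray([Posture(l).value for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("baseline training needs at least two classes")
    model = _BASELINES[kind](seed)
    model.fit(X, y)
    return model


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_model(model: StackedLSTMClassifier, path) -> None:
    """Write a single-file checkpoint (npz with a versioned JSON header)."""
    meta = {
        "format_version": _CHECKPOINT_VERSION,
        "sensor": model.config.sensor.value,
        "classes": [c.value for c in model.config.classes],
        "recurrent_layers": model.config.recurrent_layers,
        "units_per_layer": model.config.units_per_layer,
        "timesteps": model.config.timesteps,
        "features": model.config.features,
        "fitted": model.fitted,
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **model.params)


def load_model(path) -> StackedLSTMClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta["format_version"] != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
        config = ClassifierConfig(
            sensor=Sensor(meta["sensor"]),
            classes=tuple(Posture(c) for c in meta["classes"]),
            recurrent_layers=meta["recurrent_layers"],
            units_per_layer=meta["units_per_layer"],
            timesteps=meta["timesteps"],
            features=meta["features"],
        )
        model = StackedLSTMClassifier(config)
        model.params = {k: data[k] for k in data.files if k != "__meta__"}
        model.fitted = bool(meta["fitted"])
    return model
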