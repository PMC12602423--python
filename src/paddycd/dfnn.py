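"""Deep feedforward network for per-pixel 5-band spectral classification.

The classifier is a small fully connected network — input(5) → Dense(20,
ReLU) → Dropout(0.2) → Dense(15, ReLU) → Dropout(0.2) → Dense(k, softmax) —
trained with Adam on categorical cross-entropy plus an L2 weight penalty.
Hidden layers use He-normal initialization (matched to ReLU), the output
layer Glorot-uniform. Dropout is active only during training; inference is
deterministic. With k = 3 the network has 483 trainable parameters, small
enough that per-pixel inference over a whole orthomosaic is cheap.

The network is implemented directly on numpy: the model is tiny, the input
is tabular (one 5-vector per pixel), and an explicit implementation keeps
training bit-reproducible from a single integer seed.

Evaluation follows the standard confusion-matrix suite: overall accuracy,
Cohen's kappa, categorical cross-entropy, mean squared error on the
probability vectors, and one-vs-all precision/recall/F1 per class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .samples import ScalerParams
from .scene import BAND_COLUMNS

__all__ = [
    "ModelSpec", "TrainingConfig", "FittedModel", "EvaluationReport",
    "build_model", "train", "predict_proba", "predict_label",
    "confusion_matrix", "overall_accuracy", "kappa", "cross_entropy",
    "mean_squared_error", "per_class_prf", "evaluate",
]

PROB_FLOOR = 1e-12  # probability floor inside log() for cross-entropy


@dataclass(frozen=True)
class ModelSpec:
    """Architecture: layer sizes, regularization and initialization."""

    input_dim: int = 5
    hidden: tuple[int, ...] = (20, 15)
    n_classes: int = 3
    dropout: float = 0.2
    l2_lambda: float = 1e-6

    def __post_init__(self):
        if self.input_dim < 1 or self.n_classes < 2 or any(h < 1 for h in self.hidden):
            raise ValueError("layer dimensions must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")

    def parameter_count(self) -> int:
        dims = (self.input_dim, *self.hidden, self.n_classes)
        return sum(dims[i] * dims[i + 1] + dims[i + 1] for i in range(len(dims) - 1))


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.005
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience < 0:
            raise ValueError("invalid batch size, epoch count or patience")


@dataclass
class FittedModel:
    """Layer weights plus everything needed to reuse them: the training-set
    scaler, the class-code ordering, and the per-epoch training history."""

    spec: ModelSpec
    weights: list[np.ndarray]  # [W1, b1, W2, b2, W3, b3]
    class_codes: tuple[int, ...]
    scaler: ScalerParams | None = None
    history: pd.DataFrame | None = None
    trained: bool = False

    def copy_weights(self) -> list[np.ndarray]:
        return [w.copy() for w in self.weights]

    def save(self, directory: str | Path) -> None:
        """Model bundle: weights (npz), spec + class codes (JSON), scaler
        (JSON), history (CSV)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", *self.weights)
        (d / "spec.json").write_text(json.dumps({
            "input_dim": self.spec.input_dim,
            "hidden": list(self.spec.hidden),
            "n_classes": self.spec.n_classes,
            "dropout": self.spec.dropout,
            "l2_lambda": self.spec.l2_lambda,
            "class_codes": list(self.class_codes),
            "trained": self.trained,
        }))
        if self.scaler is not None:
            (d / "scaler.json").write_text(self.scaler.to_json())
        if self.history is not None:
            self.history.to_csv(d / "history.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "FittedModel":
        d = Path(directory)
        meta = json.loads((d / "spec.json").read_text())
        spec = ModelSpec(
            input_dim=meta["input_dim"], hidden=tuple(meta["hidden"]),
            n_classes=meta["n_classes"], dropout=meta["dropout"],
            l2_lambda=meta["l2_lambda"],
        )
        with np.load(d / "weights.npz") as z:
            weights = [z[k] for k in z.files]
        scaler = None
        if (d / "scaler.json").exists():
            scaler = ScalerParams.from_json((d / "scaler.json").read_text())
        history = None
        if (d / "history.csv").exists():
            history = pd.read_csv(d / "history.csv")
        return cls(spec=spec, weights=weights,
                   class_codes=tuple(meta["class_codes"]), scaler=scaler,
                   history=history, trained=meta["trained"])


def build_model(spec: ModelSpec, seed: int,
                class_codes: tuple[int, ...] | None = None) -> FittedModel:
    """Initialize an untrained model: He-normal hidden layers (std
    sqrt(2/fan_in)), Glorot-uniform output layer. Deterministic per seed."""
    rng = np.random.default_rng(seed)
    dims = (spec.input_dim, *spec.hidden, spec.n_classes)
    weights: list[np.ndarray] = []
    n_layers = len(dims) - 1
    for i in range(n_layers):
        fan_in, fan_out = dims[i], dims[i + 1]
        if i < n_layers - 1:  # hidden: He normal
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        else:  # output: Glorot uniform
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        weights.append(w)
        weights.append(np.zeros(fan_out))
    if class_codes is None:
        class_codes = tuple(range(spec.n_classes))
    if len(class_codes) != spec.n_classes:
        raise ValueError("class_codes length must equal n_classes")
    return FittedModel(spec=spec, weights=weights, class_codes=class_codes)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(weights, x, dropout=0.0, rng=None):
    """Forward pass; returns (probs, cache) — cache holds the activations
    and dropout masks needed by the backward pass."""
    n_dense = len(weights) // 2
    a = x
    cache = [a]
    masks = []
    for i in range(n_dense - 1):
        w, b = weights[2 * i], weights[2 * i + 1]
        h = np.maximum(a @ w + b, 0.0)  # ReLU
        if dropout > 0.0 and rng is not None:
            mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
            h = h * mask
            masks.append(mask)
        else:
            masks.append(None)
        a = h
        cache.append(a)
    w, b = weights[-2], weights[-1]
    probs = _softmax(a @ w + b)
    return probs, (cache, masks)


def _backward(weights, probs, y_onehot, cache, masks, l2_lambda):
    """Gradients of mean CCE + λΣw² w.r.t. every weight array."""
    n = probs.shape[0]
    activations, _ = cache, masks
    grads = [None] * len(weights)
    delta = (probs - y_onehot) / n  # dL/dlogits for softmax + CCE
    n_dense = len(weights) // 2
    for i in range(n_dense - 1, -1, -1):
        a_prev = activations[i]
        w = weights[2 * i]
        grads[2 * i] = a_prev.T @ delta + 2.0 * l2_lambda * w
        grads[2 * i + 1] = delta.sum(axis=0)
        if i > 0:
            delta = delta @ w.T
            if masks[i - 1] is not None:
                delta = delta * masks[i - 1]
            delta = delta * (activations[i] > 0)  # ReLU gate
    return grads


def _table_xy(table: pd.DataFrame, class_codes):
    x = table[list(BAND_COLUMNS)].to_numpy(dtype=np.float64)
    code_to_idx = {c: i for i, c in enumerate(class_codes)}
    labels = table["label"].to_numpy()
    unknown = set(np.unique(labels)) - set(class_codes)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} outside model class codes "
                         f"{list(class_codes)}")
    y = np.array([code_to_idx[c] for c in labels], dtype=np.int64)
    return x, y


def _loss(weights, x, y, l2_lambda):
    probs, _ = _forward(weights, x)
    n = x.shape[0]
    cce = -np.log(np.maximum(probs[np.arange(n), y], PROB_FLOOR)).mean()
    penalty = l2_lambda * sum(float((weights[2 * i] ** 2).sum())
                              for i in range(len(weights) // 2))
    return cce + penalty, probs


def train(model: FittedModel, train_table: pd.DataFrame,
          val_table: pd.DataFrame, cfg: TrainingConfig = TrainingConfig(),
          scaler: ScalerParams | None = None) -> FittedModel:
    """Train with Adam, early stopping on validation loss, best-weight
    restoration.

    Input tables must already be standardized (a loud warning is raised if
    any band's mean is far from zero at n ≥ 1000). The scaler used to
    standardize them should be passed so the fitted model can standardize
    raw reflectance itself at inference time.
    """
    for name, t in (("training", train_table), ("validation", val_table)):
        if len(t) == 0:
            raise ValueError(f"{name} table is empty")
        if len(t) >= 1000:
            band_means = t[list(BAND_COLUMNS)].mean().to_numpy()
            if np.any(np.abs(band_means) > 0.5):
                warnings.warn(
                    f"{name} table does not look standardized "
                    f"(band means {np.round(band_means, 3)})", stacklevel=2)

    x_tr, y_tr = _table_xy(train_table, model.class_codes)
    x_va, y_va = _table_xy(val_table, model.class_codes)
    spec = model.spec
    weights = model.copy_weights()
    rng = np.random.default_rng(cfg.seed)

    m = [np.zeros_like(w) for w in weights]
    v = [np.zeros_like(w) for w in weights]
    t_step = 0
    best_val = np.inf
    best_weights = [w.copy() for w in weights]
    wait = 0
    rows = []

    n = x_tr.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            y_onehot = np.zeros((len(idx), spec.n_classes))
            y_onehot[np.arange(len(idx)), yb] = 1.0
            probs, (cache, masks) = _forward(weights, xb, spec.dropout, rng)
            grads = _backward(weights, probs, y_onehot, cache, masks,
                              spec.l2_lambda)
            t_step += 1
            lr_t = cfg.learning_rate * (np.sqrt(1 - cfg.beta2 ** t_step)
                                        / (1 - cfg.beta1 ** t_step))
            for k, g in enumerate(grads):
                m[k] = cfg.beta1 * m[k] + (1 - cfg.beta1) * g
                v[k] = cfg.beta2 * v[k] + (1 - cfg.beta2) * g * g
                weights[k] -= lr_t * m[k] / (np.sqrt(v[k]) + 1e-8)

        tr_loss, tr_probs = _loss(weights, x_tr, y_tr, spec.l2_lambda)
        va_loss, va_probs = _loss(weights, x_va, y_va, spec.l2_lambda)
        rows.append({
            "epoch": epoch,
            "train_loss": tr_loss,
            "train_accuracy": float((tr_probs.argmax(1) == y_tr).mean()),
            "val_loss": va_loss,
            "val_accuracy": float((va_probs.argmax(1) == y_va).mean()),
        })
        if va_loss < best_val:
            best_val = va_loss
            best_weights = [w.copy() for w in weights]
            wait = 0
        else:
            wait += 1
            if wait > cfg.patience:
                break

    return FittedModel(
        spec=spec, weights=best_weights, class_codes=model.class_codes,
        scaler=scaler if scaler is not None else model.scaler,
        history=pd.DataFrame(rows), trained=True,
    )


def predict_proba(model: FittedModel, spectra: np.ndarray) -> np.ndarray:
    """Class probabilities for raw (unstandardized) reflectance 5-vectors.

    The model's stored training-set scaler is applied internally, so the
    same trained weights serve every acquisition date. Dropout is off:
    inference is deterministic.
    """
    if not model.trained:
        raise ValueError("model is not trained")
    if model.scaler is None:
        raise ValueError("model has no scaler; inference on raw reflectance "
                         "requires the training-set standardization")
    x = np.asarray(spectra, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.spec.input_dim:
        raise ValueError(f"expected {model.spec.input_dim} bands, "
                         f"got {x.shape[1]}")
    x = (x - model.scaler.mean) / model.scaler.sd
    probs, _ = _forward(model.weights, x)
    return probs


def predict_label(model: FittedModel, spectra: np.ndarray) -> np.ndarray:
    """Argmax class codes; ties break to the lowest class code (argmax on
    the code-ordered probability matrix returns the first maximum)."""
    probs = predict_proba(model, spectra)
    return np.asarray(model.class_codes)[probs.argmax(axis=1)]


# ---------------------------------------------------------------------------
# Confusion-matrix metric suite
# ---------------------------------------------------------------------------

def confusion_matrix(reference: np.ndarray, predicted: np.ndarray,
                     class_codes: tuple[int, ...]) -> np.ndarray:
    """k×k pixel counts; rows = reference class, columns = predicted."""
    k = len(class_codes)
    code_to_idx = {c: i for i, c in enumerate(class_codes)}
    cm = np.zeros((k, k), dtype=np.int64)
    for r, p in zip(np.asarray(reference).ravel(), np.asarray(predicted).ravel()):
        cm[code_to_idx[r], code_to_idx[p]] += 1
    return cm


def overall_accuracy(cm: np.ndarray) -> float:
    """Percentage of pixels on the diagonal: 100 · trace / total."""
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * np.trace(cm) / total


def kappa(cm: np.ndarray) -> float:
    """Cohen's kappa: (p_o − p_e)/(1 − p_e), chance agreement p_e from the
    row/column marginal products. Undefined when p_e = 1."""
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0:
        raise ValueError("chance agreement is 1; kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def _check_probs(labels_onehot: np.ndarray, probabilities: np.ndarray):
    y = np.asarray(labels_onehot, dtype=np.float64)
    p = np.asarray(probabilities, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: labels {y.shape} vs "
                         f"probabilities {p.shape}")
    return y, p


def cross_entropy(labels_onehot: np.ndarray, probabilities: np.ndarray) -> float:
    """Categorical cross-entropy, natural log, probabilities floored at
    1e-12: −(1/N) Σ_i Σ_j y_ij log p_ij."""
    y, p = _check_probs(labels_onehot, probabilities)
    n = y.shape[0]
    return float(-(y * np.log(np.maximum(p, PROB_FLOOR))).sum() / n)


def mean_squared_error(labels_onehot: np.ndarray,
                       probabilities: np.ndarray) -> float:
    """Mean over samples and classes of (y − p)² on probability vectors."""
    y, p = _check_probs(labels_onehot, probabilities)
    return float(((y - p) ** 2).mean())


def per_class_prf(cm: np.ndarray) -> pd.DataFrame:
    """One-vs-all precision, recall and F1 per class.

    A class never predicted (TP+FP = 0) or absent from the reference
    (TP+FN = 0) gets the affected metric reported as 0 and flagged in the
    ``degenerate`` column rather than raising.
    """
    cm = np.asarray(cm, dtype=np.float64)
    k = cm.shape[0]
    rows = []
    for i in range(k):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        degenerate = []
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        if tp + fp == 0:
            degenerate.append("precision")
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        if tp + fn == 0:
            degenerate.append("recall")
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        rows.append({"class_index": i, "precision": precision,
                     "recall": recall, "f1": f1,
                     "degenerate": ",".join(degenerate)})
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    confusion: np.ndarray
    accuracy: float  # percent
    kappa: float
    cross_entropy: float
    mse: float
    per_class: pd.DataFrame
    class_codes: tuple[int, ...]
    n: int

    def to_json(self) -> str:
        return json.dumps({
            "confusion": self.confusion.tolist(),
            "class_codes": list(self.class_codes),
            "accuracy_percent": self.accuracy,
            "kappa": self.kappa,
            "cross_entropy": self.cross_entropy,
            "mse": self.mse,
            "per_class": self.per_class.to_dict(orient="records"),
            "n": self.n,
        }, indent=2)


def evaluate(model: FittedModel, table: pd.DataFrame) -> EvaluationReport:
    """Evaluate on a raw-reflectance sample table: one prediction pass feeds
    the confusion matrix and every metric, so they are mutually consistent
    by construction."""
    if len(table) == 0:
        raise ValueError("cannot evaluate on an empty table")
    probs = predict_proba(model, table[list(BAND_COLUMNS)].to_numpy())
    pred_idx = probs.argmax(axis=1)
    codes = np.asarray(model.class_codes)
    predicted = codes[pred_idx]
    reference = table["label"].to_numpy()
    cm = confusion_matrix(reference, predicted, model.class_codes)

    code_to_idx = {c: i for i, c in enumerate(model.class_codes)}
    y_idx = np.array([code_to_idx[c] for c in reference])
    onehot = np.zeros_like(probs)
    onehot[np.arange(len(y_idx)), y_idx] = 1.0

    return EvaluationReport(
        confusion=cm,
        accuracy=overall_accuracy(cm),
        kappa=kappa(cm),
        cross_entropy=cross_entropy(onehot, probs),
        mse=mean_squared_error(onehot, probs),
        per_class=per_class_prf(cm),
        class_codes=model.class_codes,
        n=len(table),
    )
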