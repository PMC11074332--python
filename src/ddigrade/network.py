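"""Feed-forward softmax classifier trained with class-weighted cross-entropy.

A deliberately small, fully deterministic NumPy implementation of the
member network: dense hidden layers (ReLU ``max(x, 0)`` or tanh
``(e^{2x}-1)/(e^{2x}+1)``), inverted dropout after every hidden layer,
a 4-way softmax output, Adam (beta1=0.9, beta2=0.999, eps=1e-7), and
early stopping on a stratified validation slice held back from the
member's own training subset (never from an outer evaluation fold).

The loss is sparse categorical cross-entropy with a per-sample
multiplier w_{y_i}: the inverse-frequency class weight of the sample's
true class, so misclassifying the rare severe grades costs more.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

N_CLASSES = 4


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture + optimisation settings of one ensemble member."""

    hidden_layers: tuple[int, ...]
    activation: str = "relu"  # relu | tanh
    dropout: float = 0.2
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    max_epochs: int = 200
    batch_size: int = 128
    patience: int = 10
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")


#: "sim" and "embedding" reproduce the two published architectures;
#: "small" is a light preset sized for the modest similarity panels of
#: synthetic benchmarks (extra patience compensates its capacity).
NETWORK_PRESETS: dict[str, NetworkSpec] = {
    "sim": NetworkSpec(hidden_layers=(1024, 512, 256, 128), activation="relu"),
    "embedding": NetworkSpec(hidden_layers=(256, 128), activation="tanh"),
    "small": NetworkSpec(hidden_layers=(256, 128), activation="relu", patience=20),
}


def resolve_spec(spec: NetworkSpec | str) -> NetworkSpec:
    if isinstance(spec, NetworkSpec):
        return spec
    try:
        return NETWORK_PRESETS[spec]
    except KeyError:
        raise ValueError(
            f"unknown network preset {spec!r}; choose from {sorted(NETWORK_PRESETS)}"
        ) from None


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(z, 0.0) if kind == "relu" else np.tanh(z)


def _activate_grad(a: np.ndarray, kind: str) -> np.ndarray:
    # expressed in terms of the activation output
    return (a > 0).astype(a.dtype) if kind == "relu" else 1.0 - a * a


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    probs: np.ndarray, y: np.ndarray, class_weight: np.ndarray
) -> float:
    """Mean over the batch of w_{y_i} * (-log p_{y_i})."""
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(np.mean(class_weight[y] * -np.log(p)))


class MLPSoftmax:
    """One member network.  Not an sklearn estimator on purpose: it is the
    ensemble's internal engine; `ensemble.EnsembleDDIClassifier` is the
    public estimator surface."""

    def __init__(self, spec: NetworkSpec, input_len: int, seed: int = 0):
        if input_len <= 0:
            raise ValueError("input_len must be positive")
        self.spec = spec
        self.input_len = input_len
        self.seed = seed
        self._init_weights()

    def _init_weights(self) -> None:
        rng = np.random.default_rng(self.seed)
        dims = (self.input_len, *self.spec.hidden_layers, N_CLASSES)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            if self.spec.activation == "relu":
                scale = np.sqrt(2.0 / fan_in)  # He
            else:
                scale = np.sqrt(1.0 / fan_in)  # Xavier-ish for tanh
            self.weights.append(rng.standard_normal((fan_in, fan_out)) * scale)
            self.biases.append(np.zeros(fan_out))

    # -- forward / backward ------------------------------------------------

    def _forward(self, X, dropout_rng=None):
        """Returns (probs, activations, dropout masks)."""
        acts = [X]
        masks = []
        a = X
        n_hidden = len(self.spec.hidden_layers)
        for layer in range(n_hidden):
            z = a @ self.weights[layer] + self.biases[layer]
            a = _activate(z, self.spec.activation)
            if dropout_rng is not None and self.spec.dropout > 0:
                keep = 1.0 - self.spec.dropout
                mask = (dropout_rng.random(a.shape) < keep) / keep
                a = a * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(a)
        logits = a @ self.weights[-1] + self.biases[-1]
        return softmax(logits), acts, masks

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_len:
            raise ValueError(
                f"expected (n, {self.input_len}) features, got {X.shape}"
            )
        return self._forward(X)[0]

    def _backward(self, X, y, class_weight, probs, acts, masks):
        n = len(y)
        delta = probs.copy()
        delta[np.arange(n), y] -= 1.0
        delta *= (class_weight[y] / n)[:, None]
        grads_w, grads_b = [], []
        for layer in range(len(self.weights) - 1, -1, -1):
            a_prev = acts[layer]
            grads_w.append(a_prev.T @ delta)
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = delta @ self.weights[layer].T
                if masks[layer - 1] is not None:
                    delta *= masks[layer - 1]
                delta *= _activate_grad(acts[layer], self.spec.activation)
        return grads_w[::-1], grads_b[::-1]

    # -- training ----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        class_weight: np.ndarray | None = None,
    ) -> "MLPSoftmax":
        """Train with Adam and early stopping; restores the best-validation
        weights.  `class_weight` is a length-4 vector (defaults to all 1)."""
        spec = self.spec
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(X) == 0:
            raise ValueError("empty training set")
        if class_weight is None:
            class_weight = np.ones(N_CLASSES)
        class_weight = np.asarray(class_weight, dtype=float)

        rng = np.random.default_rng(self.seed + 1)
        dropout_rng = np.random.default_rng(self.seed + 2)
        train_idx, val_idx = _stratified_validation_split(
            y, spec.val_fraction, rng
        )
        Xt, yt = X[train_idx], y[train_idx]
        Xv, yv = X[val_idx], y[val_idx]

        m = [np.zeros_like(w) for w in self.weights + self.biases]
        v = [np.zeros_like(w) for w in self.weights + self.biases]
        t = 0
        best_val = np.inf
        best_state = None
        stale = 0
        self.history_: list[dict] = []

        for epoch in range(spec.max_epochs):
            order = rng.permutation(len(yt))
            for start in range(0, len(yt), spec.batch_size):
                batch = order[start:start + spec.batch_size]
                probs, acts, masks = self._forward(Xt[batch], dropout_rng)
                gw, gb = self._backward(
                    Xt[batch], yt[batch], class_weight, probs, acts, masks
                )
                t += 1
                params = self.weights + self.biases
                grads = gw + gb
                lr_t = spec.learning_rate * (
                    np.sqrt(1 - spec.beta2**t) / (1 - spec.beta1**t)
                )
                for i, (p, g) in enumerate(zip(params, grads)):
                    m[i] = spec.beta1 * m[i] + (1 - spec.beta1) * g
                    v[i] = spec.beta2 * v[i] + (1 - spec.beta2) * g * g
                    p -= lr_t * m[i] / (np.sqrt(v[i]) + spec.epsilon)

            train_loss = weighted_cross_entropy(
                self._forward(Xt)[0], yt, class_weight
            )
            if not np.isfinite(train_loss):
                raise RuntimeError(
                    f"training diverged (loss={train_loss}) at epoch {epoch}; "
                    f"spec={spec}"
                )
            record = {"epoch": epoch, "train_loss": train_loss}
            if len(val_idx):
                val_loss = weighted_cross_entropy(
                    self._forward(Xv)[0], yv, class_weight
                )
                record["val_loss"] = val_loss
                if val_loss < best_val - 1e-9:
                    best_val = val_loss
                    best_state = (
                        [w.copy() for w in self.weights],
                        [b.copy() for b in self.biases],
                    )
                    stale = 0
                else:
                    stale += 1
            self.history_.append(record)
            if len(val_idx) and stale > spec.patience:
                break

        if best_state is not None:
            self.weights, self.biases = best_state
        return self


def _stratified_validation_split(y, fraction, rng):
    """Hold back ~`fraction` of each class for early stopping; classes too
    small to spare a sample stay entirely in training."""
    train, val = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n_val = int(np.floor(fraction * len(idx)))
        if len(idx) - n_val < 1:
            n_val = 0
        val.extend(idx[:n_val])
        train.extend(idx[n_val:])
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(val, dtype=int))
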