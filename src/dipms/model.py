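"""Coelution classifier: a small feed-forward neural network.

The network maps a pair's 2n coelution feature vector to the probability that
the two proteins coelute as interaction partners. Architecture: input (144
features) -> three hidden layers of 72 ReLU units with 30% dropout -> one
sigmoid output. Training uses Adam (learning rate 0.001), binary
cross-entropy with label smoothing 0.1, an 80/20 train/test split with the
training portion further split 70/30 into train/validation, up to 256 epochs
at batch size 64, and early stopping (patience 10) restoring the weights with
the lowest validation loss.

The implementation is plain numpy: forward/backward passes, inverted dropout
and the Adam update are written out explicitly, which keeps training fully
deterministic under a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ModelConfig",
    "CoelutionClassifier",
    "build_model",
    "make_labels",
    "train_model",
    "predict_pairs",
]


@dataclass
class ModelConfig:
    n_features: int = 144
    hidden_layers: int = 3
    hidden_units: int = 72
    dropout: float = 0.3
    learning_rate: float = 0.001
    label_smoothing: float = 0.1
    epochs: int = 256
    batch_size: int = 64
    patience: int = 10
    test_split: float = 0.2
    val_split_of_train: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        for name in ("test_split", "val_split_of_train"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in (0, 1)")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class CoelutionClassifier:
    """A trained (or yet-untrained) coelution classifier.

    ``weights`` holds one (W, b) tuple per layer; ``training_history`` is a
    list of per-epoch ``(train_loss, val_loss)`` pairs; ``provenance``
    records the corpus identifier and master seed used for training.
    """

    config: ModelConfig
    weights: list[tuple[np.ndarray, np.ndarray]]
    training_history: list[tuple[float, float]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return int(sum(W.size + b.size for W, b in self.weights))

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None = None):
        """Forward pass; with ``rng`` given, applies inverted dropout."""
        cfg = self.config
        activations = [X]
        masks = []
        h = X
        for li, (W, b) in enumerate(self.weights):
            z = h @ W + b
            if li < len(self.weights) - 1:
                h = np.maximum(z, 0.0)
                if rng is not None and cfg.dropout > 0:
                    mask = (rng.random(h.shape) >= cfg.dropout) / (1 - cfg.dropout)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                h = _sigmoid(z)
            activations.append(h)
        return activations, masks

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Coelution probability per row of ``X`` (dropout disabled)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.config.n_features:
            raise ValueError(
                f"feature width {X.shape[1]} != model input {self.config.n_features}"
            )
        activations, _ = self._forward(X)
        return activations[-1][:, 0]

    def save(self, path) -> None:
        arrays = {}
        for i, (W, b) in enumerate(self.weights):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        arrays["history"] = np.asarray(self.training_history, dtype=float)
        import json

        arrays["config_json"] = np.frombuffer(
            json.dumps({"config": asdict(self.config), "provenance": self.provenance}).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "CoelutionClassifier":
        import json

        data = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(data["config_json"]).decode())
        config = ModelConfig(**meta["config"])
        weights = []
        i = 0
        while f"W{i}" in data:
            weights.append((data[f"W{i}"], data[f"b{i}"]))
            i += 1
        history = [tuple(row) for row in data["history"]]
        return cls(config, weights, history, meta.get("provenance", {}))


def build_model(config: ModelConfig | None = None) -> CoelutionClassifier:
    """Construct an untrained classifier with seeded He-initialized weights."""
    config = config or ModelConfig()
    rng = np.random.default_rng(config.seed)
    sizes = (
        [config.n_features]
        + [config.hidden_units] * config.hidden_layers
        + [1]
    )
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append((W, b))
    return CoelutionClassifier(config, weights)


def make_labels(
    pairs: list[tuple[str, str]],
    reference_positives: set,
    correlations: np.ndarray,
    neg_corr_band: tuple[float, float] = (-0.3, 0.3),
    seed: int = 0,
    reference_negatives: set | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Build a balanced labeled set from a reference interaction set.

    Positives are pairs present in ``reference_positives`` (for synthetic
    corpora: planted co-complex membership). Negatives are sampled, seeded,
    from pairs whose global correlation lies inside ``neg_corr_band`` and
    which are absent from the positives; pairs in ``reference_negatives``
    (known non-interactors, e.g. planted contaminant pairs) are eligible
    negatives at any correlation. The two classes are balanced by
    subsampling the larger one. Returns (row indices into ``pairs``, labels).
    """
    lo, hi = neg_corr_band
    ref = {frozenset(p) for p in reference_positives}
    known_neg = {frozenset(p) for p in (reference_negatives or ())}
    pos_idx = [i for i, p in enumerate(pairs) if frozenset(p) in ref]
    neg_pool = [
        i
        for i, p in enumerate(pairs)
        if frozenset(p) not in ref
        and (lo <= correlations[i] <= hi or frozenset(p) in known_neg)
    ]
    rng = np.random.default_rng(seed)
    n = min(len(pos_idx), len(neg_pool))
    if len(neg_pool) < len(pos_idx):
        deficit = len(pos_idx) - len(neg_pool)
        raise ValueError(
            f"too few eligible negatives: need {len(pos_idx)}, have {len(neg_pool)} "
            f"(deficit {deficit})"
        )
    pos_sel = rng.choice(len(pos_idx), size=n, replace=False) if len(pos_idx) > n else np.arange(n)
    # known negatives are scarce and informative: take them first, then fill
    # the remaining quota from the correlation band
    known_idx = [i for i in neg_pool if frozenset(pairs[i]) in known_neg]
    band_idx = [i for i in neg_pool if frozenset(pairs[i]) not in known_neg]
    if len(known_idx) >= n:
        take = rng.choice(len(known_idx), size=n, replace=False)
        neg_take = np.asarray(known_idx)[np.sort(take)]
    else:
        fill = rng.choice(len(band_idx), size=n - len(known_idx), replace=False)
        neg_take = np.concatenate(
            [np.asarray(known_idx, dtype=int), np.asarray(band_idx)[np.sort(fill)]]
        )
    idx = np.concatenate([np.asarray(pos_idx)[np.sort(pos_sel)], neg_take])
    labels = np.concatenate([np.ones(n), np.zeros(len(neg_take))])
    return idx, labels


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig | None = None,
    corpus_id: str = "corpus",
) -> CoelutionClassifier:
    """Train the classifier; returns the model with the best validation loss.

    The 20% test partition is split off first and never touched during
    training; callers can recover it via the index arrays stored in the
    model's provenance.
    """
    config = config or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")
    rng = np.random.default_rng(config.seed)

    perm = rng.permutation(len(y))
    n_test = int(round(config.test_split * len(y)))
    test_idx, work_idx = perm[:n_test], perm[n_test:]
    n_val = int(round(config.val_split_of_train * len(work_idx)))
    val_idx, train_idx = work_idx[:n_val], work_idx[n_val:]

    model = build_model(config)
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]
    ls = config.label_smoothing

    adam_m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in model.weights]
    adam_v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in model.weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best_val = np.inf
    best_weights = [(W.copy(), b.copy()) for W, b in model.weights]
    wait = 0
    history: list[tuple[float, float]] = []

    for _epoch in range(config.epochs):
        order = rng.permutation(len(ytr))
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            xb = Xtr[batch]
            yb = ytr[batch] * (1 - ls) + 0.5 * ls
            activations, masks = model._forward(xb, rng=rng)
            p = activations[-1][:, 0]
            # d(BCE)/dz for the sigmoid output layer
            delta = ((p - yb) / len(yb))[:, None]
            grads = []
            for li in range(len(model.weights) - 1, -1, -1):
                a_prev = activations[li]
                gW = a_prev.T @ delta
                gb = delta.sum(axis=0)
                grads.append((gW, gb))
                if li > 0:
                    W, _ = model.weights[li]
                    delta = delta @ W.T
                    hidden = activations[li]
                    delta = delta * (hidden > 0)
                    if masks[li - 1] is not None:
                        delta = delta * masks[li - 1]
            grads.reverse()
            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            new_weights = []
            for li, ((W, b), (gW, gb)) in enumerate(zip(model.weights, grads)):
                mW, mb = adam_m[li]
                vW, vb = adam_v[li]
                mW = beta1 * mW + (1 - beta1) * gW
                mb = beta1 * mb + (1 - beta1) * gb
                vW = beta2 * vW + (1 - beta2) * gW**2
                vb = beta2 * vb + (1 - beta2) * gb**2
                adam_m[li] = (mW, mb)
                adam_v[li] = (vW, vb)
                new_weights.append(
                    (W - lr_t * mW / (np.sqrt(vW) + eps), b - lr_t * mb / (np.sqrt(vb) + eps))
                )
            model.weights = new_weights

        train_loss = _bce(model.predict(Xtr), ytr * (1 - ls) + 0.5 * ls)
        val_loss = _bce(model.predict(Xval), yval * (1 - ls) + 0.5 * ls)
        history.append((train_loss, val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_weights = [(W.copy(), b.copy()) for W, b in model.weights]
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break

    model.weights = best_weights
    model.training_history = history
    model.provenance = {
        "corpus_id": corpus_id,
        "seed": config.seed,
        "n_samples": int(len(y)),
        "test_idx": test_idx.tolist(),
        "val_idx": val_idx.tolist(),
        "train_idx": train_idx.tolist(),
        "best_val_loss": float(best_val),
    }
    return model


def predict_pairs(model: CoelutionClassifier, feature_vectors: np.ndarray) -> np.ndarray:
    """Coelution probabilities for a batch of pair feature vectors."""
    return model.predict(feature_vectors)
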