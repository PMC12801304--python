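"""Multi-scale separable-convolution classifier for fused peptide embeddings.

The input is a 1 x L x D map (L = 20 residue positions, D embedding
channels).  Parallel branches, one per window size w, each apply a
separable convolution: a depthwise kernel spanning w positions per input
channel, then a pointwise 1x1 convolution mixing the D channels into
``filters`` output channels (one bias per output channel, no depthwise
bias).  Valid convolution leaves L - w + 1 positions, max-pooled over the
full positional extent so each branch contributes a position-invariant
``filters``-vector.  Branch outputs are concatenated, passed through
dropout, a hidden dense layer and a softmax output layer.

Training minimises categorical cross-entropy plus an L2 penalty on the
dense-layer weights with the Adam update rule.  Everything is implemented
directly on NumPy arrays, so a trained model is a plain dict of arrays and
parameter accounting is exact.

Defaults follow the reference configuration: windows {2,4,6,8} for human
(the window-8 branch is dropped for mouse), 1024 filters, 500 hidden
units, dropout 0.7, L2 1e-3, Adam at 1e-3, batch size 256, 20 epochs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from epifuse.io_formats import ValidationError
from epifuse.rag_fusion import FusedEmbedding

_ADAM_BETA1 = 0.9
_ADAM_BETA2 = 0.999
_ADAM_EPS = 1e-8


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int) -> None:
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class MSCNNConfig:
    """Architecture and training settings of the classifier."""

    window_sizes: tuple[int, ...] = (2, 4, 6, 8)
    filters: int = 1024
    hidden_units: int = 500
    classes: int = 2
    dropout: float = 0.7
    l2_penalty: float = 1e-3
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int = 20
    input_len: int = 20
    input_dim: int = 1280
    seed: int = 0
    l2_include_conv: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "window_sizes", tuple(int(w) for w in self.window_sizes))
        if not self.window_sizes:
            raise ValueError("need at least one window size")
        if any(w < 1 or w >= self.input_len for w in self.window_sizes):
            raise ValueError(
                f"window sizes {self.window_sizes} must lie in [1, input_len={self.input_len})"
            )
        if self.filters < 1 or self.hidden_units < 1 or self.classes < 2:
            raise ValueError("filters, hidden_units >= 1 and classes >= 2 required")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs >= 0 and batch_size >= 1 required")

    @classmethod
    def human_default(cls, **overrides) -> "MSCNNConfig":
        return cls(**overrides)

    @classmethod
    def mouse_default(cls, **overrides) -> "MSCNNConfig":
        overrides.setdefault("window_sizes", (2, 4, 6))
        return cls(**overrides)


def count_parameters(config: MSCNNConfig) -> int:
    """Closed-form trainable-parameter count of the architecture.

    Per window w: w * D depthwise weights, D * filters pointwise weights and
    ``filters`` biases.  Dense block: concat -> hidden (weights + biases),
    hidden -> classes (weights + biases).
    """
    D, F, H, C = config.input_dim, config.filters, config.hidden_units, config.classes
    conv = sum(w * D + D * F + F for w in config.window_sizes)
    dense = F * len(config.window_sizes) * H + H
    out = H * C + C
    return conv + dense + out


@dataclass
class PredictionSet:
    """Per-peptide inducing-class probabilities and thresholded labels."""

    epitope_ids: list[str]
    scores: np.ndarray
    labels_pred: np.ndarray
    threshold: float = 0.5


def _as_array(
    embeddings: Sequence[FusedEmbedding], config: MSCNNConfig
) -> tuple[np.ndarray, list[str]]:
    """Stack fused (or raw) embeddings into an (N, L, D) array."""
    if not embeddings:
        raise ValueError("empty embedding list")
    ids = [getattr(e, "epitope_id", str(i)) for i, e in enumerate(embeddings)]
    values = np.stack([np.asarray(e.values, dtype=np.float64) for e in embeddings])
    if values.shape[1] != config.input_len or values.shape[2] != config.input_dim:
        raise ValueError(
            f"embeddings of shape {values.shape[1:]} do not match config "
            f"({config.input_len}, {config.input_dim})"
        )
    return values, ids


class MSCNN:
    """The classifier: parameter arrays plus forward/backward passes."""

    def __init__(self, config: MSCNNConfig) -> None:
        self.config = config
        self.training_history: list[dict] = []
        rng = np.random.default_rng([config.seed, 11])
        D, F, H, C = config.input_dim, config.filters, config.hidden_units, config.classes
        B = len(config.window_sizes)
        self.params: dict[str, np.ndarray] = {}
        for w in config.window_sizes:
            self.params[f"dw{w}"] = rng.normal(0.0, np.sqrt(2.0 / (w * D)), size=(w, D))
            self.params[f"pw{w}"] = rng.normal(0.0, np.sqrt(2.0 / D), size=(D, F))
            self.params[f"pb{w}"] = np.zeros(F)
        self.params["dense_W"] = rng.normal(0.0, np.sqrt(2.0 / (F * B)), size=(F * B, H))
        self.params["dense_b"] = np.zeros(H)
        self.params["out_W"] = rng.normal(0.0, np.sqrt(2.0 / H), size=(H, C))
        self.params["out_b"] = np.zeros(C)

    # -- accounting --------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        """Trainable-parameter count as reported by the instantiated arrays."""
        return int(sum(p.size for p in self.params.values()))

    # -- forward -----------------------------------------------------------

    def separable_forward(self, x: np.ndarray, w: int) -> np.ndarray:
        """One branch's linear separable convolution: depthwise then pointwise.

        ``x`` is (N, L, D); the result is (N, L - w + 1, filters) before the
        ReLU nonlinearity.
        """
        K, P, b = self.params[f"dw{w}"], self.params[f"pw{w}"], self.params[f"pb{w}"]
        n_pos = x.shape[1] - w + 1
        depth = np.zeros((x.shape[0], n_pos, x.shape[2]))
        for i in range(w):
            depth += x[:, i : i + n_pos, :] * K[i]
        return depth @ P + b

    def _forward(self, x: np.ndarray, train: bool = False, rng=None):
        cfg = self.config
        caches = []
        pooled = []
        for w in cfg.window_sizes:
            K = self.params[f"dw{w}"]
            n_pos = x.shape[1] - w + 1
            depth = np.zeros((x.shape[0], n_pos, x.shape[2]))
            for i in range(w):
                depth += x[:, i : i + n_pos, :] * K[i]
            z = depth @ self.params[f"pw{w}"] + self.params[f"pb{w}"]
            a = np.maximum(z, 0.0)
            arg = a.argmax(axis=1)
            pooled.append(np.take_along_axis(a, arg[:, None, :], axis=1)[:, 0, :])
            caches.append({"w": w, "depth": depth, "z": z, "arg": arg})
        concat = np.concatenate(pooled, axis=1)
        if train and cfg.dropout > 0.0:
            mask = rng.random(concat.shape) >= cfg.dropout
            dropped = concat * mask / (1.0 - cfg.dropout)
        else:
            mask = None
            dropped = concat
        h_pre = dropped @ self.params["dense_W"] + self.params["dense_b"]
        h = np.maximum(h_pre, 0.0)
        logits = h @ self.params["out_W"] + self.params["out_b"]
        shifted = logits - logits.max(axis=1, keepdims=True)
        log_probs = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        cache = {
            "x": x,
            "branches": caches,
            "concat": concat,
            "mask": mask,
            "dropped": dropped,
            "h_pre": h_pre,
            "h": h,
            "log_probs": log_probs,
        }
        return np.exp(log_probs), cache

    def predict_proba(self, x: np.ndarray, batch_size: int | None = None) -> np.ndarray:
        batch_size = batch_size or self.config.batch_size
        out = []
        for start in range(0, x.shape[0], batch_size):
            probs, _ = self._forward(x[start : start + batch_size])
            out.append(probs)
        return np.concatenate(out, axis=0)

    # -- backward ----------------------------------------------------------

    def _backward(self, cache: dict, y_onehot: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        n = y_onehot.shape[0]
        grads: dict[str, np.ndarray] = {}
        probs = np.exp(cache["log_probs"])
        dlogits = (probs - y_onehot) / n
        grads["out_W"] = cache["h"].T @ dlogits
        grads["out_b"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["out_W"].T
        dh[cache["h_pre"] <= 0.0] = 0.0
        grads["dense_W"] = cache["dropped"].T @ dh
        grads["dense_b"] = dh.sum(axis=0)
        dconcat = dh @ self.params["dense_W"].T
        if cache["mask"] is not None:
            dconcat = dconcat * cache["mask"] / (1.0 - cfg.dropout)
        if cfg.l2_penalty > 0.0:
            grads["dense_W"] += 2.0 * cfg.l2_penalty * self.params["dense_W"]
            grads["out_W"] += 2.0 * cfg.l2_penalty * self.params["out_W"]
        offset = 0
        x = cache["x"]
        for branch in cache["branches"]:
            w = branch["w"]
            F = cfg.filters
            dpool = dconcat[:, offset : offset + F]
            offset += F
            da = np.zeros_like(branch["z"])
            np.put_along_axis(da, branch["arg"][:, None, :], dpool[:, None, :], axis=1)
            dz = da * (branch["z"] > 0.0)
            depth = branch["depth"]
            grads[f"pw{w}"] = np.tensordot(depth, dz, axes=([0, 1], [0, 1]))
            grads[f"pb{w}"] = dz.sum(axis=(0, 1))
            ddepth = dz @ self.params[f"pw{w}"].T
            n_pos = depth.shape[1]
            dK = np.empty_like(self.params[f"dw{w}"])
            for i in range(w):
                dK[i] = (x[:, i : i + n_pos, :] * ddepth).sum(axis=(0, 1))
            grads[f"dw{w}"] = dK
            if cfg.l2_penalty > 0.0 and cfg.l2_include_conv:
                grads[f"dw{w}"] += 2.0 * cfg.l2_penalty * self.params[f"dw{w}"]
                grads[f"pw{w}"] += 2.0 * cfg.l2_penalty * self.params[f"pw{w}"]
        return grads

    def loss(self, log_probs: np.ndarray, y_onehot: np.ndarray) -> float:
        data_loss = float(-(y_onehot * log_probs).sum(axis=1).mean())
        reg = self.config.l2_penalty * (
            np.sum(self.params["dense_W"] ** 2) + np.sum(self.params["out_W"] ** 2)
        )
        if self.config.l2_include_conv:
            for w in self.config.window_sizes:
                reg += self.config.l2_penalty * (
                    np.sum(self.params[f"dw{w}"] ** 2) + np.sum(self.params[f"pw{w}"] ** 2)
                )
        return data_loss + float(reg)


def build_model(config: MSCNNConfig) -> MSCNN:
    """Instantiate an untrained classifier from a config."""
    return MSCNN(config)


def train(
    model: MSCNN,
    fused_train: Sequence[FusedEmbedding],
    labels: Sequence[int],
    config: MSCNNConfig | None = None,
) -> MSCNN:
    """Fit the classifier with Adam on categorical cross-entropy (in place).

    Reproducible for a fixed config seed: initialisation, shuffling and
    dropout masks all derive from it.  Zero epochs returns the model
    untouched with an empty history.
    """
    cfg = config or model.config
    x, _ = _as_array(fused_train, cfg)
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != x.shape[0]:
        raise ValueError("one label per embedding required")
    present = np.unique(y)
    if present.size < 2:
        raise ValidationError("training data contains a single class")
    if not np.all(np.isin(present, np.arange(cfg.classes))):
        raise ValidationError(f"labels outside 0..{cfg.classes - 1}")
    y_onehot = np.eye(cfg.classes)[y]

    rng = np.random.default_rng([cfg.seed, 13])
    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    step = 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(x.shape[0])
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, x.shape[0], cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            probs, cache = model._forward(x[idx], train=True, rng=rng)
            batch_loss = model.loss(cache["log_probs"], y_onehot[idx])
            if not np.isfinite(batch_loss):
                raise DivergenceError(epoch)
            epoch_loss += batch_loss * idx.size
            epoch_correct += int((probs.argmax(axis=1) == y[idx]).sum())
            grads = model._backward(cache, y_onehot[idx])
            step += 1
            for key, grad in grads.items():
                adam_m[key] = _ADAM_BETA1 * adam_m[key] + (1 - _ADAM_BETA1) * grad
                adam_v[key] = _ADAM_BETA2 * adam_v[key] + (1 - _ADAM_BETA2) * grad**2
                m_hat = adam_m[key] / (1 - _ADAM_BETA1**step)
                v_hat = adam_v[key] / (1 - _ADAM_BETA2**step)
                model.params[key] -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + _ADAM_EPS)
        model.training_history.append(
            {
                "epoch": epoch,
                "loss": epoch_loss / x.shape[0],
                "accuracy": epoch_correct / x.shape[0],
            }
        )
    return model


def predict(
    model: MSCNN,
    fused: Sequence[FusedEmbedding],
    threshold: float = 0.5,
) -> PredictionSet:
    """Score peptides; label 1 (inducing) exactly when score >= threshold."""
    x, ids = _as_array(fused, model.config)
    probs = model.predict_proba(x)
    scores = probs[:, 1]
    return PredictionSet(
        epitope_ids=ids,
        scores=scores,
        labels_pred=(scores >= threshold).astype(int),
        threshold=threshold,
    )


def stratified_folds(labels: Sequence[int], folds: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment; fold sizes differ by at most one."""
    y = np.asarray(labels, dtype=int)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if y.size < folds:
        raise ValueError("dataset smaller than number of folds")
    rng = np.random.default_rng([seed, 17])
    assignment = np.empty(y.size, dtype=int)
    counter = 0
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            assignment[j] = (counter + i) % folds
        counter += idx.size
    return assignment


def cross_validate(
    embeddings: Sequence,
    labels: Sequence[int],
    config: MSCNNConfig,
    folds: int = 5,
    seed: int = 0,
    kg=None,
    rel_map=None,
    k: int = 5,
    query_fraction: float = 0.9,
) -> list:
    """Stratified k-fold evaluation with fold-internal retrieval fusion.

    When ``kg`` and ``rel_map`` are given, each fold's queries (train and
    validation alike) are fused against the training-fold embeddings only,
    so a validation peptide is never part of the retrieval database it
    queries (self-exclusion by id guards the remaining overlap).
    """
    from epifuse.metrics import compute_metrics, confusion
    from epifuse.rag_fusion import enrich_dataset

    y = np.asarray(labels, dtype=int)
    assignment = stratified_folds(y, folds, seed)
    reports = []
    for fold in range(folds):
        val_mask = assignment == fold
        train_idx = np.where(~val_mask)[0]
        val_idx = np.where(val_mask)[0]
        if np.unique(y[train_idx]).size < 2 or np.unique(y[val_idx]).size < 2:
            raise ValidationError(f"fold {fold} lost a class; reduce folds")
        train_emb = [embeddings[i] for i in train_idx]
        val_emb = [embeddings[i] for i in val_idx]
        if kg is not None and rel_map is not None:
            fused_train = enrich_dataset(
                train_emb, train_emb, kg, rel_map, k=k, query_fraction=query_fraction
            )
            fused_val = enrich_dataset(
                val_emb, train_emb, kg, rel_map, k=k, query_fraction=query_fraction
            )
        else:
            fused_train, fused_val = train_emb, val_emb
        fold_config = dataclasses.replace(config, seed=config.seed + fold)
        model = train(MSCNN(fold_config), fused_train, y[train_idx])
        preds = predict(model, fused_val)
        reports.append(
            compute_metrics(
                confusion(y[val_idx], preds.labels_pred),
                scores=preds.scores,
                labels_true=y[val_idx],
            )
        )
    return reports


def summarize_reports(reports: Sequence) -> dict[str, tuple[float, float]]:
    """Mean and standard deviation of each metric across folds."""
    names = ("sensitivity", "specificity", "accuracy", "mcc", "precision", "f1", "auc")
    out = {}
    for name in names:
        values = np.array([getattr(r, name) for r in reports], dtype=float)
        out[name] = (float(values.mean()), float(values.std()))
    return out


def save_model(model: MSCNN, path) -> None:
    """Single-file checkpoint: weights plus config and history as JSON."""
    path = Path(path)
    meta = {
        "config": dataclasses.asdict(model.config),
        "history": model.training_history,
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **model.params)


def load_model(path) -> MSCNN:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        cfg_dict = meta["config"]
        cfg_dict["window_sizes"] = tuple(cfg_dict["window_sizes"])
        config = MSCNNConfig(**cfg_dict)
        model = MSCNN(config)
        for key in model.params:
            model.params[key] = data[key]
        model.training_history = meta["history"]
    return model
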