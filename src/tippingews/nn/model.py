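"""Length-invariant LSTM-FCN classifier for transition detection.

The network runs two branches over a raw univariate series of any length T:

* FCN branch — three stacked blocks of same-padded 1-D convolution, batch
  normalisation and ReLU (``Z = ReLU(BN(W * X))``), followed by global
  average pooling over time, giving a D-vector where D is the last block's
  filter count;
* LSTM branch — the series fed stepwise as scalars to an LSTM whose final
  hidden state is kept (initial cell and hidden states zero).

The two branch outputs are concatenated and passed through two fully
connected layers ending in a 3-way softmax over the classes
catastrophic (C.T.), smooth (S.T.) and no transition (N.T.).  Global
pooling and the recurrent final state make the parameter count and the
forward pass independent of T, so no padding or resampling is ever needed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ..models import CT, NT, ST
from .layers import (
    Adam,
    BatchNorm1D,
    Conv1D,
    Dense,
    GlobalAvgPool,
    LSTMLast,
    Param,
    ReLU,
    softmax,
)

__all__ = [
    "EWSNetConfig",
    "TrainingConfig",
    "LSTMFCNClassifier",
    "CheckpointError",
    "train_ewsnet",
    "save_model",
    "load_model",
    "CLASS_ORDER",
]

#: output order of the probability vector
CLASS_ORDER = (CT, ST, NT)


class CheckpointError(RuntimeError):
    pass


@dataclass(frozen=True)
class EWSNetConfig:
    """Architecture hyperparameters (three conv blocks are fixed by design)."""

    conv_filters: tuple[int, int, int] = (128, 256, 128)
    conv_kernels: tuple[int, int, int] = (8, 5, 3)
    lstm_units: int = 128
    fc_sizes: tuple[int, int] = (128, 3)
    n_classes: int = 3

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 3 or len(self.conv_kernels) != 3:
            raise ValueError("exactly 3 convolutional blocks are required")
        if self.lstm_units <= 0:
            raise ValueError("lstm_units must be > 0")
        if self.fc_sizes[-1] != self.n_classes or self.n_classes != 3:
            raise ValueError("the final layer must have width 3 (the class count)")

    @property
    def min_length(self) -> int:
        return max(self.conv_kernels)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings; convergence is typically reached by ~25 epochs."""

    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    lr_schedule: str = "cosine"  # "cosine" decay to 0 or "constant"
    grad_clip: float = 1.0  # global-norm clip; 0 disables
    n_trials: int = 25
    validation_fraction: float = 0.2
    normalize_input: bool = False  # optional z-score ablation switch
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.n_trials < 1:
            raise ValueError("epochs and n_trials must be >= 1")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must lie in [0, 1)")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")


class LSTMFCNClassifier:
    """The two-branch deep classifier.  Build with a config and a seed."""

    def __init__(self, config: EWSNetConfig | None = None, seed: int | None = None,
                 dtype=np.float32):
        self.config = config or EWSNetConfig()
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        cf, ck = self.config.conv_filters, self.config.conv_kernels
        self.blocks = []
        c_in = 1
        for f, k in zip(cf, ck):
            self.blocks.append(
                (Conv1D(c_in, f, k, rng, dtype), BatchNorm1D(f, dtype=dtype), ReLU())
            )
            c_in = f
        self.gap = GlobalAvgPool()
        self.lstm = LSTMLast(self.config.lstm_units, rng, dtype)
        d_concat = cf[-1] + self.config.lstm_units
        self.fc1 = Dense(d_concat, self.config.fc_sizes[0], rng, dtype)
        self.fc1_act = ReLU()
        self.fc2 = Dense(self.config.fc_sizes[0], self.config.fc_sizes[1], rng, dtype)
        self._norm: tuple[float, float] | None = None  # optional input z-score

    @property
    def params(self) -> list[Param]:
        out: list[Param] = []
        for conv, bn, _ in self.blocks:
            out += conv.params + bn.params
        out += self.lstm.params + self.fc1.params + self.fc2.params
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params)

    # ------------------------------------------------------------------ core

    def forward(self, x: np.ndarray, train: bool = True,
                lengths: np.ndarray | None = None) -> np.ndarray:
        """x: (N, T) batch -> (N, 3) probabilities.

        Ragged batches are passed right-padded with ``lengths`` giving each
        series' true length; padded positions are masked throughout.
        """
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 2:
            raise ValueError("expected a (batch, time) array")
        min_len = x.shape[1] if lengths is None else int(np.min(lengths))
        if min_len < self.config.min_length:
            raise ValueError(
                f"series length {min_len} is below the minimum "
                f"{self.config.min_length} (largest convolution kernel)"
            )
        if self._norm is not None:
            mu, sd = self._norm
            x = (x - mu) / sd
            if lengths is not None:
                x = x * (np.arange(x.shape[1]) < np.asarray(lengths)[:, None])
        mask = None
        if lengths is not None:
            lengths = np.asarray(lengths)
            mask = (np.arange(x.shape[1]) < lengths[:, None]).astype(self.dtype)
        z = x[:, None, :]
        for conv, bn, act in self.blocks:
            z = act.forward(bn.forward(conv.forward(z, train, mask), train, mask), train)
        pooled = self.gap.forward(z, train, mask)
        h = self.lstm.forward(x, train, lengths)
        cat = np.concatenate([pooled, h], axis=1)
        f1 = self.fc1_act.forward(self.fc1.forward(cat, train), train)
        logits = self.fc2.forward(f1, train)
        self._last_probs = softmax(logits)
        return self._last_probs

    def backward_cross_entropy(self, onehot: np.ndarray) -> float:
        """Backprop the mean cross-entropy of the last forward pass."""
        probs = self._last_probs
        n = probs.shape[0]
        loss = float(-np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1)))
        dlogits = (probs - onehot) / n
        g = self.fc2.backward(dlogits)
        g = self.fc1.backward(self.fc1_act.backward(g))
        d = self.config.conv_filters[-1]
        g_pool, g_h = g[:, :d], g[:, d:]
        self.lstm.backward(g_h)
        gz = self.gap.backward(g_pool)
        for conv, bn, act in reversed(self.blocks):
            gz = conv.backward(bn.backward(act.backward(gz)))
        return loss

    # ------------------------------------------------------------- inference

    def predict_proba(self, series) -> np.ndarray:
        """Probabilities for one 1-D series or a list of (ragged) series."""
        if isinstance(series, np.ndarray) and series.ndim == 1:
            return self.forward(series[None, :], train=False)[0]
        out = np.empty((len(series), 3))
        by_len: dict[int, list[int]] = {}
        for i, s in enumerate(series):
            by_len.setdefault(len(s), []).append(i)
        for length, idx in by_len.items():
            batch = np.stack([np.asarray(series[i], dtype=float) for i in idx])
            out[idx] = self.forward(batch, train=False)
        return out

    def predict(self, series) -> tuple[str, np.ndarray] | list[str]:
        """Argmax label (with probabilities for a single series)."""
        probs = self.predict_proba(series)
        if probs.ndim == 1:
            return CLASS_ORDER[int(np.argmax(probs))], probs
        return [CLASS_ORDER[i] for i in np.argmax(probs, axis=1)]


def _label_codes(labels) -> np.ndarray:
    lut = {c: i for i, c in enumerate(CLASS_ORDER)}
    return np.asarray([lut[l] for l in labels])


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    """Shuffled mini-batch index lists covering 0..n-1."""
    idx = rng.permutation(n)
    return [idx[i : i + batch_size] for i in range(0, n, batch_size)]


def _pad_stack(values: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad ragged series with zeros; returns (batch, lengths)."""
    lengths = np.array([v.size for v in values])
    out = np.zeros((len(values), int(lengths.max())))
    for i, v in enumerate(values):
        out[i, : v.size] = v
    return out, lengths


def train_ewsnet(
    model: LSTMFCNClassifier,
    train_series: list,
    train_labels: list,
    tc: TrainingConfig | None = None,
) -> dict:
    """Train with Adam on 3-class cross-entropy; returns per-epoch history.

    ``train_series`` may be ragged (mixed lengths); mini-batches mix classes
    and lengths freely, right-padding shorter members under an explicit
    validity mask, so the network itself stays length-invariant and no
    information is discarded.  A stratified validation split of
    ``validation_fraction`` is carved out of the training data; raw series
    go in unmodified unless ``normalize_input`` is set.
    """
    tc = tc or TrainingConfig()
    rng = np.random.default_rng(tc.seed)
    values = [np.asarray(s, dtype=float) for s in train_series]
    y = _label_codes(train_labels)
    if tc.normalize_input:
        flat = np.concatenate(values)
        model._norm = (float(flat.mean()), float(flat.std() + 1e-12))

    # stratified validation split
    val_idx: list[int] = []
    for c in range(3):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        val_idx += list(idx[: int(round(idx.size * tc.validation_fraction))])
    val_mask = np.zeros(y.size, dtype=bool)
    val_mask[val_idx] = True
    tr_idx = np.flatnonzero(~val_mask)
    va_idx = np.flatnonzero(val_mask)

    opt = Adam([p for p in model.params], lr=tc.learning_rate)
    onehot = np.eye(3)
    history = {"loss": [], "train_accuracy": [], "val_accuracy": []}

    for _epoch in range(tc.epochs):
        if tc.lr_schedule == "cosine":
            opt.lr = tc.learning_rate * 0.5 * (1 + np.cos(np.pi * _epoch / tc.epochs))
        losses = []
        hits = 0
        for batch in _batches(tr_idx.size, tc.batch_size, rng):
            bidx = tr_idx[batch]
            xb, lens = _pad_stack([values[i] for i in bidx])
            yb = y[bidx]
            opt.zero_grad()
            probs = model.forward(xb, train=True, lengths=lens)
            loss = model.backward_cross_entropy(onehot[yb])
            if not np.isfinite(loss):
                raise RuntimeError(
                    "training loss diverged (NaN); try a lower learning rate"
                )
            if tc.grad_clip > 0:
                gnorm = np.sqrt(sum(float(np.sum(p.grad**2)) for p in model.params))
                if gnorm > tc.grad_clip:
                    scale = tc.grad_clip / gnorm
                    for p in model.params:
                        p.grad *= scale
            opt.step()
            losses.append(loss)
            hits += int(np.sum(np.argmax(probs, axis=1) == yb))
        history["loss"].append(float(np.mean(losses)))
        history["train_accuracy"].append(hits / tr_idx.size)
        if va_idx.size:
            vp = model.predict_proba([values[i] for i in va_idx])
            val_acc = float(np.mean(np.argmax(vp, axis=1) == y[va_idx]))
        else:
            val_acc = float("nan")
        history["val_accuracy"].append(val_acc)
    return history


def evaluate(model: LSTMFCNClassifier, series: list, labels: list) -> float:
    """Plain accuracy of the model on (possibly ragged) labelled series."""
    probs = model.predict_proba([np.asarray(s, dtype=float) for s in series])
    return float(np.mean(np.argmax(probs, axis=1) == _label_codes(labels)))


# ------------------------------------------------------------------ storage


def save_model(model: LSTMFCNClassifier, path: str | Path) -> None:
    """Write config (JSON) and weights (npz) into a checkpoint directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    cfg["_norm"] = model._norm
    (path / "config.json").write_text(json.dumps(cfg, indent=2))
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params)}
    for bi, (_, bn, _a) in enumerate(model.blocks):
        arrays[f"bn{bi}_mean"] = bn.running_mean
        arrays[f"bn{bi}_var"] = bn.running_var
    np.savez(path / "weights.npz", **arrays)


def load_model(
    path: str | Path, config: EWSNetConfig | None = None
) -> LSTMFCNClassifier:
    """Rebuild a checkpointed model; identical predictions are guaranteed."""
    path = Path(path)
    try:
        cfg = json.loads((path / "config.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise CheckpointError(f"cannot read checkpoint config: {exc}") from exc
    norm = cfg.pop("_norm", None)
    for key in ("conv_filters", "conv_kernels", "fc_sizes"):
        cfg[key] = tuple(cfg[key])
    stored = EWSNetConfig(**cfg)
    if config is not None and config != stored:
        raise CheckpointError(
            f"checkpoint was built with {stored}, requested {config}"
        )
    model = LSTMFCNClassifier(stored, seed=0)
    model._norm = tuple(norm) if norm is not None else None
    try:
        with np.load(path / "weights.npz") as data:
            for i, p in enumerate(model.params):
                arr = data[f"p{i}"]
                if arr.shape != p.value.shape:
                    raise CheckpointError("weight shape mismatch in checkpoint")
                p.value[...] = arr
            for bi, (_, bn, _a) in enumerate(model.blocks):
                bn.running_mean[...] = data[f"bn{bi}_mean"]
                bn.running_var[...] = data[f"bn{bi}_var"]
    except (OSError, ValueError, KeyError) as exc:
        raise CheckpointError(f"corrupt checkpoint weights: {exc}") from exc
    return model
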