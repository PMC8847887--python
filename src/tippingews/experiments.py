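"""Evaluation protocols: trial averaging, confusion analysis, robustness.

Every experiment is a deterministic function of a base seed; per-trial seeds
are spawned from it so trials are independent but reproducible.  Reported
uncertainty is a normal-approximation 95% confidence half-width over trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence
import warnings

import numpy as np

from .models import CT, NT, ST, LABELS, ModelSpec, model_library
from .nn.model import CLASS_ORDER, LSTMFCNClassifier, evaluate, train_ewsnet, TrainingConfig, EWSNetConfig
from .simulate import LabelledDataset, LabelledSeries, build_dataset, subsample_series

__all__ = [
    "TrialReport",
    "run_trials",
    "confusion_matrix",
    "imperfect_sampling_curve",
    "leave_one_model_out",
    "truncation_experiment",
    "deep_benchmark",
]

Z95 = 1.959963984540054

# ---------------------------------------------------------------------------
# Reduced-scale benchmark protocol.  The full study conditions (hundreds of
# series per class, the wide LSTM-FCN, 25 training epochs over tens of
# thousands of gradient steps) are scaled to a desktop-size problem: fewer
# series per class, a proportionally narrower network, and enough epochs to
# reach the same number of parameter updates.  These constants are the
# package's single source of truth for the bundled reproduction script.

DESK_NET = EWSNetConfig(
    conv_filters=(32, 64, 32), conv_kernels=(8, 5, 3), lstm_units=64, fc_sizes=(64, 3)
)
DESK_TRAIN = TrainingConfig(
    epochs=60, batch_size=16, learning_rate=5e-4, validation_fraction=0.1
)
DESK_N_PER_CLASS = 50
DESK_N_TRIALS = 5


@dataclass
class TrialReport:
    """Per-trial metric values with their mean and 95% CI half-width."""

    values: np.ndarray
    extras: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("a trial report needs at least one trial")

    @property
    def n_trials(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def ci_half_width(self) -> float:
        if self.values.size < 2:
            return 0.0
        sem = self.values.std(ddof=1) / np.sqrt(self.values.size)
        return float(Z95 * sem)


def run_trials(
    experiment_factory: Callable[[int], float | tuple[float, object]],
    n_trials: int = 25,
    base_seed: int | None = None,
) -> TrialReport:
    """Run a seeded experiment ``n_trials`` times and aggregate.

    The factory receives an independent integer seed per trial and returns a
    scalar metric, optionally paired with an arbitrary extra record.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(n_trials) % (2**31 - 1)
    values, extras = [], []
    for t, s in enumerate(seeds):
        try:
            out = experiment_factory(int(s))
        except Exception as exc:
            raise RuntimeError(f"trial {t} (seed {int(s)}) failed: {exc}") from exc
        if isinstance(out, tuple):
            metric, extra = out
            extras.append(extra)
        else:
            metric = out
        values.append(float(metric))
    return TrialReport(values=np.asarray(values), extras=extras)


def confusion_matrix(true_labels, predicted_labels) -> np.ndarray:
    """Row-normalised 3x3 confusion matrix in C.T., S.T., N.T. order.

    Entry (i, j) is the fraction of true-class-i series predicted as class j;
    rows of absent classes are NaN.
    """
    yt = list(true_labels)
    yp = list(predicted_labels)
    if not yt or len(yt) != len(yp):
        raise ValueError("label sequences must be non-empty and equal-length")
    lut = {c: i for i, c in enumerate(CLASS_ORDER)}
    counts = np.zeros((3, 3))
    for t, p in zip(yt, yp):
        counts[lut[t], lut[p]] += 1
    rows = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(rows > 0, counts / np.where(rows > 0, rows, 1.0), np.nan)


def imperfect_sampling_curve(
    model: LSTMFCNClassifier,
    test_series: Sequence[LabelledSeries],
    fractions: Sequence[float],
    seed: int | None = None,
) -> list[dict]:
    """Accuracy after randomly retaining a fraction of each test series."""
    if len(list(fractions)) == 0:
        raise ValueError("fraction grid must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        sub = [subsample_series(s, frac, rng) for s in test_series]
        acc = evaluate(model, [s.values for s in sub], [s.label for s in sub])
        rows.append({"fraction": float(frac), "accuracy": acc})
    return rows


def truncation_experiment(
    model: LSTMFCNClassifier,
    transition_series: Sequence[LabelledSeries],
    margins: Sequence[int],
) -> list[dict]:
    """Accuracy on prefixes ending ``margin`` points before the crossing.

    Series are expected to be already truncated at the crossing (margin 0);
    larger margins cut further back.  Series too short for a margin are
    skipped with a warning.
    """
    margins = list(margins)
    if not margins:
        raise ValueError("margin grid must be non-empty")
    min_len = model.config.min_length
    rows = []
    for margin in margins:
        vals, labels = [], []
        for s in transition_series:
            end = len(s) - margin
            if end < min_len:
                warnings.warn(
                    f"margin {margin} leaves series of model {s.model_name} too short; skipped",
                    stacklevel=2,
                )
                continue
            vals.append(s.values[:end])
            labels.append(s.label)
        acc = evaluate(model, vals, labels) if vals else float("nan")
        rows.append({"margin": int(margin), "accuracy": acc, "n": len(vals)})
    return rows


def deep_benchmark(
    variant: str,
    n_per_class: int,
    net_config: EWSNetConfig | None = None,
    train_config: TrainingConfig | None = None,
    seed: int | None = None,
    subsample_fraction: float | None = None,
    library: list[ModelSpec] | None = None,
) -> dict:
    """One full train/evaluate cycle of the deep classifier on a fresh dataset.

    Returns test accuracy, the row-normalised confusion matrix, the training
    history, the trained model and the dataset (for follow-up experiments).
    """
    import dataclasses

    ds = build_dataset(variant, n_per_class, seed=seed, library=library)
    tc = train_config or TrainingConfig()
    tc = dataclasses.replace(tc, seed=seed if tc.seed is None else tc.seed)
    model = LSTMFCNClassifier(net_config, seed=tc.seed)
    train = ds.train
    history = train_ewsnet(model, [s.values for s in train], [s.label for s in train], tc)
    test = ds.test
    if subsample_fraction is not None:
        rng = np.random.default_rng(tc.seed)
        test = [subsample_series(s, subsample_fraction, rng) for s in test]
    probs = model.predict_proba([s.values for s in test])
    pred = [CLASS_ORDER[i] for i in np.argmax(probs, axis=1)]
    truth = [s.label for s in test]
    return {
        "accuracy": float(np.mean([p == t for p, t in zip(pred, truth)])),
        "confusion": confusion_matrix(truth, pred),
        "history": history,
        "model": model,
        "dataset": ds,
    }


def leave_one_model_out(
    library: list[ModelSpec] | None = None,
    variant: str = "W",
    n_per_class: int = 30,
    net_config: EWSNetConfig | None = None,
    train_config: TrainingConfig | None = None,
    seed: int | None = None,
    **dataset_kwargs,
) -> list[dict]:
    """Generalisation test: train on all models but one, test on the rest.

    One classifier per fold; the held-out model's series (train and test
    splits pooled) form the evaluation set.  A warning is issued when the
    held-out model's class is absent from the training library.
    """
    library = model_library() if library is None else library
    if len(library) < 2:
        raise ValueError("need at least 2 models for leave-one-out folds")
    rows = []
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(len(library)) % (2**31 - 1)
    for fold, held_out in enumerate(library):
        kept = [m for m in library if m.name != held_out.name]
        train_classes = {m.transition_label for m in kept}
        if held_out.transition_label not in train_classes:
            warnings.warn(
                f"held-out model {held_out.name!r} has label "
                f"{held_out.transition_label} absent from the training library",
                stacklevel=2,
            )
        fseed = int(fold_seeds[fold])
        train_ds = build_dataset(
            variant, n_per_class, seed=fseed, library=kept,
            require_all_classes=False, **dataset_kwargs,
        )
        # held-out series simulated separately (all splits pooled)
        held_lib = [held_out]
        n_eval = max(5, n_per_class // 2)
        eval_ds = build_dataset(
            variant, n_eval, seed=fseed + 1,
            library=_pad_classes(held_lib, library), **dataset_kwargs,
        )
        eval_series = [s for s in eval_ds.series if s.model_name == held_out.name]
        tc = train_config or TrainingConfig()
        import dataclasses

        tc = dataclasses.replace(tc, seed=fseed)
        model = LSTMFCNClassifier(net_config, seed=fseed)
        tr = train_ds.train + train_ds.test  # all non-held-out data is fair game
        train_ewsnet(model, [s.values for s in tr], [s.label for s in tr], tc)
        acc = evaluate(model, [s.values for s in eval_series], [s.label for s in eval_series])
        rows.append(
            {
                "held_out": held_out.name,
                "label": held_out.transition_label,
                "accuracy": acc,
                "n_eval": len(eval_series),
            }
        )
    return rows


def _pad_classes(target: list[ModelSpec], full: list[ModelSpec]) -> list[ModelSpec]:
    """build_dataset needs every class present; pad with one model per
    missing class (their series are discarded by the caller)."""
    have = {m.transition_label for m in target}
    out = list(target)
    for m in full:
        if m.transition_label not in have:
            out.append(m)
            have.add(m.transition_label)
    return out
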