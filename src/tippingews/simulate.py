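"""Euler-Maruyama simulation of labelled transition time series.

Trajectories are integrated at a fine step ``dt`` and recorded every
``record_every`` time units, giving the canonical length-400 training series
(time points T = 1..400).  The control parameter is ramped linearly over the
full simulated interval; transition-class series are truncated at the
recorded point where the ramp crosses the bifurcation value, so classifiers
only ever see pre-transition data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .models import CT, NT, ST, LABELS, ModelSpec, model_library
from .noise import NoiseConfig, _ar1_sequence, generate_coloured_noise_batch

__all__ = [
    "LabelledSeries",
    "LabelledDataset",
    "simulate_sde",
    "assign_label",
    "truncate_pre_transition",
    "subsample_series",
    "build_dataset",
    "SimulationError",
]

#: divergence guard for the integrator
BLOWUP = 1e8


class SimulationError(RuntimeError):
    pass


@dataclass
class LabelledSeries:
    """One recorded trajectory with its class label and provenance."""

    values: np.ndarray
    times: np.ndarray  # 1-based recorded time points, strictly increasing
    label: str | None
    model_name: str
    noise: NoiseConfig
    seed: int | None = None
    truncation_index: int | None = None  # last pre-transition sample kept
    crossing_index: int | None = None  # recorded index where p crosses p_crit

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.size < 2:
            raise ValueError("a series needs at least 2 points")
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return int(self.values.size)

    def replace(self, **kw) -> "LabelledSeries":
        return dataclasses.replace(self, **kw)


@dataclass
class LabelledDataset:
    """A collection of labelled series with a train/test partition."""

    series: list[LabelledSeries]
    variant: str  # "W" (white noise) or "C" (coloured)
    split: list[str]  # per-series "train" / "test"

    def __post_init__(self) -> None:
        if self.variant not in ("W", "C"):
            raise ValueError("variant must be 'W' or 'C'")
        if len(self.split) != len(self.series):
            raise ValueError("split assignment must cover every series")

    def subset(self, which: str) -> list[LabelledSeries]:
        return [s for s, sp in zip(self.series, self.split) if sp == which]

    @property
    def train(self) -> list[LabelledSeries]:
        return self.subset("train")

    @property
    def test(self) -> list[LabelledSeries]:
        return self.subset("test")


# ---------------------------------------------------------------------------
# integration


def _integrate(
    model: ModelSpec,
    x0: np.ndarray,
    xi: np.ndarray,
    length: int,
    dt: float,
    n_sub: int,
    p_start: float | np.ndarray | None = None,
    p_end: float | np.ndarray | None = None,
) -> np.ndarray:
    """Batched Euler-Maruyama.  ``x0``: (n,) or (n, 2); ``xi``: (n, steps).

    Returns recorded values, shape (n, length); the recorded state is
    ``x[..., record_component]`` for 2-D models.  The control parameter ramps
    linearly over the whole simulated interval; ``p_start``/``p_end`` may be
    per-series arrays of shape (n,) overriding the spec's ramp (rows of
    ``xi`` already carry the noise intensity).
    """
    n = x0.shape[0]
    n_steps = length * n_sub
    if xi.shape != (n, n_steps):
        raise ValueError("noise array shape mismatch")
    p0 = np.asarray(model.p_start if p_start is None else p_start, dtype=float)
    p1 = np.asarray(model.p_end if p_end is None else p_end, dtype=float)
    p_span = p1 - p0
    frac = (np.arange(n_steps) + 1.0) / n_steps
    x = np.array(x0, dtype=float)
    out = np.empty((n, length))
    sq = np.sqrt(dt)
    two_d = model.state_dim == 2
    check_every = max(1, n_sub)
    for step in range(n_steps):
        p = p0 + p_span * frac[step]
        if two_d:
            x = x + model.drift(x, p) * dt + model.diffusion(x) * xi[:, step, None] * sq
        else:
            x = x + model.drift(x, p) * dt + model.diffusion(x) * xi[:, step] * sq
        if model.clip_zero:
            x = np.maximum(x, 0.0)
        if (step + 1) % check_every == 0 and (
            not np.all(np.isfinite(x)) or np.any(np.abs(x) > BLOWUP)
        ):
            raise SimulationError(
                f"state blow-up in model {model.name!r} at integrator step {step}"
            )
        if (step + 1) % n_sub == 0:
            rec = x[:, model.record_component] if two_d else x
            out[:, step // n_sub] = rec
    return out


def simulate_sde(
    model: ModelSpec,
    noise: NoiseConfig,
    length: int = 400,
    dt: float = 0.01,
    record_every: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> LabelledSeries:
    """Simulate one trajectory; the label is attached by :func:`assign_label`.

    One AR(1) noise innovation is drawn per integrator step; the state is
    advanced as ``X += f(X, p) dt + g(X) xi sqrt(dt)`` and recorded every
    ``record_every`` time units.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if length < 2:
        raise ValueError("length must be >= 2")
    n_sub = max(1, round(record_every / dt))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_int = int(seed) if isinstance(seed, (int, np.integer)) else None
    xi_rec = _ar1_sequence(length, noise.k, noise.sigma, noise.beta, rng)
    xi = _hold_noise(xi_rec[None, :], n_sub)
    x0 = np.asarray(model.x0_sampler(rng, 1), dtype=float)
    x0 = x0.reshape(1) if model.state_dim == 1 else x0.reshape(1, 2)
    values = _integrate(model, x0, xi, length, dt, n_sub)[0]
    series = LabelledSeries(
        values=values,
        times=np.arange(1, length + 1, dtype=float),
        label=None,
        model_name=model.name,
        noise=noise,
        seed=seed_int,
        crossing_index=_crossing_index(model, length),
    )
    return series


def _hold_noise(xi_rec: np.ndarray, n_sub: int) -> np.ndarray:
    """Expand recorded-point noise to integrator substeps.

    The AR(1) recursion defines one noise value per recorded time point;
    within each point's ``n_sub`` refinement substeps that value is held
    constant and scaled by 1/sqrt(n_sub), so the point's total Euler-
    Maruyama noise mass is g * xi(T) * sqrt(record_every) — the unit-step
    scheme — while the drift is integrated at the fine step.  The recorded
    forcing keeps pointwise variance sigma^2 and lag-1 autocorrelation k
    for every k, including anticorrelated (k < 0) noise.
    """
    if n_sub == 1:
        return xi_rec
    return np.repeat(xi_rec, n_sub, axis=-1) / np.sqrt(n_sub)


def _crossing_index(model: ModelSpec, length: int) -> int | None:
    """Recorded index (0-based) at which the ramp first crosses p_crit."""
    frac = model.crossing_fraction()
    if frac is None:
        return None
    idx = int(np.ceil(frac * length)) - 1
    return max(0, min(length - 1, idx))


def assign_label(model: ModelSpec, ramp_reached_crit: bool) -> str:
    """Class label: fold reaching its bifurcation point is catastrophic
    (C.T.), the continuous bifurcations are smooth (S.T.), anything that
    never reaches a bifurcation is a no-transition series (N.T.)."""
    if not ramp_reached_crit:
        return NT
    label = model.transition_label
    if label == NT:
        raise ValueError(
            f"model {model.name!r} has no bifurcation but the ramp reportedly "
            "reached one"
        )
    return label


def label_series(series: LabelledSeries, model: ModelSpec) -> LabelledSeries:
    reached = series.crossing_index is not None
    series.label = assign_label(model, reached)
    return series


def truncate_pre_transition(
    series: LabelledSeries, model: ModelSpec, margin: int = 0
) -> LabelledSeries:
    """Keep only the part of a transition series before the bifurcation.

    Returns the prefix ending ``margin`` points before the recorded crossing
    index; no-transition series pass through unchanged.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if series.crossing_index is None:
        return series
    end = series.crossing_index + 1 - margin  # crossing at index c -> length c+1-margin
    if end < 2:
        raise ValueError(
            f"margin {margin} leaves fewer than 2 points before the crossing "
            f"at index {series.crossing_index}"
        )
    return series.replace(
        values=series.values[:end],
        times=series.times[:end],
        truncation_index=end - 1,
    )


def subsample_series(
    series: LabelledSeries,
    fraction: float,
    seed: int | np.random.Generator | None = None,
) -> LabelledSeries:
    """Random temporal subsampling: keep ceil(fraction * length) points,
    chosen uniformly without replacement, in original order."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    n = len(series)
    if fraction * n < 2:
        raise ValueError(f"fraction {fraction} retains fewer than 2 points")
    keep = int(np.ceil(fraction * n))
    if keep == n:
        return series
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=keep, replace=False))
    return series.replace(values=series.values[idx], times=series.times[idx])


# ---------------------------------------------------------------------------
# dataset construction

#: |k| band for weakly correlated (training) coloured noise
WEAK_K = (0.0, 0.4)
#: |k| band for strongly correlated (test) coloured noise
STRONG_K = (0.4, 0.8)
#: crossing placed uniformly in this fraction band of the series
CROSSING_BAND = (0.75, 0.95)


def _class_models(library: list[ModelSpec]) -> dict[str, list[ModelSpec]]:
    out: dict[str, list[ModelSpec]] = {CT: [], ST: [], NT: []}
    for m in library:
        out[m.transition_label].append(m)
    return out


def build_dataset(
    variant: str,
    n_per_class: int,
    length: int = 400,
    seed: int | None = None,
    library: list[ModelSpec] | None = None,
    sigma: float = 1.0,
    dt: float = 0.01,
    record_every: float = 1.0,
    test_fraction: float = 0.2,
    margin: int = 0,
    require_all_classes: bool = True,
) -> LabelledDataset:
    """Generate a balanced, labelled, split dataset.

    Variant ``"W"`` uses white noise (k = 0) throughout; variant ``"C"``
    draws |k| from the weak band [0, 0.4] for training series and from the
    strong band (0.4, 0.8] for test series (random sign).  The split is
    stratified per class and per model; transition series are truncated at
    the bifurcation crossing, whose placement is jittered per series within
    ``CROSSING_BAND`` of the series length.
    """
    if variant not in ("W", "C"):
        raise ValueError("variant must be 'W' or 'C'")
    if n_per_class < 5:
        raise ValueError("n_per_class must be >= 5 to allow an 80/20 split")
    library = model_library() if library is None else library
    by_class = _class_models(library)
    for lbl, specs in list(by_class.items()):
        if not specs:
            if require_all_classes:
                raise ValueError(f"model library has no spec for class {lbl}")
            del by_class[lbl]

    master = np.random.SeedSequence(seed)
    rng = np.random.default_rng(master)
    all_series: list[LabelledSeries] = []
    split: list[str] = []
    n_sub = max(1, round(record_every / dt))

    for lbl in [l for l in LABELS if l in by_class]:
        specs = by_class[lbl]
        counts = np.full(len(specs), n_per_class // len(specs))
        counts[: n_per_class % len(specs)] += 1
        # distribute the class's exact test quota over its models
        class_n_test = int(round(n_per_class * test_fraction))
        quota = counts * test_fraction
        test_counts = np.floor(quota).astype(int)
        remainder = np.argsort(-(quota - test_counts))
        for i in remainder[: class_n_test - test_counts.sum()]:
            test_counts[i] += 1
        for spec, n_i, n_test in zip(specs, counts, test_counts):
            n_i, n_test = int(n_i), int(n_test)
            if n_i == 0:
                continue
            is_test = np.zeros(n_i, dtype=bool)
            is_test[rng.choice(n_i, size=n_test, replace=False)] = True
            # noise autocorrelation per series
            if variant == "W":
                k = np.zeros(n_i)
            else:
                lo = np.where(is_test, STRONG_K[0], WEAK_K[0])
                hi = np.where(is_test, STRONG_K[1], WEAK_K[1])
                k = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0], size=n_i)
            child_seed = int(rng.integers(0, 2**31 - 1))
            crng = np.random.default_rng(child_seed)
            xi = _hold_noise(
                generate_coloured_noise_batch(n_i, length, k, sigma, crng), n_sub
            )
            # per-series crossing jitter via per-series ramp end
            if spec.p_crit is not None and spec.p_end != spec.p_start:
                fracs = crng.uniform(*CROSSING_BAND, size=n_i)
            else:
                fracs = None
            x0 = spec.x0_sampler(crng, n_i)
            if spec.state_dim == 1:
                x0 = np.asarray(x0, dtype=float).reshape(n_i)
            if fracs is None:
                values = _integrate(spec, x0, xi, length, dt, n_sub)
                cross: list[int | None] = [None] * n_i
            else:
                p_end = spec.p_start + (spec.p_crit - spec.p_start) / fracs
                values = _integrate(
                    spec, x0, xi, length, dt, n_sub, p_start=spec.p_start, p_end=p_end
                )
                cross = [
                    max(0, min(length - 1, int(np.ceil(f * length)) - 1)) for f in fracs
                ]
            times = np.arange(1, length + 1, dtype=float)
            for j in range(n_i):
                s = LabelledSeries(
                    values=values[j],
                    times=times.copy(),
                    label=lbl,
                    model_name=spec.name,
                    noise=NoiseConfig(k=float(k[j]), sigma=sigma),
                    seed=child_seed,
                    crossing_index=cross[j],
                )
                s = truncate_pre_transition(s, spec, margin=margin)
                all_series.append(s)
                split.append("test" if is_test[j] else "train")

    order = rng.permutation(len(all_series))
    return LabelledDataset(
        series=[all_series[i] for i in order],
        variant=variant,
        split=[split[i] for i in order],
    )
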