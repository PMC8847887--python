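"""Formats and configuration: CSV series, HDF5 datasets, prediction tables.

Internal indexing is 0-based; recorded time points are reported 1-based
(T = 1..length).  Label codes in the HDF5 container are 0 = C.T., 1 = S.T.,
2 = N.T.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .models import CT, NT, ST
from .noise import NoiseConfig
from .simulate import LabelledDataset, LabelledSeries

__all__ = [
    "read_timeseries_csv",
    "write_predictions",
    "save_dataset",
    "load_dataset",
    "export_dataset_csv",
    "RunConfig",
    "load_run_config",
]

LABEL_CODES = {CT: 0, ST: 1, NT: 2}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}


def read_timeseries_csv(
    path: str | Path,
    time_column: str | int | None = None,
    value_column: str | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Read one univariate series; returns (times, values).

    Two numeric columns are interpreted as (time, value); a single column as
    values with an implicit 1..n index.  Rows are sorted by time; duplicate
    timestamps and non-numeric cells are errors naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 rows")
    if value_column is not None:
        vals_raw = df[value_column] if isinstance(value_column, str) else df.iloc[:, value_column]
    else:
        vals_raw = df.iloc[:, 1] if df.shape[1] >= 2 else df.iloc[:, 0]
    if time_column is not None:
        times_raw = df[time_column] if isinstance(time_column, str) else df.iloc[:, time_column]
    else:
        times_raw = df.iloc[:, 0] if df.shape[1] >= 2 else None

    def _numeric(col, what):
        out = pd.to_numeric(col, errors="coerce")
        bad = out.index[out.isna() & col.notna()]
        if len(bad) or out.isna().any():
            row = int((out.isna()).idxmax())
            raise ValueError(f"{path}: non-numeric {what} at row {row + 2}")  # header+1-based
        return out.to_numpy(dtype=float)

    values = _numeric(vals_raw, "value")
    if times_raw is None:
        times = np.arange(1, values.size + 1, dtype=float)
    else:
        times = _numeric(times_raw, "time")
        order = np.argsort(times, kind="stable")
        times, values = times[order], values[order]
        if np.any(np.diff(times) == 0):
            dup = float(times[np.flatnonzero(np.diff(times) == 0)[0]])
            raise ValueError(f"{path}: duplicate timestamp {dup}")
    return times, values


def write_predictions(records: list[dict], path: str | Path) -> None:
    """CSV with columns series_id,label,p_CT,p_ST,p_NT (>= 6 sig. digits)."""
    path = Path(path)
    cols = ["series_id", "label", "p_CT", "p_ST", "p_NT"]
    lines = [",".join(cols)]
    for r in records:
        probs = np.asarray(r["probs"], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError(f"probabilities for {r['series_id']} do not sum to 1")
        lines.append(
            f"{r['series_id']},{r['label']},"
            + ",".join(f"{p:.8g}" for p in probs)
        )
    path.write_text("\n".join(lines) + "\n")


def save_dataset(dataset: LabelledDataset, path: str | Path) -> None:
    """One HDF5 container: padded /values + /lengths, /labels codes, /meta."""
    path = Path(path)
    lengths = np.array([len(s) for s in dataset.series])
    maxlen = int(lengths.max())
    values = np.full((len(dataset.series), maxlen), np.nan)
    for i, s in enumerate(dataset.series):
        values[i, : len(s)] = s.values
    meta = [
        json.dumps(
            {
                "model": s.model_name,
                "k": s.noise.k,
                "sigma": s.noise.sigma,
                "rho": s.noise.rho,
                "seed": s.seed,
                "truncation_index": s.truncation_index,
                "crossing_index": s.crossing_index,
            }
        )
        for s in dataset.series
    ]
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=values)
        f.create_dataset("lengths", data=lengths)
        f.create_dataset("labels", data=np.array([LABEL_CODES[s.label] for s in dataset.series]))
        f.create_dataset("split", data=np.array([sp == "test" for sp in dataset.split]))
        f.create_dataset("meta", data=np.array(meta, dtype=h5py.string_dtype()))
        f.attrs["variant"] = dataset.variant


def load_dataset(path: str | Path) -> LabelledDataset:
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        lengths = f["lengths"][()]
        labels = f["labels"][()]
        is_test = f["split"][()]
        meta = [json.loads(m) for m in f["meta"].asstr()[()]]
        variant = f.attrs["variant"]
    series = []
    for i in range(values.shape[0]):
        n = int(lengths[i])
        m = meta[i]
        series.append(
            LabelledSeries(
                values=values[i, :n],
                times=np.arange(1, n + 1, dtype=float),
                label=CODE_LABELS[int(labels[i])],
                model_name=m["model"],
                noise=NoiseConfig(k=m["k"], sigma=m["sigma"], rho=m["rho"]),
                seed=m["seed"],
                truncation_index=m["truncation_index"],
                crossing_index=m["crossing_index"],
            )
        )
    return LabelledDataset(
        series=series,
        variant=str(variant),
        split=["test" if t else "train" for t in is_test],
    )


def export_dataset_csv(dataset: LabelledDataset, out_dir: str | Path) -> Path:
    """One time,value CSV per series plus a provenance manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (s, sp) in enumerate(zip(dataset.series, dataset.split)):
        sid = f"series_{i:05d}"
        pd.DataFrame({"time": s.times, "value": s.values}).to_csv(
            out_dir / f"{sid}.csv", index=False
        )
        rows.append(
            {
                "series_id": sid,
                "label": s.label,
                "model": s.model_name,
                "k": s.noise.k,
                "sigma": s.noise.sigma,
                "seed": s.seed,
                "split": sp,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------- run config

_ALLOWED_SECTIONS = {"simulation", "ews", "baseline", "network", "training", "experiment"}
_ALLOWED_GLOBAL = {"seed", "out_dir", "log_level"}


@dataclass
class RunConfig:
    """Nested run configuration with strict (unknown-key-rejecting) parsing."""

    seed: int | None = None
    out_dir: str = "results"
    log_level: str = "INFO"
    simulation: dict = field(default_factory=dict)
    ews: dict = field(default_factory=dict)
    baseline: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    experiment: dict = field(default_factory=dict)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _ALLOWED_SECTIONS - _ALLOWED_GLOBAL
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)
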