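"""Design-of-experiments sampling, dataset tables and splits.

Material-parameter designs are Latin-hypercube samples over the study's
printed ranges: the active triplet (l0, t0, Tmax) for LV and RV tissue in
the pressure/volume ensemble, and the four passive stiffnesses
(a, a_f, a_s, a_fs) in the stress ensemble.  Flat feature tables carry one
row per (model, time point) with 8 features for pressure/volume and one
row per (model, centroid) with 7 features for stress; sequence datasets
window the targets with a 20-step lookback, chaining models in design
order.  Splits are model-wise (never row-wise), with the validation count
equal to 10% of the training+validation pool, rounded half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = [
    "ACTIVE_RANGES",
    "PASSIVE_RANGES",
    "ParameterRanges",
    "DOEDesign",
    "SplitSpec",
    "FeatureTable",
    "SequenceDataset",
    "PV_FEATURES",
    "STRESS_FEATURES",
    "sample_design",
    "split_models",
    "build_pv_table",
    "build_stress_table",
    "build_sequences",
    "normalize_to_range",
]

#: Printed design ranges of the active parameters: l0 (m), t0 (s) and the
#: dimensionless Tmax multiplier; applied to both LV and RV tissue.
ACTIVE_RANGES: dict[str, tuple[float, float]] = {
    "l0": (0.0015, 0.0028),
    "t0": (0.075, 0.25),
    "tmax": (0.65, 1.9),
}

#: Printed design ranges of the passive stiffnesses (MPa).
PASSIVE_RANGES: dict[str, tuple[float, float]] = {
    "a": (0.387e-4, 9.881e-3),
    "a_f": (0.005e-1, 49.901e-3),
    "a_s": (9.1e-5, 6.986e-3),
    "a_fs": (4.4e-5, 3.952e-3),
}

PV_FEATURES_BASE = ["l0_lv", "t0_lv", "tmax_lv", "l0_rv", "t0_rv", "tmax_rv"]
PV_FEATURES = {
    "pressure": PV_FEATURES_BASE + ["time", "volume"],
    "volume": PV_FEATURES_BASE + ["time", "pressure"],
}
STRESS_FEATURES = ["a", "a_f", "a_s", "a_fs", "x", "y", "z"]


def _check_ranges(ranges: dict[str, tuple[float, float]]) -> None:
    for name, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ValueError(f"range for {name} must satisfy low < high")


@dataclass(frozen=True)
class ParameterRanges:
    """Named (low, high) bounds per parameter."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        _check_ranges(self.bounds)

    @classmethod
    def active_pair(cls) -> "ParameterRanges":
        """LV+RV active triplets (6 parameters, printed ranges)."""
        b = {}
        for side in ("lv", "rv"):
            for k, v in ACTIVE_RANGES.items():
                b[f"{k}_{side}"] = v
        return cls(bounds=b)

    @classmethod
    def passive(cls) -> "ParameterRanges":
        return cls(bounds=dict(PASSIVE_RANGES))

    @property
    def names(self) -> list[str]:
        return list(self.bounds)


@dataclass(frozen=True)
class DOEDesign:
    """Latin-hypercube design: ``samples`` is an (n_models, n_params)
    DataFrame with one column per parameter; rows are model designs."""

    samples: pd.DataFrame
    seed: int
    scheme: str = "latin-hypercube"

    @property
    def n_models(self) -> int:
        return len(self.samples)

    @property
    def model_ids(self) -> list[str]:
        return list(self.samples.index)


def sample_design(
    ranges: ParameterRanges, n_models: int, seed: int
) -> DOEDesign:
    """Latin-hypercube sample over ``ranges``: each parameter's n_models
    values occupy distinct equal-width strata; reproducible under seed."""
    if n_models < 2:
        raise ValueError("n_models must be >= 2")
    names = ranges.names
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n=n_models)
    lo = np.array([ranges.bounds[n][0] for n in names])
    hi = np.array([ranges.bounds[n][1] for n in names])
    vals = qmc.scale(unit, lo, hi)
    ids = [f"m{i:04d}" for i in range(n_models)]
    df = pd.DataFrame(vals, columns=names, index=ids)
    return DOEDesign(samples=df, seed=seed)


def normalize_to_range(x: float, bounds: tuple[float, float]) -> float:
    """Map a value in [lo, hi] to a z-score in [-1, 1] about the midpoint."""
    lo, hi = bounds
    return 2.0 * (x - 0.5 * (lo + hi)) / (hi - lo)


@dataclass(frozen=True)
class SplitSpec:
    """Model-wise split sizes: ``n_test`` held-out models, validation =
    10% of the remaining pool (rounded half away from zero)."""

    n_total: int
    n_test: int
    val_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_test >= self.n_total:
            raise ValueError("n_test must be < n_total")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")

    @property
    def n_val(self) -> int:
        # round half away from zero, but keep at least one validation
        # model so early stopping is always defined
        pool = self.n_total - self.n_test
        return max(1, int(math.floor(self.val_fraction * pool + 0.5)))

    @property
    def n_train(self) -> int:
        return self.n_total - self.n_test - self.n_val


def split_models(
    spec: SplitSpec, model_ids: list[str] | None = None
) -> tuple[list[str], list[str], list[str]]:
    """Seeded disjoint (train, val, test) model-id lists with the spec's
    sizes; whole models are assigned to one split, never rows."""
    if model_ids is None:
        model_ids = [f"m{i:04d}" for i in range(spec.n_total)]
    if len(model_ids) != spec.n_total:
        raise ValueError("model_ids length must equal n_total")
    rng = np.random.default_rng(spec.seed)
    perm = list(rng.permutation(model_ids))
    test = perm[: spec.n_test]
    val = perm[spec.n_test: spec.n_test + spec.n_val]
    train = perm[spec.n_test + spec.n_val:]
    return sorted(train), sorted(val), sorted(test)


@dataclass(frozen=True)
class FeatureTable:
    """Flat training table: feature matrix, target vector and model ids.

    ``schema`` is one of pv_pressure, pv_volume, stress_ff, stress_cc,
    stress_fs; rows are grouped contiguously by model_id.
    """

    frame: pd.DataFrame
    schema: str
    feature_columns: list[str]
    target_column: str

    def __post_init__(self) -> None:
        expect = 8 if self.schema.startswith("pv_") else 7
        if len(self.feature_columns) != expect:
            raise ValueError(
                f"schema {self.schema} requires {expect} feature columns"
            )
        missing = [c for c in self.feature_columns + [self.target_column, "model_id"]
                   if c not in self.frame.columns]
        if missing:
            raise ValueError(f"table missing columns {missing}")

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.target_column].to_numpy(dtype=float)

    @property
    def model_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["model_id"]))

    def subset(self, ids: list[str]) -> "FeatureTable":
        sub = self.frame[self.frame["model_id"].isin(set(ids))].reset_index(drop=True)
        return FeatureTable(frame=sub, schema=self.schema,
                           feature_columns=self.feature_columns,
                           target_column=self.target_column)

    def __len__(self) -> int:
        return len(self.frame)


def build_pv_table(traces, design: DOEDesign, target: str) -> FeatureTable:
    """Flat table for the pressure/volume task: one row per (model, time
    point); features are the six active design parameters, time, and the
    co-signal (volume when predicting pressure and vice versa)."""
    if target not in ("pressure", "volume"):
        raise ValueError("target must be 'pressure' or 'volume'")
    co = "volume" if target == "pressure" else "pressure"
    by_id = {tr.model_id: tr for tr in traces}
    frames = []
    for mid in design.model_ids:
        tr = by_id.get(mid)
        if tr is None:
            raise ValueError(f"missing trace for model {mid}")
        row = design.samples.loc[mid]
        n = len(tr.time)
        block = pd.DataFrame({
            "model_id": [mid] * n,
            "l0_lv": row["l0_lv"], "t0_lv": row["t0_lv"], "tmax_lv": row["tmax_lv"],
            "l0_rv": row["l0_rv"], "t0_rv": row["t0_rv"], "tmax_rv": row["tmax_rv"],
            "time": tr.time,
            co: getattr(tr, co),
            target: getattr(tr, target),
        })
        frames.append(block)
    frame = pd.concat(frames, ignore_index=True)
    return FeatureTable(frame=frame, schema=f"pv_{target}",
                        feature_columns=PV_FEATURES[target],
                        target_column=target)


def build_stress_table(fields, design: DOEDesign, component: str) -> FeatureTable:
    """Flat table for the stress task: one row per (model, centroid);
    features are the four passive stiffnesses and the centroid
    coordinates; target is the chosen stress component."""
    if component not in ("ff", "cc", "fs"):
        raise ValueError("component must be one of ff, cc, fs")
    by_id = {f.model_id: f for f in fields}
    frames = []
    for mid in design.model_ids:
        fld = by_id.get(mid)
        if fld is None:
            raise ValueError(f"missing stress field for model {mid}")
        row = design.samples.loc[mid]
        n = len(fld.centroids)
        block = pd.DataFrame({
            "model_id": [mid] * n,
            "a": row["a"], "a_f": row["a_f"], "a_s": row["a_s"], "a_fs": row["a_fs"],
            "x": fld.centroids[:, 0], "y": fld.centroids[:, 1],
            "z": fld.centroids[:, 2],
            "sigma": getattr(fld, f"sigma_{component}"),
        })
        frames.append(block)
    frame = pd.concat(frames, ignore_index=True)
    return FeatureTable(frame=frame, schema=f"stress_{component}",
                        feature_columns=list(STRESS_FEATURES),
                        target_column="sigma")


@dataclass(frozen=True)
class SequenceDataset:
    """Windowed dataset for the LSTM surrogate.

    ``history``: (n_windows, lookback) previous target values in the
    chained model order; ``static``: (n_windows, n_static) current-step
    property features; ``target``: (n_windows,) current target.  Models
    are chained in design order, so only the global first ``lookback``
    positions are dropped.
    """

    history: np.ndarray
    static: np.ndarray
    target: np.ndarray
    lookback: int
    batch_size: int
    schema: str
    static_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.history.shape[1] != self.lookback:
            raise ValueError("window length must equal lookback")
        if not (len(self.history) == len(self.static) == len(self.target)):
            raise ValueError("inconsistent window counts")

    def __len__(self) -> int:
        return len(self.target)

    def subset(self, idx: np.ndarray) -> "SequenceDataset":
        return SequenceDataset(
            history=self.history[idx], static=self.static[idx],
            target=self.target[idx], lookback=self.lookback,
            batch_size=self.batch_size, schema=self.schema,
            static_columns=list(self.static_columns),
        )


def build_sequences(
    table: FeatureTable, lookback: int = 20, mode: str | None = None
) -> SequenceDataset:
    """Window a flat table into 20-step-history sequences.

    Rows must already be ordered (time within model for pv, centroid
    traversal order within model for stress) with models in design order;
    the history channel continues across model boundaries (each model is
    treated as the sequence continuation of the previous design), so only
    the very first ``lookback`` rows are dropped.  The static features
    exclude the co-signal for the pv task: histories stand in for it.
    """
    if mode is None:
        mode = "pv" if table.schema.startswith("pv_") else "stress"
    if len(table) < lookback + 1:
        raise ValueError("need more than lookback rows")
    if mode == "pv":
        static_cols = list(PV_FEATURES_BASE) + ["time"]
        batch = 401
    else:
        static_cols = list(STRESS_FEATURES)
        batch = 576
    y = table.y
    stat = table.frame[static_cols].to_numpy(dtype=float)
    n = len(y) - lookback
    hist = np.lib.stride_tricks.sliding_window_view(y, lookback)[:n]
    return SequenceDataset(
        history=hist.copy(), static=stat[lookback:], target=y[lookback:],
        lookback=lookback, batch_size=batch, schema=table.schema,
        static_columns=static_cols,
    )
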