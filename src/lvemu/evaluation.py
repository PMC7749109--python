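"""Per-model error analysis.

Surrogate accuracy is scored by the mean absolute error per held-out
model, MAE = sum_i |y_i - yhat_i| / n over that model's time points (or
element centroids), and MAE_Average = sum_m MAE / m across the m test
models — per-model first, because the rows within one model are not
independent samples.  The spread reported alongside is the sample
standard deviation across test models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .doe import FeatureTable

__all__ = [
    "LeakageError",
    "EvaluationReport",
    "TABLE1_REFERENCE",
    "mae",
    "mae_average",
    "evaluate_surrogate",
]


class LeakageError(ValueError):
    """A test model also appears in the training manifest."""


#: Published reference errors (MAE ± SD) the package's reports are printed
#: next to.  These are fixed constants from the emulated study's Table 1 /
#: Abstract, shipped as data — never recomputed here.  "a" entries used 3
#: test models, "b" entries 6; the XGBoost column is the earlier
#: decision-tree baseline.
TABLE1_REFERENCE: dict[str, dict[str, tuple[float, float] | None]] = {
    "stress_ff": {"dl": (0.179, 0.050), "xgboost": (0.334, 0.228), "units": "kPa"},
    "stress_cc": {"dl": (0.049, 0.017), "xgboost": (0.075, 0.024), "units": "kPa"},
    "stress_fs": {"dl": (0.039, 0.011), "xgboost": (0.050, 0.032), "units": "kPa"},
    "pv_volume_3test": {"dl": (0.687, 0.165), "xgboost": (1.734, 0.584), "units": "ml"},
    "pv_pressure_3test": {"dl": (0.923, 0.285), "xgboost": (1.544, 0.298), "units": "mmHg"},
    "pv_volume": {"dl": (1.599, 1.227), "xgboost": None, "units": "ml"},
    "pv_pressure": {"dl": (1.257, 0.488), "xgboost": None, "units": "mmHg"},
}

_UNITS = {
    "pv_volume": "ml",
    "pv_pressure": "mmHg",
    "stress_ff": "kPa",
    "stress_cc": "kPa",
    "stress_fs": "kPa",
}


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute error between equal-length vectors."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 1:
        raise ValueError("need at least one sample")
    return float(np.mean(np.abs(y - yhat)))


@dataclass(frozen=True)
class EvaluationReport:
    """Per-test-model MAEs, their mean (MAE_Average) and the sample SD
    across test models."""

    per_model_mae: dict[str, float]
    mae_average: float
    sd: float
    task: str
    units: str

    @property
    def n_models(self) -> int:
        return len(self.per_model_mae)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"model_id": list(self.per_model_mae),
             "mae": list(self.per_model_mae.values())}
        )

    def summary(self) -> str:
        ref = TABLE1_REFERENCE.get(self.task)
        lines = [
            f"Evaluation report — task {self.task}",
            "=" * 40,
            f"test models:  {self.n_models}",
            f"MAE_Average:  {self.mae_average:.4f} ± {self.sd:.4f} {self.units}",
        ]
        if ref is not None and ref.get("dl") is not None:
            m, s = ref["dl"]
            lines.append(
                f"published DL reference: {m:.3f} ± {s:.3f} {ref['units']}"
            )
            if ref.get("xgboost") is not None:
                mx, sx = ref["xgboost"]
                lines.append(
                    f"published XGBoost reference: {mx:.3f} ± {sx:.3f} {ref['units']}"
                )
        for mid, v in self.per_model_mae.items():
            lines.append(f"  {mid}: {v:.4f} {self.units}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def mae_average(
    per_model: dict[str, tuple[np.ndarray, np.ndarray]],
    task: str = "unspecified",
    units: str = "",
) -> EvaluationReport:
    """Per-model MAEs and their mean/SD across models.

    ``per_model`` maps model_id -> (y, yhat).  With a single model the SD
    is reported as 0 (with a warning)."""
    if len(per_model) < 1:
        raise ValueError("need at least one test model")
    maes = {mid: mae(y, yh) for mid, (y, yh) in per_model.items()}
    vals = np.array(list(maes.values()))
    if len(vals) == 1:
        warnings.warn("single test model: SD reported as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(vals, ddof=1))
    return EvaluationReport(
        per_model_mae=maes, mae_average=float(np.mean(vals)), sd=sd,
        task=task, units=units or _UNITS.get(task, ""),
    )


def evaluate_surrogate(
    results, test: FeatureTable, task: str | None = None
) -> EvaluationReport:
    """Score a fitted surrogate on a held-out table, model by model.

    Refuses to evaluate if any test model appears in the surrogate's
    training manifest (leakage guard).
    """
    if task is None:
        task = test.schema
    train_ids = set(getattr(results, "train_model_ids", []))
    overlap = train_ids & set(test.model_ids)
    if overlap:
        raise LeakageError(
            f"test models also present in training manifest: {sorted(overlap)}"
        )
    per_model: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for mid in test.model_ids:
        sub = test.subset([mid])
        per_model[mid] = (sub.y, results.predict(sub))
    return mae_average(per_model, task=task)
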