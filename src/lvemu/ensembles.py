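"""Ensemble generation: DOE designs driven through the reduced simulator.

Two study-analog ensembles:

* pressure/volume — active-parameter designs (LV and RV triplets of l0,
  t0, Tmax) over the printed ranges, one full-cycle 401-point trace per
  design; the RV triplet enters through preload/afterload perturbations.
* stress — passive-stiffness designs (a, a_f, a_s, a_fs) over the printed
  ranges, one end-diastolic 576-centroid endocardial stress field per
  design at a fixed end-diastolic pressure.
"""

from __future__ import annotations

import pandas as pd

from .chamber import (
    DEFAULT_CIRCULATION,
    DEFAULT_GEOMETRY,
    CardiacCycleTrace,
    CirculationParams,
    LVGeometry,
    SolverError,
    StressField,
    inflate_diastole,
    simulate_cycle,
)
from .constitutive import DEFAULT_PASSIVE, ActiveParams, PassiveParams
from .doe import (
    ACTIVE_RANGES,
    DOEDesign,
    ParameterRanges,
    normalize_to_range,
    sample_design,
)

__all__ = [
    "DEFAULT_EDP_MMHG",
    "generate_pv_ensemble",
    "generate_stress_ensemble",
]

#: End-diastolic pressure (mmHg) at which the stress ensemble is evaluated.
DEFAULT_EDP_MMHG = 10.0


def rv_zscores(row: pd.Series) -> tuple[float, float, float]:
    """Normalized (Tmax, t0, l0) deviations of the RV design triplet."""
    return (
        normalize_to_range(float(row["tmax_rv"]), ACTIVE_RANGES["tmax"]),
        normalize_to_range(float(row["t0_rv"]), ACTIVE_RANGES["t0"]),
        normalize_to_range(float(row["l0_rv"]), ACTIVE_RANGES["l0"]),
    )


def generate_pv_ensemble(
    n_models: int = 80,
    seed: int = 0,
    passive: PassiveParams = DEFAULT_PASSIVE,
    circ: CirculationParams = DEFAULT_CIRCULATION,
    geom: LVGeometry = DEFAULT_GEOMETRY,
    n_substeps: int = 10,
    failures: dict | None = None,
) -> tuple[DOEDesign, list[CardiacCycleTrace]]:
    """Sample the 6-parameter active design and simulate one cardiac cycle
    per model.  Deterministic given the seed.

    If ``failures`` is a dict, per-model solver failures are recorded
    there (model_id -> message) and the run continues; otherwise the
    first failure raises.
    """
    design = sample_design(ParameterRanges.active_pair(), n_models, seed)
    traces = []
    for mid in design.model_ids:
        row = design.samples.loc[mid]
        act_lv = ActiveParams.from_design(
            l0=float(row["l0_lv"]), t0=float(row["t0_lv"]),
            tmax=float(row["tmax_lv"]),
        )
        try:
            traces.append(
                simulate_cycle(act_lv, rv_z=rv_zscores(row), p=passive,
                               circ=circ, geom=geom, model_id=mid,
                               n_substeps=n_substeps)
            )
        except SolverError as exc:
            if failures is None:
                raise
            failures[mid] = str(exc)
    return design, traces


def generate_stress_ensemble(
    n_models: int = 124,
    seed: int = 0,
    edp: float = DEFAULT_EDP_MMHG,
    base_passive: PassiveParams = DEFAULT_PASSIVE,
    geom: LVGeometry = DEFAULT_GEOMETRY,
    failures: dict | None = None,
) -> tuple[DOEDesign, list[StressField]]:
    """Sample the 4-parameter passive design and inflate each model to the
    end-diastolic pressure; exponents are held at the base profile.
    ``failures`` behaves as in :func:`generate_pv_ensemble`."""
    design = sample_design(ParameterRanges.passive(), n_models, seed)
    fields = []
    for mid in design.model_ids:
        row = design.samples.loc[mid]
        p = base_passive.replace(
            a=float(row["a"]), a_f=float(row["a_f"]),
            a_s=float(row["a_s"]), a_fs=float(row["a_fs"]),
        )
        try:
            fields.append(inflate_diastole(p, geom=geom, edp=edp,
                                           model_id=mid))
        except SolverError as exc:
            if failures is None:
                raise
            failures[mid] = str(exc)
    return design, fields
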