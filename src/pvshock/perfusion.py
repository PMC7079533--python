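"""End-organ perfusion summaries.

Relative differences versus the pump-alone reference stage use the paired
(within-pig) construction: each pig's relative change is computed first, then
averaged across pigs with a t-based 95% CI — consistent with the crossover
design.  The oxygen-axis summary pairs stage-mean mixed venous saturation
with stage-mean cardiac work (HR x PVA) for the delivery-vs-work scatter.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, UndefinedReferenceError


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    n = len(values)
    m = float(np.mean(values))
    if n < 2:
        raise InsufficientDataError("need >= 2 values for a CI")
    se = float(np.std(values, ddof=1)) / np.sqrt(n)
    tq = sps.t.ppf(0.5 + level / 2.0, df=n - 1)
    return m, m - tq * se, m + tq * se


def relative_difference_vs_reference(
    records: pd.DataFrame,
    variable: str,
    reference_stage: str = "impella",
) -> pd.DataFrame:
    """Per-stage mean relative difference (fraction) vs the reference stage.

    For each pig, (x_stage - x_ref) / x_ref; across pigs, mean and t-based
    95% CI.  The reference stage maps to exactly zero with a zero-width CI.
    """
    wide = records.pivot(index="pig_id", columns="stage", values=variable)
    if reference_stage not in wide.columns:
        raise UndefinedReferenceError(f"reference stage {reference_stage!r} absent")
    ref = wide[reference_stage]
    zero_ref = ref.index[ref == 0].tolist()
    if zero_ref:
        raise UndefinedReferenceError(
            f"reference value of {variable!r} is zero for pigs: {zero_ref}"
        )
    rows = []
    for stage in records["stage"].unique():
        if stage == reference_stage:
            rows.append({"variable": variable, "stage": stage,
                         "estimate": 0.0, "ci_lo": 0.0, "ci_hi": 0.0,
                         "n": int(ref.notna().sum())})
            continue
        rel = ((wide[stage] - ref) / ref).dropna()
        m, lo, hi = _t_ci(rel.to_numpy())
        rows.append({"variable": variable, "stage": stage,
                     "estimate": m, "ci_lo": lo, "ci_hi": hi, "n": len(rel)})
    return pd.DataFrame(rows)


def oxygen_axis_summary(records: pd.DataFrame) -> pd.DataFrame:
    """(stage, mean SvO2, mean cardiac work) pairs for the delivery-vs-work plot."""
    rows = []
    for stage, grp in records.groupby("stage", sort=False):
        if grp.empty or grp["SvO2"].isna().all():
            warnings.warn(f"stage {stage!r} has no records; omitted", stacklevel=2)
            continue
        rows.append({
            "stage": stage,
            "SvO2": float(grp["SvO2"].mean()),
            "cardiac_work": float(grp["cardiac_work"].mean()),
            "n": len(grp),
        })
    return pd.DataFrame(rows)
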