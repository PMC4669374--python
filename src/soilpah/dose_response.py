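"""Dose-response summaries and the Orwin-Wardle soil-resistance index.

Works on tidy activity records with columns

    analyte, hydrocarbon, dose_mg_per_kg, replicate, value

where the analytes are organotrophic bacteria counts (1e9 cfu/kg DM),
dehydrogenase activity (umol TPF/kg DM/h) and urease activity
(mmol N-NH4/kg DM/h).  Provided summaries: per-treatment means, column
means over the four doses, fold-changes versus the dose-0 control, Pearson
correlations of value with dose, and soil resistance

    RS = 1 - 2|D0| / (C0 + |D0|),   D0 = C0 - P(t0)

with C0 the control value and P(t0) the treated value at the assessment
time.  RS = 1 means the stressor had no effect; RS = 0 a 100 % impact
(P = 0 or P = 2*C0); values approach -1 as the impact approaches 200 %.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import require_columns
from .exceptions import (
    EmptyGroupError,
    InvalidControlError,
    UndefinedCorrelationError,
)
from .plate_counts import TreatmentKey

#: Analytes and their reporting units.
ANALYTE_UNITS: dict[str, str] = {
    "organotrophic_count": "1e9 cfu kg-1 DM",
    "dehydrogenases": "umol TPF kg-1 DM h-1",
    "urease": "mmol N-NH4 kg-1 DM h-1",
}

RECORD_COLUMNS = ["analyte", "hydrocarbon", "dose_mg_per_kg", "replicate", "value"]


@dataclass(frozen=True)
class ResistanceResult:
    """RS for one analyte x hydrocarbon x dose, with its intermediates."""

    analyte: str
    treatment: TreatmentKey
    c0: float
    p_t0: float
    d0: float
    rs: float


def resistance_index(c0: float, p_t0: float) -> float:
    """Orwin-Wardle resistance index in (-1, 1].

    Symmetric in the sign of the disturbance (stimulation and inhibition of
    equal magnitude score identically) and strictly decreasing in
    ``|c0 - p_t0|``; equals 1 iff the treated value matches the control.
    """
    if not c0 > 0:
        raise InvalidControlError(f"control value must be > 0, got {c0!r}")
    if p_t0 < 0:
        raise InvalidControlError(f"treated value must be >= 0, got {p_t0!r}")
    d0 = abs(c0 - p_t0)
    return 1.0 - 2.0 * d0 / (c0 + d0)


def read_activity_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    require_columns(df, RECORD_COLUMNS, source=str(path))
    return df


def treatment_mean(
    records: pd.DataFrame,
    analyte: str,
    hydrocarbon: str,
    dose_mg_per_kg: int | None = None,
) -> float:
    """Arithmetic mean for one treatment cell, or the column mean.

    With ``dose_mg_per_kg=None`` returns the per-hydrocarbon column mean,
    i.e. the average of the four dose-level means (control included) — the
    "average" row of the report tables.
    """
    sel = records[(records["analyte"] == analyte) & (records["hydrocarbon"] == hydrocarbon)]
    if dose_mg_per_kg is not None:
        sel = sel[sel["dose_mg_per_kg"] == dose_mg_per_kg]
        if len(sel) == 0:
            raise EmptyGroupError(
                f"no records for {analyte}/{hydrocarbon}/{dose_mg_per_kg} mg kg-1"
            )
        return float(sel["value"].mean())
    if len(sel) == 0:
        raise EmptyGroupError(f"no records for {analyte}/{hydrocarbon}")
    return float(sel.groupby("dose_mg_per_kg")["value"].mean().mean())


def fold_change(treated_mean: float, control_mean: float) -> float:
    """Ratio of a treated mean to the dose-0 control mean of the same column."""
    if not control_mean > 0:
        raise InvalidControlError(f"control mean must be > 0, got {control_mean!r}")
    return treated_mean / control_mean


def pearson_dose_correlation(
    records: pd.DataFrame,
    analyte: str,
    hydrocarbon: str,
    level: str = "auto",
) -> float:
    """Pearson r between dose and value.

    ``level`` selects the observations: ``"replicate"`` correlates every
    replicate-level record with its dose, ``"mean"`` the per-dose means;
    ``"auto"`` uses replicates when more than one exists per dose and means
    otherwise.
    """
    sel = records[(records["analyte"] == analyte) & (records["hydrocarbon"] == hydrocarbon)]
    if level not in ("auto", "replicate", "mean"):
        raise ValueError(f"unknown level {level!r}")
    if level == "auto":
        reps = sel.groupby("dose_mg_per_kg")["value"].size()
        level = "replicate" if len(reps) and reps.max() > 1 else "mean"
    if level == "mean":
        per_dose = sel.groupby("dose_mg_per_kg")["value"].mean()
        doses, values = per_dose.index.to_numpy(float), per_dose.to_numpy(float)
    else:
        doses = sel["dose_mg_per_kg"].to_numpy(float)
        values = sel["value"].to_numpy(float)
    if len(np.unique(doses)) < 3:
        raise UndefinedCorrelationError("need data at >= 3 dose levels")
    if np.ptp(values) == 0 or np.ptp(doses) == 0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    return float(stats.pearsonr(doses, values).statistic)


def mean_table(records: pd.DataFrame, analyte: str) -> pd.DataFrame:
    """Wide dose x hydrocarbon table of treatment means for one analyte."""
    sel = records[records["analyte"] == analyte]
    if len(sel) == 0:
        raise EmptyGroupError(f"no records for analyte {analyte!r}")
    return sel.pivot_table(
        index="dose_mg_per_kg", columns="hydrocarbon", values="value", aggfunc="mean"
    )


def resistance_table(records: pd.DataFrame, level: str = "mean") -> pd.DataFrame:
    """RS per analyte x hydrocarbon x non-zero dose.

    ``level="mean"`` (default) computes RS from treatment means, matching
    how the report tables are built; ``level="replicate"`` pairs replicate k
    of the treated cell with replicate k of the control and averages the
    per-pair RS values.
    """
    if level not in ("mean", "replicate"):
        raise ValueError(f"unknown level {level!r}")
    rows = []
    for (analyte, hc), grp in records.groupby(["analyte", "hydrocarbon"], sort=False):
        control = grp[grp["dose_mg_per_kg"] == 0]
        if len(control) == 0:
            raise EmptyGroupError(f"no dose-0 control for {analyte}/{hc}")
        c0 = float(control["value"].mean())
        for dose, cell in grp[grp["dose_mg_per_kg"] > 0].groupby("dose_mg_per_kg"):
            p = float(cell["value"].mean())
            if level == "mean":
                rs = resistance_index(c0, p)
            else:
                ctrl_vals = control.sort_values("replicate")["value"].to_numpy(float)
                cell_vals = cell.sort_values("replicate")["value"].to_numpy(float)
                k = min(len(ctrl_vals), len(cell_vals))
                rs = float(
                    np.mean([resistance_index(ctrl_vals[i], cell_vals[i]) for i in range(k)])
                )
            rows.append(
                {
                    "analyte": analyte,
                    "hydrocarbon": hc,
                    "dose_mg_per_kg": int(dose),
                    "c0": c0,
                    "p_t0": p,
                    "d0": c0 - p,
                    "rs": rs,
                }
            )
    return pd.DataFrame(
        rows, columns=["analyte", "hydrocarbon", "dose_mg_per_kg", "c0", "p_t0", "d0", "rs"]
    )


def dose_response_summary(records: pd.DataFrame, level: str = "auto") -> pd.DataFrame:
    """Per analyte x hydrocarbon: dose means, column mean, fold-changes, r.

    Fold-changes use the dose-0 mean of the same hydrocarbon column as the
    control; the correlation level follows :func:`pearson_dose_correlation`.
    """
    rows = []
    for (analyte, hc), grp in records.groupby(["analyte", "hydrocarbon"], sort=False):
        per_dose = grp.groupby("dose_mg_per_kg")["value"].mean()
        if 0 not in per_dose.index:
            raise EmptyGroupError(f"no dose-0 control for {analyte}/{hc}")
        c0 = float(per_dose.loc[0])
        col_mean = float(per_dose.mean())
        try:
            r = pearson_dose_correlation(records, analyte, hc, level=level)
        except UndefinedCorrelationError:
            r = float("nan")
        for dose, m in per_dose.items():
            rows.append(
                {
                    "analyte": analyte,
                    "hydrocarbon": hc,
                    "dose_mg_per_kg": int(dose),
                    "mean": float(m),
                    "column_mean": col_mean,
                    "fold_change_vs_control": fold_change(float(m), c0),
                    "column_mean_fold_change": fold_change(col_mean, c0),
                    "pearson_r": r,
                }
            )
    return pd.DataFrame(rows)
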