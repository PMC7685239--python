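"""Per-subject exposure metrics and trial-level summary tables.

Derives dose-normalized exposure metrics (AUC/D, Cmax/D, Ctrough/D, tmax,
t1/2, CL/F, Vz/F) from empirical-Bayes individual parameters, summarises
them with geometric statistics by age group, classifies steady-state AUC
against the adult reference interval, and tabulates titrated dose levels.

Geometric statistics follow the conventional definitions
``geomean = exp(mean(log x))`` and
``geoCV% = sqrt(exp(sd(log x)^2) - 1) * 100`` with the n-1 sample SD;
``tmax`` is summarised as median (range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .covariate_model import age_group_label
from .structural_pk import (
    DoseRegimen,
    StructuralParams,
    ValidationError,
    secondary_params,
)

__all__ = [
    "PosthocRow",
    "AdultReference",
    "ADULT_REFERENCE",
    "geometric_stats",
    "derive_posthoc",
    "posthoc_table",
    "adult_range_fraction",
    "dosing_summary",
    "summarize_by_age",
]


@dataclass(frozen=True)
class PosthocRow:
    """Derived exposure metrics for one subject at the sampled dose."""

    id: str
    age_group: str
    dose_mg: float
    auc_per_dose: float  # ng*h/mL per mg
    cmax_per_dose: float  # ng/mL per mg
    ctrough_per_dose: float  # ng/mL per mg
    tmax: float  # h
    t_half: float  # h
    cl_f: float  # L/h
    vz_f: float  # L

    def __post_init__(self) -> None:
        vals = (self.auc_per_dose, self.cmax_per_dose, self.ctrough_per_dose,
                self.tmax, self.t_half, self.cl_f, self.vz_f, self.dose_mg)
        if any(not v > 0 for v in vals):
            raise ValidationError(f"subject {self.id}: non-positive metric")
        if abs(self.vz_f - self.cl_f * self.t_half / math.log(2)) > 1e-6 * self.vz_f:
            raise ValidationError(
                f"subject {self.id}: vz_f inconsistent with cl_f * t_half / ln 2"
            )


@dataclass(frozen=True)
class AdultReference:
    """Adult steady-state AUC reference interval at the 10 mg dose."""

    target: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.target < self.upper:
            raise ValidationError("reference must satisfy lower < target < upper")


#: adult 10 mg suspension reference: target steady-state AUC with the
#: 5th-95th percentile interval (ng*h/mL)
ADULT_REFERENCE = AdultReference(target=889.0, lower=421.0, upper=1896.0)


def geometric_stats(values) -> tuple[float, float]:
    """Geometric mean and geometric CV% of strictly positive values.

    CV% requires at least two values and uses the n-1 sample SD on the log
    scale; with a single value it is returned as 0.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("geometric_stats requires at least one value")
    bad = np.nonzero(~(arr > 0))[0]
    if bad.size:
        raise ValidationError(f"non-positive value at position {bad[0]}")
    logs = np.log(arr)
    gmean = float(np.exp(np.mean(logs)))
    if arr.size < 2:
        return gmean, 0.0
    sd = float(np.std(logs, ddof=1))
    gcv = math.sqrt(math.exp(sd**2) - 1.0) * 100.0
    return gmean, gcv


def derive_posthoc(
    subject_id: str,
    age: float,
    params: StructuralParams,
    dose_mg: float,
    tau: float = 24.0,
) -> PosthocRow:
    """Exposure metrics for one subject from individual parameters and the
    steady-state dose at PK sampling; "/D" metrics are dose-normalized."""
    if not dose_mg > 0:
        raise ValidationError(f"subject {subject_id}: missing dose at sampling")
    sec = secondary_params(params, DoseRegimen.steady_state(dose_mg, tau))
    return PosthocRow(
        id=subject_id,
        age_group=age_group_label(age),
        dose_mg=dose_mg,
        auc_per_dose=sec.auc_inf_per_dose,
        cmax_per_dose=sec.cmax / dose_mg,
        ctrough_per_dose=sec.ctrough / dose_mg,
        tmax=sec.tmax,
        t_half=sec.t_half,
        cl_f=params.cl_f,
        vz_f=sec.vz_f,
    )


def posthoc_table(rows: list[PosthocRow]) -> pd.DataFrame:
    return pd.DataFrame([row.__dict__ for row in rows])


def adult_range_fraction(aucs, ref: AdultReference = ADULT_REFERENCE) -> float:
    """Fraction of steady-state AUC values inside the closed adult reference
    interval ``[lower, upper]``."""
    arr = np.asarray(list(aucs), dtype=float)
    if arr.size == 0:
        raise ValidationError("adult_range_fraction requires at least one AUC")
    if np.any(~(arr > 0)):
        raise ValidationError("AUC values must be positive")
    inside = (arr >= ref.lower) & (arr <= ref.upper)
    return float(np.mean(inside))


def _round_half_up(x: float, digits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{digits}"), ROUND_HALF_UP))


def dosing_summary(assignments: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per visit x dose level x group.

    ``assignments`` needs columns ``group``, ``visit``, ``level`` and one
    row per subject per visit; percentages use the group size at that visit
    as the denominator and are rounded half-up to one decimal.  A pooled
    ``at PK sampling`` row is computed from the visit labelled
    ``pk_sampling`` when present.
    """
    if assignments.empty:
        raise ValidationError("dosing_summary requires at least one assignment")
    out = []
    for (visit, group), g in assignments.groupby(["visit", "group"], sort=False):
        denom = len(g)
        for level, cnt in g["level"].value_counts().sort_index().items():
            out.append(dict(
                visit=visit, group=group, level=level, n=int(cnt),
                pct=_round_half_up(100.0 * cnt / denom),
            ))
    return pd.DataFrame(out)


def summarize_by_age(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = (
        "auc_per_dose", "cmax_per_dose", "tmax", "t_half", "cl_f", "vz_f",
        "ctrough_per_dose",
    ),
    group_col: str = "age_group",
) -> pd.DataFrame:
    """Geometric mean (CV%) per metric per age group, plus a pooled row.

    ``tmax`` is summarised as median (min-max).  Groups with no subjects
    are omitted.
    """
    if table.empty:
        raise ValidationError("summarize_by_age requires at least one row")
    groups = [(g, sub) for g, sub in table.groupby(group_col, sort=True)]
    groups.append(("all", table))
    out = []
    for label, sub in groups:
        row: dict[str, object] = {"group": label, "n": len(sub)}
        for mcol in metrics:
            vals = sub[mcol].to_numpy(float)
            if mcol == "tmax":
                row["tmax_median"] = float(np.median(vals))
                row["tmax_min"] = float(np.min(vals))
                row["tmax_max"] = float(np.max(vals))
            else:
                gm, gcv = geometric_stats(vals)
                row[f"{mcol}_gmean"] = gm
                row[f"{mcol}_gcv"] = gcv
        out.append(row)
    return pd.DataFrame(out)
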