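"""Post-CPB acute kidney injury outcomes and KDIGO staging.

Five outcomes are derived per operation from the 48-hour postoperative
window:

1. creatinine ratio — postoperative / baseline serum creatinine;
2. hours with urine output below 0.5 ml/kg/h;
3. hours with urine output below 0.3 ml/kg/h;
4. KDIGO ordinal stage 0-3, the maximum of a creatinine stage and a
   urine-output stage;
5. KDIGO binary ("severe AKI"): 1 iff the ordinal stage is 2 or 3.

Stage cutoffs are kept in a single editable table.  Stage 1 encodes the
rule: creatinine ratio in [1.5, 2.0) or strictly more than 6 and fewer
than 12 hours below 0.5 ml/kg/h.  Stages 2-3 follow the KDIGO
guideline: ratio in [2.0, 3.0) / >= 3.0, >= 12 h below 0.5, >= 24 h
below 0.3.  Boundary conventions (half-open ratio intervals aligned at
the stage-2 lower bound, the open (6, 12) hour interval) are explicit
choices documented in docs/methods.md.  The guideline's anuria
criterion is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WINDOW_HOURS = 48

#: Editable stage cutoffs; each rule maps measurements to True at that stage.
KDIGO_STAGE_RULES = {
    3: lambda ratio, h05, h03: ratio >= 3.0 or h03 >= 24,
    2: lambda ratio, h05, h03: ratio >= 2.0 or h05 >= 12,
    1: lambda ratio, h05, h03: ratio >= 1.5 or (6 < h05 < 12),
}


@dataclass(frozen=True)
class AKIOutcomes:
    creatinine_ratio: float
    hours_below_05: float
    hours_below_03: float
    kdigo_ordinal: int
    kdigo_binary: int

    def __post_init__(self) -> None:
        if self.hours_below_03 > self.hours_below_05:
            raise ValueError("hours below 0.3 cannot exceed hours below 0.5")
        if self.kdigo_binary != int(self.kdigo_ordinal >= 2):
            raise ValueError("binary/ordinal KDIGO inconsistency")


OUTCOME_COLUMNS = [
    "creatinine_ratio",
    "hours_below_05",
    "hours_below_03",
    "kdigo_ordinal",
    "kdigo_binary",
]


def creatinine_ratio(postop: float, baseline: float) -> float:
    """Ratio of postoperative to baseline serum creatinine."""
    if baseline <= 0:
        raise ValueError("baseline creatinine must be positive")
    return postop / baseline


def urine_low_hours(series, threshold: float) -> int:
    """Hours (of the 48-hour window) with urine output strictly below
    ``threshold`` ml/kg/h."""
    series = np.asarray(series, dtype=np.float64)
    if series.shape != (WINDOW_HOURS,):
        raise ValueError(f"urine series must have {WINDOW_HOURS} hourly entries")
    if np.any(series < 0):
        raise ValueError("urine output cannot be negative")
    return int(np.sum(series < threshold))


def kdigo_ordinal(ratio: float, hours05: float, hours03: float) -> int:
    """KDIGO stage 0-3: the highest stage whose creatinine or
    urine-output criterion is met."""
    if ratio <= 0:
        raise ValueError("creatinine ratio must be positive")
    if not (0 <= hours03 <= hours05 <= WINDOW_HOURS):
        raise ValueError("hour counts must satisfy 0 <= h03 <= h05 <= 48")
    for stage in (3, 2, 1):
        if KDIGO_STAGE_RULES[stage](ratio, hours05, hours03):
            return stage
    return 0


def kdigo_binary(ordinal: int) -> int:
    """Severe-AKI indicator: 1 iff the ordinal stage is 2 or 3."""
    if ordinal not in (0, 1, 2, 3):
        raise ValueError(f"KDIGO ordinal stage must be 0-3, got {ordinal!r}")
    return int(ordinal >= 2)


def compute_outcomes(ratio: float, series) -> AKIOutcomes:
    """All five outcomes from a creatinine ratio and an hourly urine series."""
    h05 = urine_low_hours(series, 0.5)
    h03 = urine_low_hours(series, 0.3)
    ordinal = kdigo_ordinal(ratio, h05, h03)
    return AKIOutcomes(
        creatinine_ratio=float(ratio),
        hours_below_05=h05,
        hours_below_03=h03,
        kdigo_ordinal=ordinal,
        kdigo_binary=kdigo_binary(ordinal),
    )


def outcomes_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-row outcomes keyed by patient_id.

    Expects ``creatinine_postop``, ``creatinine_baseline`` and a
    ``urine_series`` column holding 48-entry sequences (lists or
    JSON-decoded arrays).
    """
    records = []
    for _, row in cohort.iterrows():
        ratio = creatinine_ratio(row["creatinine_postop"], row["creatinine_baseline"])
        out = compute_outcomes(ratio, row["urine_series"])
        records.append(
            {
                "patient_id": row["patient_id"],
                "creatinine_ratio": out.creatinine_ratio,
                "hours_below_05": out.hours_below_05,
                "hours_below_03": out.hours_below_03,
                "kdigo_ordinal": out.kdigo_ordinal,
                "kdigo_binary": out.kdigo_binary,
            }
        )
    return pd.DataFrame.from_records(records)
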