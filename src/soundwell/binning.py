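"""Age and BMI discretization shared by the generator and preprocessing.

Bins are left-closed/right-open, except that the last interior bin is closed
at its upper edge so the open-ended top bin starts strictly above it
(age 60.0 -> "50-60", BMI 35.0 -> "30-35").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AGE_LEVELS = ["age_below_30", "age_30_40", "age_40_50", "age_50_60", "age_above_60"]
BMI_LEVELS = ["bmi_below_25", "bmi_25_30", "bmi_30_35", "bmi_above_35"]

AGE_LABELS = {
    "age_below_30": "Below 30",
    "age_30_40": "30-40",
    "age_40_50": "40-50",
    "age_50_60": "50-60",
    "age_above_60": "Above 60",
}
BMI_LABELS = {
    "bmi_below_25": "Below 25",
    "bmi_25_30": "25-30",
    "bmi_30_35": "30-35",
    "bmi_above_35": "Above 35",
}


def _index_of(values):
    return values.index if isinstance(values, (pd.Series, pd.DataFrame)) else None


def age_group(age) -> pd.Series:
    a = np.asarray(age, dtype=float)
    out = np.select(
        [a < 30, a < 40, a < 50, a <= 60],
        AGE_LEVELS[:4],
        AGE_LEVELS[4],
    )
    return pd.Series(out, index=_index_of(age), name="age_group")


def bmi_group(bmi) -> pd.Series:
    b = np.asarray(bmi, dtype=float)
    out = np.select(
        [b < 25, b < 30, b <= 35],
        BMI_LEVELS[:3],
        BMI_LEVELS[3],
    )
    return pd.Series(out, index=_index_of(bmi), name="bmi_group")
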