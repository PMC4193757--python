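"""Bundled reference cohort of per-case box-counting dimensions.

A published 46-case cervical biopsy cohort reports one d_BOX value per
case (the median over that patient's regions of interest), grouped by the
pathologist's grade: normal epithelium (n=15), CIN 1 (n=8), CIN 2 (n=6)
and CIN 3 (n=17).  Values are printed to two decimals.  The low-grade
group is CIN 1; the high-grade group pools CIN 2 and CIN 3.

These values are the worked-example input for the statistics layer
(group summaries, ANOVA/Tukey, low-vs-high t-test, nearest-median
classification).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_dbox_values", "reference_dbox_table", "reference_medians"]

_REFERENCE_DBOX = {
    "normal": [1.67, 1.67, 1.67, 1.65, 1.62, 1.61, 1.60, 1.59,
               1.58, 1.57, 1.56, 1.55, 1.52, 1.51, 1.46],
    "CIN1": [1.74, 1.67, 1.66, 1.64, 1.62, 1.58, 1.56, 1.55],
    "CIN2": [1.78, 1.77, 1.72, 1.70, 1.68, 1.63],
    "CIN3": [1.95, 1.87, 1.86, 1.83, 1.82, 1.82, 1.81, 1.80, 1.80,
             1.79, 1.79, 1.78, 1.77, 1.77, 1.75, 1.75, 1.66],
}


def reference_dbox_values() -> dict[str, list[float]]:
    """Per-grade lists of per-case d_BOX values (fresh copies)."""
    return {g: list(v) for g, v in _REFERENCE_DBOX.items()}


def reference_dbox_table() -> pd.DataFrame:
    """The cohort as a tidy table with columns case_id, grade, dbox."""
    rows = [
        {"case_id": f"{g}_{i:02d}", "grade": g, "dbox": v}
        for g, vals in _REFERENCE_DBOX.items()
        for i, v in enumerate(vals)
    ]
    return pd.DataFrame(rows)


def reference_medians() -> dict[str, float]:
    """Per-grade median d_BOX of the reference cohort."""
    import numpy as np

    return {g: float(np.median(v)) for g, v in _REFERENCE_DBOX.items()}
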