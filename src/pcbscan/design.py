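"""Fixed-effect design construction from a cohort table.

Categoricals enter as dummy columns with the first level dropped; columns
that are constant within the analyzed subset (e.g. sex inside a sex stratum,
cancer type inside the control stratum) are dropped automatically and
recorded, so the same scan specification works unchanged across strata.
Granulocytes are excluded from the WBC covariates by default: the six
fractions live on the simplex, and dropping the dominant type removes the
structural collinearity with the intercept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import CELL_TYPES, PCB_COLUMNS

DEFAULT_CONFOUNDERS: tuple[str, ...] = (
    "cohort_label",
    "sex",
    "cancer_type",
    "age",
    "bmi",
    "smoking",
)

EXPOSURE_TRANSFORMS = ("none", "log", "zscore", "log+zscore")


def transform_exposure(x, how: str = "log+zscore") -> np.ndarray:
    """Apply the scan's exposure transform (serum levels are right-skewed)."""
    x = np.asarray(x, dtype=float)
    if how not in EXPOSURE_TRANSFORMS:
        raise ValueError(f"unknown exposure transform {how!r}")
    if "log" in how:
        if np.any(x <= 0):
            raise ValueError("log transform requires strictly positive exposures")
        x = np.log(x)
    if "zscore" in how:
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError("cannot z-score a constant exposure")
        x = (x - x.mean()) / sd
    return x


def confounder_matrix(
    cohort: pd.DataFrame,
    confounders=DEFAULT_CONFOUNDERS,
    include_wbc: bool = True,
    drop_granulocytes: bool = True,
    exclude_cell_types=(),
) -> tuple[pd.DataFrame, list[str]]:
    """Numeric confounder design (no intercept) and the dropped-column log."""
    pieces = []
    for name in confounders:
        col = cohort[name]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            pieces.append(col.astype(float).rename(name).to_frame())
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
            pieces.append(dummies.astype(float))
    if include_wbc:
        cells = [c for c in CELL_TYPES if c not in set(exclude_cell_types)]
        if drop_granulocytes and "Gran" in cells:
            cells.remove("Gran")
        pieces.append(cohort[cells].astype(float))
    design = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=cohort.index)
    dropped = [c for c in design.columns if design[c].nunique() <= 1]
    return design.drop(columns=dropped), dropped


def pcb_column(congener) -> str:
    name = f"PCB{int(congener)}"
    if name not in PCB_COLUMNS:
        raise ValueError(f"unknown PCB congener {congener!r}")
    return name
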