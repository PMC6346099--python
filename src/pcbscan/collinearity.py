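"""Variance-inflation-factor screening of candidate model covariates.

VIF_j = 1 / (1 - R^2_j), with R^2_j from the ordinary regression of column j
on all other columns plus an intercept.  Covariates exceeding the threshold
(default 4) are removed worst-first, recomputing after each removal, until
every retained covariate sits below the threshold — encoding the working
rule that strongly co-measured covariates (e.g. the individual PCB congeners,
or granulocytes with the remaining WBC fractions) must not share a model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_VIF_THRESHOLD = 4.0
_EXACT_TOL = 1e-12


@dataclass
class VIFReport:
    vif: pd.Series                       # +inf flags exact collinearity
    retained: tuple[str, ...]
    excluded: tuple[str, ...] = ()
    threshold: float | None = None
    removal_order: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "vif": {k: (None if np.isinf(v) else float(v)) for k, v in self.vif.items()},
            "retained": list(self.retained),
            "excluded": list(self.excluded),
            "threshold": self.threshold,
            "removal_order": list(self.removal_order),
        }


def _validate(design: pd.DataFrame) -> np.ndarray:
    X = design.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values")
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 covariate columns")
    if n <= p:
        raise ValueError(f"need more rows than columns (n={n}, p={p})")
    const = np.where(X.std(axis=0) == 0)[0]
    if const.size:
        names = [str(design.columns[j]) for j in const]
        raise ValueError(f"constant column(s): {names}")
    return X


def compute_vif(design: pd.DataFrame) -> VIFReport:
    """VIF of every column of a numeric design matrix.

    Exact collinearity is reported as +inf, not raised.
    """
    X = _validate(design)
    n, p = X.shape
    ones = np.ones((n, 1))
    values = np.empty(p)
    for j in range(p):
        y = X[:, j]
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        rss = float(np.sum((y - others @ coef) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        frac = rss / tss
        values[j] = np.inf if frac < _EXACT_TOL else 1.0 / frac
    vif = pd.Series(values, index=design.columns)
    return VIFReport(vif=vif, retained=tuple(map(str, design.columns)))


def screen_variables(
    design: pd.DataFrame, threshold: float = DEFAULT_VIF_THRESHOLD
) -> VIFReport:
    """Iteratively drop the worst-VIF covariate until all are below threshold.

    Ties (including several +inf) are broken by column order.  The terminal
    report carries the surviving VIFs, the exclusion list and the removal
    order.
    """
    if threshold <= 1.0:
        raise ValueError("threshold must exceed 1 (the VIF lower bound)")
    current = design.copy()
    removed: list[str] = []
    while True:
        if current.shape[1] < 2:
            vif = pd.Series(np.ones(current.shape[1]), index=current.columns)
            break
        vif = compute_vif(current).vif
        worst = float(vif.max())
        if worst < threshold:
            break
        name = str(vif.idxmax())  # idxmax returns the first maximum
        removed.append(name)
        current = current.drop(columns=[name])
    return VIFReport(
        vif=vif,
        retained=tuple(map(str, current.columns)),
        excluded=tuple(removed),
        threshold=float(threshold),
        removal_order=tuple(removed),
    )
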