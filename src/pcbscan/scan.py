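"""Transcriptome-wide mixed-model scans.

``scan`` tests one exposure (a PCB congener, or any cohort covariate) per
transcript; ``interaction_scan`` tests the product of one congener and one
WBC fraction, always keeping both main effects in the full model.  Each
transcript is tested by an ML likelihood-ratio test between the full model
and the model without the variable of interest, both carrying the scan-date
random intercept; Benjamini-Hochberg correction is applied within the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import lmm
from .design import (
    DEFAULT_CONFOUNDERS,
    confounder_matrix,
    pcb_column,
    transform_exposure,
)
from .lmm import bh_fdr, f2_for_power
from .simulate import CELL_TYPES

#: variance below which a transcript is treated as degenerate and skipped
DEGENERATE_VAR = 1e-12


@dataclass(frozen=True)
class ScanSpec:
    """Configuration of one scan.

    ``confounders`` name cohort columns; WBC fractions enter as additional
    confounders (granulocytes excluded by default).  ``fdr_alpha = 0.2`` is
    the conventional lenient preset for exploratory scans.
    """

    confounders: tuple[str, ...] = DEFAULT_CONFOUNDERS
    include_wbc: bool = True
    drop_granulocytes: bool = True
    batch: str = "batch"
    fdr_alpha: float = 0.05
    exposure_transform: str = "log+zscore"
    test: str = "lrt"               # or "wald"
    #: reference distribution for the LRT statistic: "f" maps
    #: 2*dll = n*log(1 + df*F/(n-p)) back to an F(df, n-p) quantile, which is
    #: exact when the batch variance vanishes and keeps desk-scale scans
    #: calibrated; "chisq" is the large-sample chi-square reference.
    lrt_reference: str = "f"

    def __post_init__(self):
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.test not in ("lrt", "wald"):
            raise ValueError("test must be 'lrt' or 'wald'")
        if self.lrt_reference not in ("f", "chisq"):
            raise ValueError("lrt_reference must be 'f' or 'chisq'")

    def lenient(self) -> "ScanSpec":
        return replace(self, fdr_alpha=0.2)


@dataclass
class ScanResult:
    """Per-transcript results of one scan configuration."""

    table: pd.DataFrame             # transcript_id, beta, lrt_stat, p, q, converged
    spec: ScanSpec
    variable: str
    n: int
    stratum: str = ""
    skipped: tuple[str, ...] = field(default_factory=tuple)

    @property
    def significant(self) -> set[str]:
        t = self.table
        return set(t.index[t["significant"]])

    def __len__(self) -> int:
        return len(self.table)


def _align(expression: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    subjects = cohort["subject_id"].astype(str)
    missing = set(subjects) - set(map(str, expression.columns))
    if missing:
        raise ValueError(
            f"{len(missing)} cohort subjects absent from expression matrix "
            f"(e.g. {sorted(missing)[:3]})"
        )
    return expression.loc[:, subjects.to_numpy()]


def _run_scan(
    expression: pd.DataFrame,
    cohort: pd.DataFrame,
    full_X: pd.DataFrame,
    voi_cols: list[str],
    spec: ScanSpec,
    variable: str,
    stratum: str = "",
) -> ScanResult:
    Y = _align(expression, cohort).to_numpy(float)
    codes, _ = pd.factorize(cohort[spec.batch])
    n, p = full_X.shape
    if n < p + 2:
        raise ValueError(f"stratum too small for the design (n={n}, p={p})")
    if np.linalg.matrix_rank(full_X.to_numpy(float)) < p:
        raise ValueError("singular fixed-effect design")

    var = Y.var(axis=1)
    keep = var > DEGENERATE_VAR
    skipped = tuple(expression.index[~keep])
    Yk = Y[keep]

    X_full = full_X.to_numpy(float)
    X_red = full_X.drop(columns=voi_cols).to_numpy(float)
    df = len(voi_cols)

    full = lmm._profile_ml(Yk, X_full, codes)
    if spec.test == "lrt":
        red = lmm._profile_ml(Yk, X_red, codes)
        stat = np.maximum(0.0, 2.0 * (full["loglik"] - red["loglik"]))
        if spec.lrt_reference == "f":
            fstat = np.expm1(stat / n) * (n - p) / df
            pvals = stats.f.sf(fstat, df, n - p)
        else:
            pvals = stats.chi2.sf(stat, df)
        converged = full["converged"] & red["converged"]
    else:
        stat, pvals, converged = _wald(full, Yk, X_full, codes, full_X, voi_cols)
    pvals = np.where(converged, pvals, np.nan)

    j = full_X.columns.get_loc(voi_cols[-1])
    beta = full["beta"][:, j]
    q, sig = bh_fdr(pvals, spec.fdr_alpha)

    table = pd.DataFrame(
        {
            "beta": beta,
            "lrt_stat": stat,
            "p": pvals,
            "q": q,
            "significant": sig,
            "converged": converged,
        },
        index=pd.Index(expression.index[keep], name="transcript_id"),
    )
    return ScanResult(
        table=table, spec=spec, variable=variable, n=n, stratum=stratum,
        skipped=skipped,
    )


def _wald(full, Y, X_full, codes, full_frame, voi_cols):
    """Wald z-test on the variable-of-interest coefficient (sensitivity path)."""
    pre = lmm._Profiled(Y, X_full, codes)
    beta, sigma2_e, ll, G = pre.solve_at(full["lam"])
    j = full_frame.columns.get_loc(voi_cols[-1])
    var = np.linalg.inv(G)[:, j, j] * sigma2_e
    z = beta[:, j] / np.sqrt(np.maximum(var, 1e-300))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z**2, p, full["converged"]


def scan(
    expression: pd.DataFrame,
    cohort: pd.DataFrame,
    variable: str,
    spec: ScanSpec | None = None,
    stratum: str = "",
) -> ScanResult:
    """Per-transcript LMM scan of one exposure variable.

    ``variable`` is a cohort column (typically one PCB congener column, the
    congeners being modelled one at a time after collinearity screening).
    """
    spec = spec or ScanSpec()
    conf, _ = confounder_matrix(
        cohort, spec.confounders, spec.include_wbc, spec.drop_granulocytes
    )
    if variable in conf.columns:
        raise ValueError(f"variable of interest {variable!r} is also a confounder")
    voi = transform_exposure(cohort[variable], spec.exposure_transform)
    X = pd.DataFrame({"Intercept": np.ones(len(cohort))}, index=cohort.index)
    X[variable] = voi
    X = pd.concat([X, conf.set_axis(X.index)], axis=1)
    return _run_scan(expression, cohort, X, [variable], spec, variable, stratum)


def interaction_scan(
    expression: pd.DataFrame,
    cohort: pd.DataFrame,
    pcb,
    wbc: str,
    spec: ScanSpec | None = None,
    stratum: str = "",
) -> ScanResult:
    """Per-transcript scan of one PCB x WBC interaction.

    The full model carries the congener main effect, the cell-type fraction
    main effect and their product; the reduced model drops only the product,
    so the LRT has one degree of freedom.
    """
    spec = spec or ScanSpec()
    pcb_col = pcb_column(pcb)
    if wbc not in CELL_TYPES:
        raise ValueError(f"unknown cell type {wbc!r}; known: {CELL_TYPES}")
    conf, _ = confounder_matrix(
        cohort, spec.confounders, spec.include_wbc, spec.drop_granulocytes,
        exclude_cell_types=(wbc,),
    )
    p = transform_exposure(cohort[pcb_col], spec.exposure_transform)
    w = cohort[wbc].to_numpy(float)
    inter = f"{pcb_col}x{wbc}"
    X = pd.DataFrame({"Intercept": np.ones(len(cohort))}, index=cohort.index)
    X[pcb_col] = p
    X[wbc] = w
    X[inter] = p * w
    X = pd.concat([X, conf.set_axis(X.index)], axis=1)
    return _run_scan(expression, cohort, X, [inter], spec, inter, stratum)


def interaction_effect_for_power(
    cohort: pd.DataFrame,
    pcb,
    wbc: str,
    spec: ScanSpec | None = None,
    power: float = 0.8,
    alpha: float = 0.05,
    sigma2_e: float = 1.0,
) -> float:
    """Interaction coefficient giving the requested per-test power.

    Converts the Cohen f2 solving ``power_linear_model`` into a raw
    coefficient via the realized design: beta = sqrt(f2 * sigma2_e / v_r)
    with v_r the variance of the interaction column after residualizing on
    all other full-model fixed effects.
    """
    spec = spec or ScanSpec()
    pcb_col = pcb_column(pcb)
    conf, _ = confounder_matrix(
        cohort, spec.confounders, spec.include_wbc, spec.drop_granulocytes,
        exclude_cell_types=(wbc,),
    )
    p = transform_exposure(cohort[pcb_col], spec.exposure_transform)
    w = cohort[wbc].to_numpy(float)
    x = p * w
    others = np.column_stack(
        [np.ones(len(cohort)), p, w, conf.to_numpy(float)]
    )
    coef, *_ = np.linalg.lstsq(others, x, rcond=None)
    resid = x - others @ coef
    v_r = float(np.mean(resid**2))
    n = len(cohort)
    p_full = others.shape[1] + 1
    f2 = f2_for_power(1, n - p_full, power, alpha)
    return float(np.sqrt(f2 * sigma2_e / v_r))
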