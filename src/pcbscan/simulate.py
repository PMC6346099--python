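"""Synthetic cohort, exposure, blood-composition and expression generators.

This module emulates the statistical structure of a prospective two-cohort
lymphoma case-control study with serum PCB measurements: correlated
log-normal exposures for six congeners (118, 138, 153, 156, 170, 180) with a
female shift on the dioxin-like-leaning subset, Dirichlet white-blood-cell
(WBC) fractions over six cell types, a scan-date batch random intercept on
expression, and sparse planted exposure main / exposure-by-cell-type
interaction effects with known ground truth.

All generators are deterministic given their seed.  The generator targets
statistical structure (correlations, variance components, effect sparsity),
not the magnitudes or noise spectra of any real array platform.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CONGENERS: tuple[int, ...] = (118, 138, 153, 156, 170, 180)
PCB_COLUMNS: tuple[str, ...] = tuple(f"PCB{c}" for c in CONGENERS)
#: congeners whose serum levels run higher in females by default
SEX_SHIFTED_CONGENERS: tuple[int, ...] = (118, 156, 170, 180)

CELL_TYPES: tuple[str, ...] = ("NK", "B", "Mono", "Gran", "CD8T", "CD4T")

SMOKING_LEVELS: tuple[str, ...] = ("never", "former", "current")

#: fixed-effect (confounder) encoding order used by the expression generator
FE_NAMES: tuple[str, ...] = (
    "cohort_EPIC",
    "sex_M",
    "cancer_lymphoma",
    "age_z",
    "bmi_z",
    "smoking_former",
    "smoking_current",
)


def pcb_index(congener: int) -> int:
    """Position of a congener in the fixed PCB order."""
    try:
        return CONGENERS.index(int(congener))
    except ValueError:
        raise ValueError(f"unknown PCB congener {congener!r}; known: {CONGENERS}")


def cell_index(cell_type: str) -> int:
    try:
        return CELL_TYPES.index(cell_type)
    except ValueError:
        raise ValueError(f"unknown cell type {cell_type!r}; known: {CELL_TYPES}")


@dataclass(frozen=True)
class CohortConfig:
    """Distributional parameters of the synthetic cohort.

    Exposures are log-normal per congener with an equicorrelated Gaussian
    copula on the log scale (serum congeners are strongly co-accumulating).
    ``female_shift_sd`` is applied additively on the log scale, in units of
    the congener's log-SD, to :data:`SEX_SHIFTED_CONGENERS` for females.
    Follow-up time (years to diagnosis for future cases) is truncated normal.
    """

    female_fraction: float = 0.5
    age_mean: float = 53.3
    age_sd: float = 7.8
    bmi_mean: float = 26.0
    bmi_sd: float = 4.0
    smoking_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    # log-scale locations, arbitrary mass/volume units; congener order as CONGENERS
    pcb_log_mean: tuple[float, ...] = (3.0, 4.3, 4.8, 2.5, 3.6, 4.4)
    pcb_log_sd: tuple[float, ...] = (0.5, 0.5, 0.5, 0.5, 0.5, 0.5)
    pcb_corr: float = 0.6
    female_shift_sd: float = 0.3
    # Dirichlet concentration: mean fractions (.07,.05,.08,.60,.08,.12), precision 60
    wbc_concentration: tuple[float, ...] = (4.2, 3.0, 4.8, 36.0, 4.8, 7.2)
    n_batches: int = 20
    epic_fraction: float = 0.5
    followup_mean: float = 5.96
    followup_sd: float = 2.85
    followup_bounds: tuple[float, float] = (2.0, 17.0)

    def validate(self) -> None:
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        for name in ("age_sd", "bmi_sd", "followup_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.pcb_log_mean) != 6 or len(self.pcb_log_sd) != 6:
            raise ValueError("pcb_log_mean / pcb_log_sd must have 6 entries")
        if any(s <= 0 for s in self.pcb_log_sd):
            raise ValueError("pcb_log_sd entries must be positive")
        if not -1.0 < self.pcb_corr < 1.0:
            raise ValueError("pcb_corr must be in (-1, 1)")
        if any(a <= 0 for a in self.wbc_concentration):
            raise ValueError("wbc_concentration entries must be positive")
        if abs(sum(self.smoking_probs) - 1.0) > 1e-9:
            raise ValueError("smoking_probs must sum to 1")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        lo, hi = self.followup_bounds
        if not 0 < lo < hi:
            raise ValueError("followup_bounds must satisfy 0 < lo < hi")


def generate_wbc_proportions(
    n: int, concentration=None, seed: int = 0
) -> np.ndarray:
    """Draw ``n`` WBC fraction vectors from a Dirichlet distribution.

    Rows are on the unit simplex (renormalized so sums are exact to 1e-12
    regardless of the magnitude spread of ``concentration``).
    """
    if concentration is None:
        concentration = CohortConfig().wbc_concentration
    conc = np.asarray(concentration, dtype=float)
    if conc.ndim != 1 or conc.size != len(CELL_TYPES):
        raise ValueError(f"concentration must be a vector of length {len(CELL_TYPES)}")
    if np.any(conc <= 0):
        raise ValueError("all concentration entries must be positive")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    rows = rng.dirichlet(conc, size=n)
    # guard degenerate concentrations where a whole row underflows to 0
    sums = rows.sum(axis=1)
    zero = sums <= 0
    if np.any(zero):
        rows[zero] = 0.0
        rows[zero, np.argmax(conc)] = 1.0
        sums = rows.sum(axis=1)
    return rows / sums[:, None]


def _batch_labels(n: int, n_batches: int, rng: np.random.Generator) -> np.ndarray:
    """Random batch assignment with at least 2 subjects per used level."""
    b = min(n_batches, max(1, n // 2))
    codes = np.concatenate(
        [np.repeat(np.arange(b), 2), rng.integers(0, b, size=n - 2 * b)]
    )
    rng.shuffle(codes)
    return np.array([f"B{c:02d}" for c in codes])


def generate_cohort(
    n: int = 512,
    n_cases: int = 217,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a subject-level cohort table.

    Columns: subject_id, cohort_label, sex, age, bmi, smoking, the six
    PCB columns, the six WBC fraction columns, batch, future_case,
    time_to_diagnosis (NaN for controls), cancer_type.

    The default sizes (512 subjects, 217 future lymphoma cases) match the
    study design this generator emulates.
    """
    config = config or CohortConfig()
    config.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= n_cases <= n:
        raise ValueError(f"n_cases ({n_cases}) must lie in [0, n] (n={n})")

    rng = np.random.default_rng(seed)
    subject_id = np.array([f"S{i:04d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    cohort_label = np.where(rng.random(n) < config.epic_fraction, "EPIC", "NSHDS")
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, size=n)
    smoking = rng.choice(SMOKING_LEVELS, size=n, p=config.smoking_probs)

    # correlated log-normal exposures via an equicorrelated Gaussian copula
    sd = np.asarray(config.pcb_log_sd)
    corr = np.full((6, 6), config.pcb_corr)
    np.fill_diagonal(corr, 1.0)
    z = rng.multivariate_normal(np.zeros(6), corr, size=n, method="cholesky")
    logx = np.asarray(config.pcb_log_mean) + z * sd
    shift_cols = [pcb_index(c) for c in SEX_SHIFTED_CONGENERS]
    logx[np.ix_(sex == "F", shift_cols)] += config.female_shift_sd * sd[shift_cols]
    pcb = np.exp(logx)

    wbc = generate_wbc_proportions(
        n, config.wbc_concentration, seed=int(rng.integers(0, 2**31 - 1))
    )
    batch = _batch_labels(n, config.n_batches, rng)

    future_case = np.zeros(n, dtype=bool)
    future_case[rng.permutation(n)[:n_cases]] = True
    lo, hi = config.followup_bounds
    a = (lo - config.followup_mean) / config.followup_sd
    b = (hi - config.followup_mean) / config.followup_sd
    ttd = np.full(n, np.nan)
    ttd[future_case] = stats.truncnorm.rvs(
        a, b, loc=config.followup_mean, scale=config.followup_sd,
        size=n_cases, random_state=rng,
    )

    frame = pd.DataFrame(
        {
            "subject_id": subject_id,
            "cohort_label": cohort_label,
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "smoking": smoking,
        }
    )
    for j, col in enumerate(PCB_COLUMNS):
        frame[col] = pcb[:, j]
    for j, col in enumerate(CELL_TYPES):
        frame[col] = wbc[:, j]
    frame["batch"] = batch
    frame["future_case"] = future_case
    frame["time_to_diagnosis"] = ttd
    frame["cancer_type"] = np.where(future_case, "lymphoma", "none")
    return frame


# ---------------------------------------------------------------------------
# ground truth + expression


@dataclass
class SimulationTruth:
    """Planted generative parameters for a block of transcripts.

    The linear predictor for transcript t and subject i is

        alpha[t]
        + sum_c beta_pcb[t, c] * P[i, c]              (sex mask applied)
        + sum_k beta_wbc[t, k] * W[i, k]
        + sum_{c,k} beta_inter[t, c, k] * P[i, c] * W[i, k]   (sex mask applied)
        + sum_f beta_fe[t, f] * FE[i, f]

    where P holds log-then-z-scored PCB levels, W raw WBC fractions and FE
    the confounder encoding of :data:`FE_NAMES`.  A batch random intercept
    (variance ``sigma2_u``, shared within scan-date batch, independent across
    transcripts) and iid Gaussian noise (variance ``sigma2_e``) are added.
    ``sex_mask`` ('both'/'F'/'M') restricts the exposure-driven terms
    (beta_pcb, beta_inter) to one sex, emulating sex-specific responses.
    """

    alpha: np.ndarray
    beta_pcb: np.ndarray        # (T, 6)
    beta_wbc: np.ndarray        # (T, 6)
    beta_inter: np.ndarray      # (T, 6, 6)
    beta_fe: np.ndarray         # (T, len(FE_NAMES))
    sigma2_u: float
    sigma2_e: float
    sex_mask: np.ndarray = field(default=None)  # (T,) of 'both'/'F'/'M'

    def __post_init__(self):
        t = self.n_transcripts
        if self.sex_mask is None:
            self.sex_mask = np.full(t, "both", dtype=object)
        if self.sigma2_u < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")
        shapes = {
            "alpha": (t,),
            "beta_pcb": (t, 6),
            "beta_wbc": (t, 6),
            "beta_inter": (t, 6, 6),
            "beta_fe": (t, len(FE_NAMES)),
            "sex_mask": (t,),
        }
        for name, shape in shapes.items():
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")

    @property
    def n_transcripts(self) -> int:
        return int(np.asarray(self.alpha).shape[0])

    @classmethod
    def null(
        cls, n_transcripts: int, sigma2_u: float = 0.2, sigma2_e: float = 1.0
    ) -> "SimulationTruth":
        """All effects zero; only batch and residual variance."""
        t = int(n_transcripts)
        return cls(
            alpha=np.zeros(t),
            beta_pcb=np.zeros((t, 6)),
            beta_wbc=np.zeros((t, 6)),
            beta_inter=np.zeros((t, 6, 6)),
            beta_fe=np.zeros((t, len(FE_NAMES))),
            sigma2_u=float(sigma2_u),
            sigma2_e=float(sigma2_e),
        )

    def plant_interactions(
        self,
        congener: int,
        cell_type: str,
        effect: float,
        fraction: float,
        seed: int = 0,
    ) -> np.ndarray:
        """Plant ``effect`` on the (congener, cell_type) interaction for a
        random ``fraction`` of transcripts; returns the planted indices."""
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        rng = np.random.default_rng(seed)
        k = int(round(fraction * self.n_transcripts))
        idx = rng.choice(self.n_transcripts, size=k, replace=False)
        self.beta_inter[idx, pcb_index(congener), cell_index(cell_type)] = effect
        return np.sort(idx)

    def to_json(self, path) -> None:
        payload = {
            f.name: (
                getattr(self, f.name).tolist()
                if isinstance(getattr(self, f.name), np.ndarray)
                else getattr(self, f.name)
            )
            for f in dataclasses.fields(self)
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        for key in ("alpha", "beta_pcb", "beta_wbc", "beta_inter", "beta_fe"):
            payload[key] = np.asarray(payload[key], dtype=float)
        payload["sex_mask"] = np.asarray(payload["sex_mask"], dtype=object)
        return cls(**payload)


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=0)
    return (x - x.mean()) / s if s > 0 else x - x.mean()


def encode_fixed_effects(cohort: pd.DataFrame) -> np.ndarray:
    """Confounder encoding used by the generator; order is FE_NAMES."""
    return np.column_stack(
        [
            (cohort["cohort_label"] == "EPIC").to_numpy(float),
            (cohort["sex"] == "M").to_numpy(float),
            (cohort["cancer_type"] == "lymphoma").to_numpy(float),
            _zscore(cohort["age"].to_numpy(float)),
            _zscore(cohort["bmi"].to_numpy(float)),
            (cohort["smoking"] == "former").to_numpy(float),
            (cohort["smoking"] == "current").to_numpy(float),
        ]
    )


def generate_expression(
    cohort: pd.DataFrame,
    truth: SimulationTruth,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a transcripts x subjects expression matrix under ``truth``.

    Returns a DataFrame with transcript ids in the index and subject ids as
    columns, aligned to ``cohort['subject_id']``.
    """
    n = len(cohort)
    t = truth.n_transcripts
    rng = np.random.default_rng(seed)

    p = np.column_stack(
        [_zscore(np.log(cohort[c].to_numpy(float))) for c in PCB_COLUMNS]
    )
    if np.any(~np.isfinite(p)):
        raise ValueError("PCB levels must be strictly positive")
    w = cohort[list(CELL_TYPES)].to_numpy(float)
    fe = encode_fixed_effects(cohort)

    sex = cohort["sex"].to_numpy()
    sexw = np.ones((t, n))
    mask = np.asarray(truth.sex_mask)
    sexw[mask == "F"] = (sex == "F").astype(float)
    sexw[mask == "M"] = (sex == "M").astype(float)

    mean = (
        truth.alpha[:, None]
        + (truth.beta_pcb @ p.T) * sexw
        + truth.beta_wbc @ w.T
        + np.einsum("tck,ic,ik->ti", truth.beta_inter, p, w, optimize=True) * sexw
        + truth.beta_fe @ fe.T
    )

    batch_codes, _ = pd.factorize(cohort["batch"])
    n_batches = batch_codes.max() + 1
    u = rng.normal(0.0, np.sqrt(truth.sigma2_u), size=(t, n_batches))
    eps = rng.normal(0.0, np.sqrt(truth.sigma2_e), size=(t, n))
    y = mean + u[:, batch_codes] + eps

    index = pd.Index([f"T{i:05d}" for i in range(t)], name="transcript_id")
    return pd.DataFrame(y, index=index, columns=cohort["subject_id"].to_numpy())


# ---------------------------------------------------------------------------
# methylation fixtures for the deconvolution stage


def generate_reference_signature(n_cpgs: int = 200, seed: int = 0) -> pd.DataFrame:
    """Synthetic purified-leukocyte methylation signature (CpG x cell type).

    Beta(0.5, 0.5) draws give well-separated, full-rank cell-type profiles in
    [0, 1]; a stand-in for signatures derived from sorted blood cells.
    """
    if n_cpgs < 1:
        raise ValueError("n_cpgs must be >= 1")
    rng = np.random.default_rng(seed)
    vals = rng.beta(0.5, 0.5, size=(n_cpgs, len(CELL_TYPES)))
    index = pd.Index([f"cpg{i:05d}" for i in range(n_cpgs)], name="cpg_id")
    return pd.DataFrame(vals, index=index, columns=list(CELL_TYPES))


def generate_methylation(
    fractions,
    reference: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mix reference profiles by WBC fractions plus Gaussian noise.

    ``fractions`` is (subjects x cell types), rows on the simplex (checked to
    1e-8); ``reference`` is (CpG x cell types).  Output beta-values are
    clipped to [0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    fr = np.asarray(
        fractions[list(CELL_TYPES)] if isinstance(fractions, pd.DataFrame) else fractions,
        dtype=float,
    )
    if fr.ndim != 2 or fr.shape[1] != reference.shape[1]:
        raise ValueError("fractions columns must match reference cell types")
    if np.any(fr < -1e-8) or np.any(np.abs(fr.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("fraction rows must lie on the unit simplex (tol 1e-8)")
    rng = np.random.default_rng(seed)
    beta = reference.to_numpy(float) @ fr.T
    if noise_sd > 0:
        beta = beta + rng.normal(0.0, noise_sd, size=beta.shape)
    beta = np.clip(beta, 0.0, 1.0)
    if isinstance(fractions, pd.DataFrame) and fractions.index.name == "subject_id":
        cols = fractions.index.to_numpy()
    elif isinstance(fractions, pd.DataFrame):
        cols = fractions.index.to_numpy()
    else:
        cols = [f"S{i:04d}" for i in range(fr.shape[0])]
    return pd.DataFrame(beta, index=reference.index, columns=cols)
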