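"""Linear mixed model with a single random intercept, fitted by profiled ML.

The model for subject i is

    y_i = x_i' beta + u_{a(i)} + e_i,     u_a ~ N(0, sigma2_u),  e_i ~ N(0, sigma2_e)

with one Gaussian random intercept per batch (scan date).  Writing
lambda = sigma2_u / sigma2_e, the marginal covariance is
sigma2_e * (I + lambda Z Z').  For fixed lambda the GLS estimate of beta and
the ML estimate of sigma2_e are closed form, so the likelihood is profiled
down to a 1-D function of lambda, maximized by a coarse log-grid followed by
golden-section refinement; the lambda = 0 boundary (no batch variance) is
always admitted as a candidate.

The implementation never forms the n x n covariance.  Whitening by batch,
(I + lambda J)^{-1/2} y = y - theta_a * ybar_a with
theta_a = 1 - 1/sqrt(1 + n_a lambda), reduces every quantity to per-batch
sums, so a whole transcriptome can be scanned with one set of batched
matrix operations (one profile search per transcript, vectorized).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LAMBDA_LO = 1e-8
LAMBDA_HI = 1e3
_GRID_SIZE = 34
_GOLDEN_ITERS = 42
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0

__all__ = [
    "LMMFit",
    "fit_lmm",
    "lrt_nested",
    "bh_fdr",
    "power_linear_model",
    "f2_for_power",
]


@dataclass
class LMMFit:
    """One fitted mixed model: fixed effects plus two variance components."""

    beta: pd.Series
    sigma2_u: float
    sigma2_e: float
    loglik: float
    n: int
    converged: bool
    lam: float                      # sigma2_u / sigma2_e at the optimum
    batch_levels: tuple = ()

    @property
    def n_fixed(self) -> int:
        return len(self.beta)


class _Profiled:
    """Per-batch sufficient statistics for the profiled likelihood.

    Y is (T, n) — one row per response; X is (n, p); codes in [0, B).
    """

    def __init__(self, Y: np.ndarray, X: np.ndarray, codes: np.ndarray):
        self.Y, self.X = Y, X
        n, p = X.shape
        B = int(codes.max()) + 1
        P = np.zeros((B, n))
        P[codes, np.arange(n)] = 1.0
        self.n, self.p, self.B = n, p, B
        self.nj = P.sum(axis=1)                    # (B,)
        self.s = P @ X                             # (B, p) per-batch sums of X
        self.S = np.einsum("bp,bq->bpq", self.s, self.s)   # (B, p, p)
        self.G0 = X.T @ X                          # (p, p)
        self.C0 = Y @ X                            # (T, p)
        self.t = Y @ P.T                           # (T, B) per-batch sums of Y
        self.yy0 = np.einsum("tn,tn->t", Y, Y)     # (T,)

    def _weights(self, lam):
        """w_j = theta (2 - theta) / n_j = lambda / (1 + n_j lambda)."""
        return lam / (1.0 + self.nj * lam)

    def loglik_shared(self, lam: float) -> np.ndarray:
        """Profiled log-likelihood at one lambda, for all T rows at once."""
        w = self._weights(np.float64(lam))                       # (B,)
        G = self.G0 - np.einsum("b,bpq->pq", w, self.S)
        b = self.C0 - (self.t * w) @ self.s                      # (T, p)
        yy = self.yy0 - self.t**2 @ w
        try:
            sol = np.linalg.solve(G, b.T).T
        except np.linalg.LinAlgError:
            return np.full(self.Y.shape[0], -np.inf)
        rss = yy - np.einsum("tp,tp->t", b, sol)
        return self._ll_from_rss(rss, np.float64(lam))

    def loglik_per_row(self, lam: np.ndarray) -> np.ndarray:
        """Profiled log-likelihood with a separate lambda per row."""
        w = lam[:, None] / (1.0 + self.nj[None, :] * lam[:, None])   # (T, B)
        G = self.G0[None] - np.einsum("tb,bpq->tpq", w, self.S)
        b = self.C0 - np.einsum("tb,bp->tp", w * self.t, self.s)
        yy = self.yy0 - np.einsum("tb,tb->t", w, self.t**2)
        try:
            sol = np.linalg.solve(G, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            sol = np.stack(
                [np.linalg.lstsq(Gi, bi, rcond=None)[0] for Gi, bi in zip(G, b)]
            )
        rss = yy - np.einsum("tp,tp->t", b, sol)
        return self._ll_from_rss(rss, lam)

    def _ll_from_rss(self, rss: np.ndarray, lam) -> np.ndarray:
        n = self.n
        rss = np.maximum(rss, 1e-300)
        logdet = np.sum(np.log1p(np.multiply.outer(lam, self.nj)), axis=-1)
        return -0.5 * (n * (np.log(2.0 * np.pi * rss / n) + 1.0) + logdet)

    def solve_at(self, lam: np.ndarray):
        """beta, sigma2_e, loglik at per-row lambda values."""
        w = lam[:, None] / (1.0 + self.nj[None, :] * lam[:, None])
        G = self.G0[None] - np.einsum("tb,bpq->tpq", w, self.S)
        b = self.C0 - np.einsum("tb,bp->tp", w * self.t, self.s)
        yy = self.yy0 - np.einsum("tb,tb->t", w, self.t**2)
        beta = np.linalg.solve(G, b[..., None])[..., 0]
        rss = np.maximum(yy - np.einsum("tp,tp->t", b, beta), 0.0)
        ll = self._ll_from_rss(rss, lam)
        sigma2_e = rss / self.n
        return beta, sigma2_e, ll, G


def _profile_ml(Y: np.ndarray, X: np.ndarray, codes: np.ndarray) -> dict:
    """Maximize the profiled ML likelihood per row of Y; vectorized.

    Returns lam, beta, sigma2_e, sigma2_u, loglik, converged arrays.
    """
    pre = _Profiled(Y, X, codes)
    T = Y.shape[0]

    if pre.B == 1:
        # a single batch is confounded with the intercept: lambda pinned to 0
        lam_hat = np.zeros(T)
        beta, sigma2_e, ll, _ = pre.solve_at(lam_hat)
        return _pack(lam_hat, beta, sigma2_e, ll)

    grid = np.concatenate(
        [[0.0], np.logspace(np.log10(LAMBDA_LO), np.log10(LAMBDA_HI), _GRID_SIZE)]
    )
    ll_grid = np.stack([pre.loglik_shared(l) for l in grid], axis=1)  # (T, G)
    best = np.argmax(ll_grid, axis=1)

    # golden-section refinement on log10(lambda) within the bracketing interval
    lo_idx = np.maximum(best - 1, 1)
    hi_idx = np.minimum(best + 1, grid.size - 1)
    a = np.log10(grid[lo_idx])
    b = np.log10(grid[hi_idx])
    for _ in range(_GOLDEN_ITERS):
        h = b - a
        c = b - _INVPHI * h
        d = a + _INVPHI * h
        fc = pre.loglik_per_row(10.0**c)
        fd = pre.loglik_per_row(10.0**d)
        left = fc > fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
    lam_hat = 10.0 ** ((a + b) / 2.0)

    # admit the lambda = 0 boundary whenever it is at least as good
    ll_ref = pre.loglik_per_row(lam_hat)
    lam_hat = np.where(ll_grid[:, 0] >= ll_ref, 0.0, lam_hat)

    beta, sigma2_e, ll, _ = pre.solve_at(lam_hat)
    return _pack(lam_hat, beta, sigma2_e, ll)


def _pack(lam, beta, sigma2_e, ll):
    converged = np.isfinite(ll) & np.all(np.isfinite(beta), axis=1) & (sigma2_e > 0)
    return {
        "lam": lam,
        "beta": beta,
        "sigma2_e": sigma2_e,
        "sigma2_u": lam * sigma2_e,
        "loglik": ll,
        "converged": converged,
    }


def _as_design(fixed_design) -> tuple[np.ndarray, list[str]]:
    if isinstance(fixed_design, pd.DataFrame):
        X = fixed_design.to_numpy(float)
        names = [str(c) for c in fixed_design.columns]
    else:
        X = np.asarray(fixed_design, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    return X, names


def fit_lmm(y, fixed_design, batch) -> LMMFit:
    """Fit the single-random-intercept LMM by maximum likelihood.

    ``fixed_design`` must include its own intercept column if one is wanted.
    ``batch`` is a vector of grouping labels (the scan-date batches).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be a 1-D vector")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    X, names = _as_design(fixed_design)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and fixed_design have different lengths")
    if n < p + 2:
        raise ValueError(f"need n >= p + 2 (n={n}, p={p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular fixed-effect design")
    codes, levels = pd.factorize(np.asarray(batch))
    if len(levels) < 1 or len(codes) != n:
        raise ValueError("batch labels must be non-empty and match y")

    res = _profile_ml(y[None, :], X, codes)
    return LMMFit(
        beta=pd.Series(res["beta"][0], index=names),
        sigma2_u=float(res["sigma2_u"][0]),
        sigma2_e=float(res["sigma2_e"][0]),
        loglik=float(res["loglik"][0]),
        n=n,
        converged=bool(res["converged"][0]),
        lam=float(res["lam"][0]),
        batch_levels=tuple(levels),
    )


def lrt_nested(full: LMMFit, reduced: LMMFit) -> tuple[float, float]:
    """Likelihood-ratio test of two nested ML fits on the same data.

    Returns (statistic, p).  The statistic is 2 * (ll_full - ll_reduced)
    floored at 0; p comes from chi-square with df = difference in number of
    fixed effects.  Unconverged fits propagate as a missing p-value.
    """
    if full.n != reduced.n:
        raise ValueError("fits are not on the same data (different n)")
    if not set(reduced.beta.index) <= set(full.beta.index):
        raise ValueError("reduced fixed effects are not nested in the full model")
    df = full.n_fixed - reduced.n_fixed
    if df < 0:
        raise ValueError("full model has fewer fixed effects than reduced")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if not (full.converged and reduced.converged):
        return stat, float("nan")
    if df == 0:
        return stat, 1.0
    return stat, float(stats.chi2.sf(stat, df))


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and the q <= alpha mask.

    Missing p-values (NaN) are excluded from the correction and come back as
    NaN q with a False mask.  p outside [0, 1] raises.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    flat = p.ravel()
    ok = ~np.isnan(flat)
    if np.any((flat[ok] < 0) | (flat[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(flat.shape, np.nan)
    m = int(ok.sum())
    if m:
        pv = flat[ok]
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        qv = np.minimum.accumulate(ranked[::-1])[::-1]
        qs = np.empty(m)
        qs[order] = np.minimum(qv, 1.0)
        q[ok] = qs
    mask = np.where(np.isnan(q), False, q <= alpha)
    return q.reshape(p.shape), mask.reshape(p.shape).astype(bool)


def power_linear_model(u: int, v: int, f2: float, alpha: float = 0.05) -> float:
    """Power of the linear-model F test at Cohen effect size f2.

    Noncentral F(u, v) with noncentrality f2 * (u + v + 1) against the
    (1 - alpha) central-F critical value; f2 = 0 returns alpha exactly.
    """
    if u < 1 or v < 1:
        raise ValueError("numerator and denominator df must be >= 1")
    if f2 < 0:
        raise ValueError("f2 must be >= 0")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if f2 == 0:
        return float(alpha)
    crit = stats.f.isf(alpha, u, v)
    return float(stats.ncf.sf(crit, u, v, f2 * (u + v + 1)))


def f2_for_power(
    u: int, v: int, power: float, alpha: float = 0.05
) -> float:
    """Cohen f2 achieving the target power (inverse of power_linear_model)."""
    if not 0.0 < power < 1.0:
        raise ValueError("power must be in (0, 1)")
    if power <= alpha:
        return 0.0
    from scipy.optimize import brentq

    hi = 1.0
    while power_linear_model(u, v, hi, alpha) < power:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("no f2 below 1e6 reaches the requested power")
    return float(
        brentq(lambda f2: power_linear_model(u, v, f2, alpha) - power, 0.0, hi,
               xtol=1e-12)
    )
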