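"""Independent oracles used to cross-check the package's implementations.

Each oracle deliberately takes a different computational route from the code
it checks: explicit n x n covariance matrices for the mixed model, brute
force grids / SLSQP for the constrained projection, combinatorial
enumeration for the hypergeometric tail, quadrature for noncentral-F power,
and statsmodels for OLS-based quantities.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import integrate, stats
from scipy.optimize import minimize, minimize_scalar


def ols_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form normal-equations OLS solution."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def lmm_loglik_direct(y, X, Z, lam):
    """Profiled ML log-likelihood via the explicit marginal covariance."""
    n = len(y)
    V = np.eye(n) + lam * Z @ Z.T
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    s2 = r @ Vi @ r / n
    _, logdet = np.linalg.slogdet(V)
    return -0.5 * (n * (np.log(2 * np.pi * s2) + 1) + logdet)


def lmm_ml_oracle(y, X, codes, grid_size=400):
    """Grid + bounded-refine maximization of the direct profiled likelihood."""
    n = len(y)
    B = int(np.max(codes)) + 1
    Z = np.zeros((n, B))
    Z[np.arange(n), codes] = 1.0
    grid = np.concatenate([[0.0], np.logspace(-8, 3, grid_size)])
    lls = np.array([lmm_loglik_direct(y, X, Z, l) for l in grid])
    i = int(np.argmax(lls))
    best = lls[i]
    if 0 < i < len(grid) - 1:
        res = minimize_scalar(
            lambda t: -lmm_loglik_direct(y, X, Z, 10.0**t),
            bounds=(np.log10(grid[max(i - 1, 1)]), np.log10(grid[i + 1])),
            method="bounded",
            options={"xatol": 1e-12},
        )
        best = max(best, -res.fun)
    return best


def deconv_objective(R, m, f):
    r = R @ f - m
    return float(r @ r)


def deconv_slsqp_oracle(R, m, sum_to_one=False):
    """Constrained least squares via scipy SLSQP (independent solver)."""
    k = R.shape[1]
    cons = (
        {"type": "eq", "fun": lambda f: np.sum(f) - 1.0}
        if sum_to_one
        else {"type": "ineq", "fun": lambda f: 1.0 - np.sum(f)}
    )
    res = minimize(
        lambda f: deconv_objective(R, m, f),
        x0=np.full(k, 1.0 / k),
        bounds=[(0.0, 1.0)] * k,
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return res.x


def simplex_grid(k: int, steps: int):
    """All compositions of `steps` into k parts, scaled to the simplex."""
    for cuts in combinations(range(steps + k - 1), k - 1):
        parts = np.diff(np.concatenate([[-1], cuts, [steps + k - 1]])) - 1
        yield parts / steps


def deconv_grid_oracle(R, m, steps=20):
    """Dense-grid brute-force minimizer over the full simplex."""
    best, best_obj = None, np.inf
    for f in simplex_grid(R.shape[1], steps):
        obj = deconv_objective(R, m, f)
        if obj < best_obj:
            best, best_obj = f, obj
    return best, best_obj


def vif_oracle(X: np.ndarray) -> np.ndarray:
    """Two-regression VIF definition via statsmodels OLS."""
    import statsmodels.api as sm

    p = X.shape[1]
    out = np.empty(p)
    for j in range(p):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[j] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def ncf_power_quadrature(u, v, f2, alpha):
    """Noncentral-F power by numerical integration of the density."""
    crit = stats.f.isf(alpha, u, v)
    nc = f2 * (u + v + 1)
    val, _ = integrate.quad(
        lambda x: stats.ncf.pdf(x, u, v, nc), crit, np.inf, limit=200
    )
    return val


def hypergeom_tail_enumeration(n_bg, pathway, hits, observed):
    """P(overlap >= observed) by exhaustive enumeration of draws.

    `pathway` and `hits` are sets of integers inside range(n_bg); the draw is
    every subset of size |hits|, i.e. the exact permutation null.
    """
    hits = frozenset(hits)
    pathway = frozenset(pathway)
    total = hit = 0
    for draw in combinations(range(n_bg), len(hits)):
        total += 1
        if len(pathway & set(draw)) >= observed:
            hit += 1
    return hit / total


def bh_hand(p):
    """Step-up BH computed index-by-index, no vectorized shortcuts."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q
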