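"""Reference-based white-blood-cell deconvolution from methylation.

Each subject's beta-value profile is projected onto purified-leukocyte
reference signatures under the constraints fraction >= 0 and
sum(fractions) <= 1 (optionally == 1), and the solution is renormalized onto
the simplex.  With six cell types the constrained least-squares problem is
tiny, so it is solved exactly by enumerating KKT active sets: every subset
of zeroed cell types, with and without the sum constraint active, yields an
equality-constrained solve; the feasible candidate with the smallest
objective is the global optimum of this convex program.  The procedure is
deterministic and accurate to linear-algebra precision.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .simulate import CELL_TYPES

_FEAS_TOL = 1e-9


def _solve_constrained_ls(R: np.ndarray, m: np.ndarray, sum_to_one: bool) -> np.ndarray:
    """argmin ||R f - m||^2  s.t.  f >= 0 and sum(f) <= 1 (or == 1)."""
    k = R.shape[1]
    Q = R.T @ R
    c = R.T @ m
    ones = np.ones(k)
    best, best_obj = None, np.inf

    def objective(f):
        return f @ Q @ f - 2.0 * c @ f

    for n_zero in range(k):
        for zeroed in combinations(range(k), n_zero):
            free = [j for j in range(k) if j not in zeroed]
            Qf = Q[np.ix_(free, free)]
            cf = c[free]
            sum_states = (True,) if sum_to_one else (False, True)
            for active_sum in sum_states:
                try:
                    if active_sum:
                        kk = len(free)
                        A = np.zeros((kk + 1, kk + 1))
                        A[:kk, :kk] = 2.0 * Qf
                        A[:kk, kk] = 1.0
                        A[kk, :kk] = 1.0
                        rhs = np.concatenate([2.0 * cf, [1.0]])
                        sol = np.linalg.solve(A, rhs)[:kk]
                    else:
                        sol = np.linalg.solve(Qf, cf)
                except np.linalg.LinAlgError:
                    continue
                f = np.zeros(k)
                f[free] = sol
                if np.any(f < -_FEAS_TOL) or f.sum() > 1.0 + _FEAS_TOL:
                    continue
                obj = objective(f)
                if obj < best_obj - 1e-15 or best is None:
                    best, best_obj = np.clip(f, 0.0, None), obj
    if best is None:  # all coordinates zero is always feasible for <= 1
        best = np.zeros(k)
    return best


def estimate_cell_fractions(
    meth: pd.DataFrame,
    reference: pd.DataFrame,
    sum_to_one: bool = False,
) -> pd.DataFrame:
    """Estimate per-subject WBC fractions by constrained projection.

    ``meth`` is CpG x subjects, ``reference`` CpG x cell types, both with
    beta-values in [0, 1]; rows are matched on the CpG index.  With
    ``sum_to_one`` the fractions are constrained to the simplex inside the
    solver; otherwise sum <= 1 is solved and the result renormalized, the
    two conventions differing only through noise.  Returns subjects x cell
    types in the fixed order NK, B, Mono, Gran, CD8T, CD4T.
    """
    shared = reference.index.intersection(meth.index)
    if len(shared) == 0:
        raise ValueError("no shared CpGs between methylation matrix and reference")
    k = reference.shape[1]
    if len(shared) < k:
        raise ValueError(
            f"need at least {k} shared CpGs (one per cell type); got {len(shared)}"
        )
    R = reference.loc[shared].to_numpy(float)
    if np.linalg.matrix_rank(R) < k:
        raise ValueError("reference signature is rank deficient on shared CpGs")
    M = meth.loc[shared].to_numpy(float)
    if np.any((M < -1e-9) | (M > 1 + 1e-9)) or np.any((R < -1e-9) | (R > 1 + 1e-9)):
        raise ValueError("beta-values must lie in [0, 1]")

    out = np.empty((M.shape[1], k))
    for s in range(M.shape[1]):
        f = _solve_constrained_ls(R, M[:, s], sum_to_one)
        total = f.sum()
        out[s] = f / total if total > _FEAS_TOL else np.full(k, 1.0 / k)
    cols = list(reference.columns) if list(reference.columns) else list(CELL_TYPES)
    return pd.DataFrame(
        out, index=pd.Index(meth.columns, name="subject_id"), columns=cols
    )
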