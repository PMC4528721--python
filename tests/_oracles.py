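"""Independent brute-force oracles for the solver primitives.

These deliberately avoid the code paths they validate: vertex enumeration
for LPs, exhaustive sign patterns for the L1 problem, and exhaustive
active-set KKT solves for the MOMA QP.  Only usable on tiny instances.
"""

from __future__ import annotations

import itertools

import numpy as np


def lp_vertex_oracle(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                     c: np.ndarray, sense: str = "min",
                     tol: float = 1e-9) -> float:
    """Optimal value of ``c.x`` over {Sx=0, lb<=x<=ub} by vertex enumeration.

    A vertex fixes (n - rank(S)) coordinates at a bound; every choice of
    fixed set and bound side is tried.
    """
    n = S.shape[1]
    r = np.linalg.matrix_rank(S, tol=1e-10)
    k = n - r
    best = None
    for fixed_tup in itertools.combinations(range(n), k):
        fixed = list(fixed_tup)
        free = [i for i in range(n) if i not in fixed]
        for sides in itertools.product((0, 1), repeat=k):
            x = np.zeros(n)
            for i, s in zip(fixed, sides):
                x[i] = lb[i] if s == 0 else ub[i]
            rhs = -S[:, fixed] @ x[fixed] if fixed else np.zeros(S.shape[0])
            if free:
                sol, res, rank, _ = np.linalg.lstsq(S[:, free], rhs,
                                                    rcond=None)
                x[np.array(free)] = sol
            if np.max(np.abs(S @ x)) > 1e-7:
                continue
            if np.any(x < lb - 1e-7) or np.any(x > ub + 1e-7):
                continue
            val = float(c @ x)
            if best is None or (val < best if sense == "min" else val > best):
                best = val
    if best is None:
        raise ValueError("no feasible vertex found")
    return best


def l1_sign_pattern_oracle(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                           extra_eq: list[tuple[np.ndarray, float]] | None = None,
                           ) -> float:
    """Minimal L1 norm over the flux polytope via exhaustive orthant LPs."""
    from scipy.optimize import linprog

    n = S.shape[1]
    best = None
    A_eq = S
    b_eq = np.zeros(S.shape[0])
    for row, rhs in extra_eq or []:
        A_eq = np.vstack([A_eq, row[None, :]])
        b_eq = np.append(b_eq, rhs)
    for signs in itertools.product((-1.0, 1.0), repeat=n):
        s = np.array(signs)
        lo = np.where(s > 0, np.maximum(lb, 0.0), lb)
        hi = np.where(s > 0, ub, np.minimum(ub, 0.0))
        if np.any(lo > hi):
            continue
        res = linprog(s, A_eq=A_eq, b_eq=b_eq, bounds=list(zip(lo, hi)),
                      method="highs")
        if res.status == 0:
            val = float(np.abs(res.x).sum())
            if best is None or val < best:
                best = val
    if best is None:
        raise ValueError("infeasible")
    return best


def moma_active_set_oracle(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                           ref: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    """Unique optimum of min ||x-ref||^2 over {Sx=0, lb<=x<=ub}.

    Enumerates every bound active set, solves the equality-constrained KKT
    system, and returns the first candidate satisfying primal feasibility
    and the multiplier sign conditions.
    """
    n = S.shape[1]
    best = None
    best_val = np.inf
    for states in itertools.product((0, 1, 2), repeat=n):  # free/lb/ub
        rows = [S]
        rhs = [np.zeros(S.shape[0])]
        for i, st in enumerate(states):
            if st:
                e = np.zeros(n)
                e[i] = 1.0
                rows.append(e[None, :])
                rhs.append([lb[i] if st == 1 else ub[i]])
        A = np.vstack(rows)
        b = np.concatenate([np.atleast_1d(np.asarray(v, float))
                            for v in rhs])
        m = A.shape[0]
        K = np.block([[2 * np.eye(n), A.T], [A, np.zeros((m, m))]])
        try:
            sol, *_ = np.linalg.lstsq(K, np.concatenate([2 * ref, b]),
                                      rcond=None)
        except np.linalg.LinAlgError:
            continue
        x = sol[:n]
        if (np.any(x < lb - tol) or np.any(x > ub + tol)
                or np.max(np.abs(S @ x)) > tol):
            continue
        # multiplier sign conditions on active bounds
        g = 2 * (x - ref)
        free = [i for i, st in enumerate(states) if st == 0]
        lam, *_ = np.linalg.lstsq(S[:, free].T, -g[free], rcond=None)
        mu = g + S.T @ lam
        ok = True
        for i, st in enumerate(states):
            if st == 1 and mu[i] < -1e-6:
                ok = False
            elif st == 2 and mu[i] > 1e-6:
                ok = False
            elif st == 0 and abs(mu[i]) > 1e-6:
                ok = False
        if not ok:
            continue
        val = float(np.sum((x - ref) ** 2))
        if val < best_val - 1e-12:
            best, best_val = x, val
    if best is None:
        raise ValueError("no KKT point found")
    return best
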