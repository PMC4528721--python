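"""Solver-backed flux balance analysis primitives.

Everything here operates on the steady-state polytope

    { v : S v = 0,  lb <= v <= ub }

with S written over intracellular metabolites only.  Linear programs (growth
maximisation, weighted flux objectives, L1 flux minimisation, FVA) are solved
with HiGHS through :func:`scipy.optimize.linprog`; the MOMA quadratic program
is solved with OSQP and then refined by a KKT solve on the detected active
set so that solutions are accurate to ~1e-9 on the problem sizes this package
targets.

Sign conventions: exchange reactions are written in the export direction, so
uptake is a negative exchange flux and a measured uptake rate u is imposed as
a lower bound of -u (or a pinned value of -u for the substrate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import MetabolicModel, build_stoich_matrix

__all__ = [
    "Environment",
    "FluxVector",
    "ConstrainedProblem",
    "LinearConstraint",
    "apply_environment",
    "fba_max_growth",
    "linear_flux_objective",
    "l1_minimize",
    "moma_qp",
    "fva_range",
    "production_weights",
]

#: Numerical stand-in for an unbounded enzymatic capacity, mmol/(g-DW.h).
BIG_BOUND = 1e4

#: Steady-state feasibility reported solutions must satisfy.
STEADY_STATE_TOL = 1e-6


@dataclass
class Environment:
    """Exchange-bound set defining one culture phase.

    Uptake magnitudes are non-negative, in mmol/(g-DW.h).  The substrate
    uptake is *pinned* (both bounds) at the measured rate, while ammonium and
    phosphate uptakes act as capacities (lower bound only); a nitrogen-limited
    phase is expressed by ``nh4_uptake = 0``.  ``ngam`` is forced on the ATP
    maintenance reaction as an equality.  ``fixed_rates`` pins further
    reaction fluxes (e.g. measured storage accumulation rates for FVA).
    """

    substrate_exchange: str
    substrate_uptake: float
    nh4_exchange: str = "EX_nh4"
    nh4_uptake: float = 0.0
    pi_exchange: str = "EX_pi"
    pi_uptake: float = 10.0
    o2_exchange: str = "EX_o2"
    o2_unlimited: bool = True
    o2_uptake: float = 0.0  # bound used when o2_unlimited is False
    ngam: float = 0.0
    fixed_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("substrate_uptake", "nh4_uptake", "pi_uptake"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_limited(self) -> bool:
        return self.nh4_uptake == 0.0

    def with_ngam(self, ngam: float) -> "Environment":
        from dataclasses import replace
        return replace(self, fixed_rates=dict(self.fixed_rates), ngam=ngam)


@dataclass
class FluxVector:
    """One steady-state flux distribution."""

    values: dict[str, float]
    objective_value: float = float("nan")
    status: str = "optimal"  # optimal | infeasible | unbounded

    def __getitem__(self, rid: str) -> float:
        return self.values[rid]

    def get(self, rid: str, default: float = 0.0) -> float:
        return self.values.get(rid, default)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def as_array(self, reaction_ids: list[str]) -> np.ndarray:
        return np.array([self.values[r] for r in reaction_ids])


@dataclass
class LinearConstraint:
    """A row ``sum_i w_i v_i  (=|<=|>=)  rhs`` added to a problem."""

    weights: dict[str, float]
    rhs: float
    sense: str = "eq"  # eq | le | ge

    def row(self, reaction_index: dict[str, int], n: int) -> np.ndarray:
        row = np.zeros(n)
        for rid, w in self.weights.items():
            row[reaction_index[rid]] = w
        return row


@dataclass
class ConstrainedProblem:
    """An environment applied to a model: S, bounds, and index maps."""

    model: MetabolicModel
    S: np.ndarray
    met_ids: list[str]
    reaction_ids: list[str]
    lb: np.ndarray
    ub: np.ndarray

    @property
    def n(self) -> int:
        return len(self.reaction_ids)

    @property
    def reaction_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.reaction_ids)}

    def flux_vector(self, x: np.ndarray, objective: float,
                    status: str = "optimal") -> FluxVector:
        return FluxVector(dict(zip(self.reaction_ids, map(float, x))),
                          objective_value=float(objective), status=status)

    def check_steady_state(self, x: np.ndarray) -> float:
        return float(np.max(np.abs(self.S @ x))) if len(x) else 0.0


def apply_environment(model: MetabolicModel, env: Environment) -> ConstrainedProblem:
    """Build the constrained steady-state problem for one culture phase."""
    S, met_ids = build_stoich_matrix(model)
    rids = [r.id for r in model.reactions]
    idx = {r: i for i, r in enumerate(rids)}
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)

    # empty exchange ids mean "this species is not part of the model"
    # (used by minimal test networks)
    for rid in filter(None, (env.substrate_exchange, env.nh4_exchange,
                             env.pi_exchange, env.o2_exchange,
                             *env.fixed_rates)):
        if rid not in idx:
            raise KeyError(f"environment references missing reaction {rid!r}")

    j = idx[env.substrate_exchange]
    lb[j] = ub[j] = -env.substrate_uptake
    if env.nh4_exchange:
        lb[idx[env.nh4_exchange]] = -env.nh4_uptake
    if env.pi_exchange:
        lb[idx[env.pi_exchange]] = -env.pi_uptake
    if env.o2_exchange:
        if env.o2_unlimited:
            lb[idx[env.o2_exchange]] = -BIG_BOUND
        else:
            lb[idx[env.o2_exchange]] = -env.o2_uptake
    if model.maintenance_reaction_id:
        j = idx[model.maintenance_reaction_id]
        lb[j] = ub[j] = env.ngam
    for rid, val in env.fixed_rates.items():
        j = idx[rid]
        lb[j] = ub[j] = val
    return ConstrainedProblem(model, S, met_ids, rids, lb, ub)


_LP_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible",
              3: "unbounded", 4: "numerical"}


def _split_constraints(prob: ConstrainedProblem,
                       constraints: list[LinearConstraint] | None):
    """Extra constraint rows as (A_eq_extra, b_eq, A_ub_extra, b_ub)."""
    idx = prob.reaction_index
    eq_rows, eq_rhs, ub_rows, ub_rhs = [], [], [], []
    for con in constraints or []:
        row = con.row(idx, prob.n)
        if con.sense == "eq":
            eq_rows.append(row), eq_rhs.append(con.rhs)
        elif con.sense == "le":
            ub_rows.append(row), ub_rhs.append(con.rhs)
        elif con.sense == "ge":
            ub_rows.append(-row), ub_rhs.append(-con.rhs)
        else:
            raise ValueError(f"unknown constraint sense {con.sense!r}")
    return eq_rows, eq_rhs, ub_rows, ub_rhs


def solve_lp(prob: ConstrainedProblem, c: np.ndarray, sense: str = "min",
             constraints: list[LinearConstraint] | None = None) -> FluxVector:
    """Solve ``min/max c.v`` over the constrained steady-state polytope."""
    sign = 1.0 if sense == "min" else -1.0
    eq_rows, eq_rhs, ub_rows, ub_rhs = _split_constraints(prob, constraints)
    A_eq = np.vstack([prob.S] + [r[None, :] for r in eq_rows]) if eq_rows else prob.S
    b_eq = np.concatenate([np.zeros(prob.S.shape[0]), np.asarray(eq_rhs)]) \
        if eq_rhs else np.zeros(prob.S.shape[0])
    kw = {}
    if ub_rows:
        kw["A_ub"] = np.vstack([r[None, :] for r in ub_rows])
        kw["b_ub"] = np.asarray(ub_rhs)
    res = linprog(sign * c, A_eq=A_eq, b_eq=b_eq,
                  bounds=list(zip(prob.lb, prob.ub)), method="highs", **kw)
    status = _LP_STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxVector({r: float("nan") for r in prob.reaction_ids},
                          float("nan"), status)
    x = res.x
    viol = prob.check_steady_state(x)
    if viol > STEADY_STATE_TOL:
        raise RuntimeError(f"LP solution violates steady state by {viol:.2e}")
    return prob.flux_vector(x, sign * res.fun)


def fba_max_growth(model: MetabolicModel, env: Environment) -> FluxVector:
    """Maximise the biomass (growth) flux."""
    prob = apply_environment(model, env)
    c = np.zeros(prob.n)
    c[prob.reaction_index[model.biomass_reaction_id]] = 1.0
    return solve_lp(prob, c, sense="max")


def production_weights(model: MetabolicModel, met_id: str) -> dict[str, float]:
    """Gross production stoichiometry of one metabolite across reactions.

    Only positive (producing) coefficients are counted -- consumption is not
    netted out -- so ``sum_j w_j v_j`` is the gross production rate when all
    producing reactions run forward.
    """
    weights = {}
    for rxn in model.reactions:
        coeff = rxn.stoichiometry.get(met_id, 0.0)
        if coeff > 0:
            weights[rxn.id] = coeff
    if not weights:
        raise ValueError(f"no reaction produces {met_id!r}")
    return weights


def linear_flux_objective(model: MetabolicModel, env: Environment,
                          weights: dict[str, float], sense: str = "max",
                          constraints: list[LinearConstraint] | None = None,
                          ) -> FluxVector:
    """Optimise a weighted sum of fluxes."""
    if not weights:
        raise ValueError("weights must be non-empty")
    prob = apply_environment(model, env)
    idx = prob.reaction_index
    c = np.zeros(prob.n)
    for rid, w in weights.items():
        c[idx[rid]] = w
    return solve_lp(prob, c, sense=sense, constraints=constraints)


def l1_minimize(model: MetabolicModel, env: Environment,
                constraints: list[LinearConstraint] | None = None,
                include_exchanges: bool = True) -> FluxVector:
    """Minimise the Manhattan norm ``sum_i |v_i|`` of the flux vector.

    Uses the standard auxiliary formulation ``t_i >= |v_i|``, minimising
    ``sum t_i``; at the optimum no cancelling forward/backward pair can be
    active because it would only add norm.  ``include_exchanges=False``
    restricts the sum to non-exchange reactions.
    """
    prob = apply_environment(model, env)
    n = prob.n
    mask = np.ones(n)
    if not include_exchanges:
        for i, rxn in enumerate(model.reactions):
            if rxn.kind in ("exchange", "storage_exchange"):
                mask[i] = 0.0
    eq_rows, eq_rhs, ub_rows, ub_rhs = _split_constraints(prob, constraints)

    # variables z = [v, t]
    c = np.concatenate([np.zeros(n), mask])
    A_eq = np.hstack([prob.S, np.zeros_like(prob.S)])
    if eq_rows:
        A_eq = np.vstack([A_eq] + [np.hstack([r, np.zeros(n)])[None, :]
                                   for r in eq_rows])
    b_eq = np.concatenate([np.zeros(prob.S.shape[0]), np.asarray(eq_rhs)]) \
        if eq_rhs else np.zeros(prob.S.shape[0])
    I = np.eye(n)
    A_ub = np.vstack([np.hstack([I, -I]), np.hstack([-I, -I])])
    b_ub = np.zeros(2 * n)
    if ub_rows:
        A_ub = np.vstack([A_ub] + [np.hstack([r, np.zeros(n)])[None, :]
                                   for r in ub_rows])
        b_ub = np.concatenate([b_ub, np.asarray(ub_rhs)])
    tmax = np.maximum(np.abs(prob.lb), np.abs(prob.ub))
    bounds = list(zip(prob.lb, prob.ub)) + list(zip(np.zeros(n), tmax))
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                  bounds=bounds, method="highs")
    status = _LP_STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxVector({r: float("nan") for r in prob.reaction_ids},
                          float("nan"), status)
    x = res.x[:n]
    viol = prob.check_steady_state(x)
    if viol > STEADY_STATE_TOL:
        raise RuntimeError(f"L1 LP violates steady state by {viol:.2e}")
    return prob.flux_vector(x, float(mask @ np.abs(x)))


# ---------------------------------------------------------------------------
# MOMA quadratic program
# ---------------------------------------------------------------------------

def _osqp_solve(P, q, A, l, u, eps: float = 1e-10):
    import osqp

    solver = osqp.OSQP()
    settings = dict(eps_abs=eps, eps_rel=eps, max_iter=400000, verbose=False)
    try:
        solver.setup(P=P, q=q, A=A, l=l, u=u, polishing=True, **settings)
    except TypeError:  # osqp < 1.0 called it "polish"
        solver = osqp.OSQP()
        solver.setup(P=P, q=q, A=A, l=l, u=u, polish=True, **settings)
    try:
        return solver.solve(raise_error=False)
    except TypeError:  # osqp < 1.0 has no raise_error argument
        return solver.solve()


def _kkt_refine(prob: ConstrainedProblem, ref: np.ndarray, x: np.ndarray,
                eq_rows, eq_rhs, ub_rows, ub_rhs,
                active_tol: float = 1e-6) -> np.ndarray | None:
    """Polish a QP solution by solving the KKT system on its active set.

    min ||v - ref||^2 s.t. S v = 0, extra equalities, and the bound /
    inequality constraints detected active in ``x`` held at equality.
    Returns None when the refined point is worse or infeasible.
    """
    n = prob.n
    rows = [prob.S]
    rhs = [np.zeros(prob.S.shape[0])]
    for r, b in zip(eq_rows, eq_rhs):
        rows.append(r[None, :]), rhs.append([b])
    for i in range(n):
        if x[i] <= prob.lb[i] + active_tol and prob.lb[i] > -BIG_BOUND * 0.999:
            e = np.zeros(n); e[i] = 1.0
            rows.append(e[None, :]), rhs.append([prob.lb[i]])
        elif x[i] >= prob.ub[i] - active_tol and prob.ub[i] < BIG_BOUND * 0.999:
            e = np.zeros(n); e[i] = 1.0
            rows.append(e[None, :]), rhs.append([prob.ub[i]])
    for r, b in zip(ub_rows, ub_rhs):
        if float(r @ x) >= b - active_tol:
            rows.append(r[None, :]), rhs.append([b])
    A = np.vstack(rows)
    b = np.concatenate([np.atleast_1d(np.asarray(v, dtype=float)) for v in rhs])
    m = A.shape[0]
    # KKT: [2I A^T; A 0] [v; lam] = [2 ref; b]
    K = np.block([[2 * np.eye(n), A.T], [A, np.zeros((m, m))]])
    try:
        sol, *_ = np.linalg.lstsq(K, np.concatenate([2 * ref, b]), rcond=None)
    except np.linalg.LinAlgError:
        return None
    v = sol[:n]
    feas_tol = 1e-7
    if (np.any(v < prob.lb - feas_tol) or np.any(v > prob.ub + feas_tol)
            or prob.check_steady_state(v) > feas_tol):
        return None
    for r, bb in zip(ub_rows, ub_rhs):
        if float(r @ v) > bb + feas_tol:
            return None
    if np.sum((v - ref) ** 2) > np.sum((x - ref) ** 2) + 1e-9:
        return None
    return v


def moma_qp(model: MetabolicModel, env: Environment, reference: FluxVector,
            constraints: list[LinearConstraint] | None = None) -> FluxVector:
    """Minimisation of metabolic adjustment.

    Finds the flux vector feasible under ``env`` closest (Euclidean) to the
    reference distribution; the QP is strictly convex, so the optimum in v is
    unique.  The objective value reported is the squared distance.
    """
    prob = apply_environment(model, env)
    n = prob.n
    ref = reference.as_array(prob.reaction_ids)
    eq_rows, eq_rhs, ub_rows, ub_rhs = _split_constraints(prob, constraints)

    m_eq = prob.S.shape[0]
    A_parts = [prob.S, np.eye(n)]
    l_parts = [np.zeros(m_eq), prob.lb]
    u_parts = [np.zeros(m_eq), prob.ub]
    for r, b in zip(eq_rows, eq_rhs):
        A_parts.append(r[None, :]), l_parts.append([b]), u_parts.append([b])
    for r, b in zip(ub_rows, ub_rhs):
        A_parts.append(r[None, :]), l_parts.append([-np.inf]), u_parts.append([b])
    A = sp.csc_matrix(np.vstack(A_parts))
    l = np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in l_parts])
    u = np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in u_parts])
    P = sp.csc_matrix(2 * np.eye(n))
    q = -2 * ref

    # cheap LP feasibility screen: near-infeasible QPs make OSQP stall
    feas = solve_lp(prob, np.zeros(n), constraints=constraints)
    if not feas.optimal:
        return FluxVector({r: float("nan") for r in prob.reaction_ids},
                          float("nan"), "infeasible")

    res = _osqp_solve(P, q, A, l, u)
    status = res.info.status.lower()
    if "solved" not in status and "infeasible" not in status:
        # retry at looser tolerance; the KKT refinement below restores
        # accuracy once the active set is identified
        res = _osqp_solve(P, q, A, l, u, eps=1e-8)
        status = res.info.status.lower()
    if "infeasible" in status:
        return FluxVector({r: float("nan") for r in prob.reaction_ids},
                          float("nan"), "infeasible")
    if "solved" not in status:
        raise RuntimeError(f"OSQP failed: {res.info.status}")
    x = np.asarray(res.x, dtype=float)
    refined = _kkt_refine(prob, ref, x, eq_rows, eq_rhs, ub_rows, ub_rhs)
    if refined is not None:
        x = refined
    viol = prob.check_steady_state(x)
    if viol > STEADY_STATE_TOL:
        raise RuntimeError(f"MOMA solution violates steady state by {viol:.2e}")
    return prob.flux_vector(x, float(np.sum((x - ref) ** 2)))


def fva_range(model: MetabolicModel, env: Environment, reaction_id: str,
              constraints: list[LinearConstraint] | None = None,
              ) -> tuple[float, float]:
    """Flux variability: tight LP min and max of one reaction's flux."""
    prob = apply_environment(model, env)
    c = np.zeros(prob.n)
    c[prob.reaction_index[reaction_id]] = 1.0
    lo = solve_lp(prob, c, sense="min", constraints=constraints)
    hi = solve_lp(prob, c, sense="max", constraints=constraints)
    if not (lo.optimal and hi.optimal):
        raise RuntimeError(
            f"FVA infeasible for {reaction_id!r}: the environment's fixed "
            f"rates are mutually inconsistent (status {lo.status}/{hi.status})")
    return lo.objective_value, hi.objective_value
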