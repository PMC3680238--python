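"""Flux-space optimisation: FBA, parsimonious FBA, FVA and MOMA.

All solvers operate on the steady-state flux polytope

.. math::

    \\{ v : S v = 0,\\; lb \\le v \\le ub \\}

where ``S`` is the model's stoichiometric matrix and the bounds come
from the model plus an optional :class:`~fluxscreen.model.ConstraintSet`.

* **FBA** maximises one flux (the biomass reaction, giving the specific
  growth rate in 1/h) by linear programming (HiGHS via scipy).
* **pFBA** fixes the FBA optimum and then minimises the total absolute
  flux, selecting a unique, parsimonious representative among the
  generally degenerate FBA optima.  All screens use the pFBA vector as
  the wild-type reference so that predictions do not depend on an
  arbitrary LP vertex.
* **FVA** reports per-reaction flux ranges at a given fraction of the
  optimum, which is how tests certify that screen rankings are robust
  to the remaining degeneracy.
* **MOMA** (minimisation of metabolic adjustment) solves the quadratic
  program ``min Σ_j (v_j − v_ref_j)²`` over the perturbed polytope,
  modelling the immediate metabolic state of a knockout or
  flux-amplified mutant as the feasible flux distribution closest to
  the parent strain's.  Solved with OSQP (polished, tight tolerances).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import osqp
from scipy import sparse
from scipy.optimize import linprog

from .model import ConstraintSet, MetabolicModel

__all__ = [
    "FluxState",
    "SolverOptions",
    "solve_fba",
    "solve_pfba",
    "solve_fva",
    "solve_moma",
    "TOL_STEADY",
    "TOL_BOUND",
    "NONZERO_FLUX",
]

#: steady-state residual tolerance, ‖S v‖∞
TOL_STEADY = 1e-6
#: bound-violation tolerance for returned flux vectors
TOL_BOUND = 1e-9
#: fluxes below this magnitude count as zero (overexpression candidacy)
NONZERO_FLUX = 1e-6

_LP_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


@dataclass
class SolverOptions:
    """Backend knobs; defaults give deterministic, polished solutions."""

    lp_backend: str = "highs"
    qp_eps: float = 1e-10
    qp_max_iter: int = 400_000
    # iteration-based rho adaptation keeps OSQP runs bit-reproducible
    qp_adaptive_rho_interval: int = 50


@dataclass
class FluxState:
    """One flux distribution plus solver status.

    ``fluxes`` is empty unless ``status == "optimal"``.  For FBA/pFBA
    ``objective_value`` is the optimised flux (e.g. growth rate, 1/h);
    for MOMA it is the minimised squared flux distance.
    """

    fluxes: dict[str, float] = field(default_factory=dict)
    objective_value: float | None = None
    status: str = "optimal"
    solver_meta: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def value(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    def vector(self, reaction_ids: list[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in reaction_ids])


def _assemble(model: MetabolicModel, constraints: ConstraintSet | None):
    S = model.stoichiometric_matrix().tocsc()
    lb, ub = model.bounds_arrays(constraints)
    return S, lb, ub, model.reaction_ids


def _lp(c, S, lb, ub, options: SolverOptions, extra_ub=None, extra_rhs=None):
    return linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=extra_ub,
        b_ub=extra_rhs,
        bounds=list(zip(lb, ub)),
        method=options.lp_backend,
    )


def solve_fba(
    model: MetabolicModel,
    constraints: ConstraintSet | None = None,
    objective: str | None = None,
    options: SolverOptions = SolverOptions(),
) -> FluxState:
    """Maximise one reaction's flux over the steady-state polytope.

    ``objective`` defaults to the model's objective (biomass) reaction.
    An unbounded result signals a missing exchange bound and is
    reported as ``status="unbounded"`` rather than raised.
    """
    objective = objective or model.objective_id
    if objective is None or objective not in model.reactions:
        raise ValueError(f"objective reaction {objective!r} not in model")
    S, lb, ub, rxn_ids = _assemble(model, constraints)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective)] = -1.0
    res = _lp(c, S, lb, ub, options)
    status = _LP_STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FluxState(status=status, solver_meta=res.message)
    fluxes = dict(zip(rxn_ids, res.x))
    return FluxState(
        fluxes=fluxes,
        objective_value=fluxes[objective],
        status="optimal",
        solver_meta=f"highs fba it={res.nit}",
    )


def solve_pfba(
    model: MetabolicModel,
    constraints: ConstraintSet | None = None,
    objective: str | None = None,
    options: SolverOptions = SolverOptions(),
    weights: dict[str, float] | None = None,
) -> FluxState:
    """Parsimonious FBA: minimise Σ w_j |v_j| at the FBA optimum.

    The returned ``objective_value`` is the FBA optimum (not the flux
    sum); the flux sum is recorded in ``solver_meta``.  Reversible
    reactions are split into forward/reverse parts inside the solver
    only — the returned state carries net fluxes.

    ``weights`` (default: all 1) perturbs the parsimony tie-break;
    robustness analyses re-solve with mildly perturbed weights to
    generate alternate parsimonious references.
    """
    objective = objective or model.objective_id
    fba = solve_fba(model, constraints, objective, options)
    if not fba.optimal:
        return fba
    S, lb, ub, rxn_ids = _assemble(model, constraints)
    n = len(rxn_ids)
    j_obj = rxn_ids.index(objective)
    opt = fba.objective_value
    # pin the objective at its optimum (tiny relaxation absorbs LP round-off)
    slack = 1e-10 * max(1.0, abs(opt))
    lb, ub = lb.copy(), ub.copy()
    lb[j_obj] = max(lb[j_obj], opt - slack)
    ub[j_obj] = min(ub[j_obj], opt + slack)
    # variables [v, t], minimise 1ᵀt subject to −t ≤ v ≤ t
    eye = sparse.identity(n, format="csc")
    A_eq = sparse.hstack([S, sparse.csc_matrix((S.shape[0], n))], format="csc")
    A_ub = sparse.vstack(
        [sparse.hstack([eye, -eye]), sparse.hstack([-eye, -eye])], format="csc"
    )
    w = np.ones(n)
    if weights:
        for rid, wj in weights.items():
            w[rxn_ids.index(rid)] = wj
    c = np.concatenate([np.zeros(n), w])
    bounds = list(zip(lb, ub)) + [(0.0, None)] * n
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=np.zeros(2 * n),
        bounds=bounds,
        method=options.lp_backend,
    )
    status = _LP_STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FluxState(status=status, solver_meta=res.message)
    v = res.x[:n]
    fluxes = dict(zip(rxn_ids, v))
    return FluxState(
        fluxes=fluxes,
        objective_value=fluxes[objective],
        status="optimal",
        solver_meta=f"highs pfba flux_sum={np.abs(v).sum():.9g}",
    )


def solve_fva(
    model: MetabolicModel,
    constraints: ConstraintSet | None = None,
    reaction_ids: list[str] | None = None,
    fraction_of_optimum: float = 1.0,
    objective: str | None = None,
    options: SolverOptions = SolverOptions(),
) -> dict[str, tuple[float, float]]:
    """Flux variability: per-reaction (min, max) at ≥ fraction × optimum."""
    if not 0 < fraction_of_optimum <= 1:
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    objective = objective or model.objective_id
    fba = solve_fba(model, constraints, objective, options)
    if not fba.optimal:
        raise RuntimeError(f"FVA requires an optimal FBA solution (got {fba.status})")
    S, lb, ub, rxn_ids = _assemble(model, constraints)
    j_obj = rxn_ids.index(objective)
    opt = fba.objective_value
    lb = lb.copy()
    # growth constraint; the sign handles maximisation objectives only,
    # which is the only mode the screens use
    target = fraction_of_optimum * opt
    lb[j_obj] = max(lb[j_obj], target - 1e-9 * max(1.0, abs(target)))
    out: dict[str, tuple[float, float]] = {}
    for rid in reaction_ids or rxn_ids:
        j = rxn_ids.index(rid)
        c = np.zeros(len(rxn_ids))
        c[j] = 1.0
        lo = _lp(c, S, lb, ub, options)
        hi = _lp(-c, S, lb, ub, options)
        if lo.status != 0 or hi.status != 0:
            raise RuntimeError(f"FVA subproblem for {rid} not optimal")
        out[rid] = (lo.x[j], hi.x[j])
    return out


def solve_moma(
    model: MetabolicModel,
    constraints: ConstraintSet | None,
    v_ref: FluxState,
    options: SolverOptions = SolverOptions(),
) -> FluxState:
    """Minimisation of metabolic adjustment (quadratic programming).

    Returns the flux vector of the *perturbed* polytope (knockout zeros
    and/or amplification pins encoded in ``constraints``) closest in
    squared Euclidean distance to the reference distribution ``v_ref``
    (all reactions weighted equally, exchanges included).

    ``objective_value`` is the minimised squared distance.  An empty
    perturbed polytope — a lethal perturbation — yields
    ``status="infeasible"`` rather than an exception, so screens can
    iterate over candidates.
    """
    if not v_ref.optimal:
        raise ValueError("MOMA reference must be an optimal FluxState")
    S, lb, ub, rxn_ids = _assemble(model, constraints)
    n = len(rxn_ids)
    ref = v_ref.vector(rxn_ids)
    # min ‖v − ref‖² ⇔ min ½ vᵀ(2I)v − 2 refᵀv (+ const)
    P = sparse.identity(n, format="csc") * 2.0
    q = -2.0 * ref
    A = sparse.vstack([S, sparse.identity(n, format="csc")], format="csc")
    l = np.concatenate([np.zeros(S.shape[0]), lb])
    u = np.concatenate([np.zeros(S.shape[0]), ub])
    solver = osqp.OSQP()
    solver.setup(
        P, q, A, l, u,
        verbose=False,
        eps_abs=options.qp_eps,
        eps_rel=options.qp_eps,
        eps_prim_inf=1e-10,
        eps_dual_inf=1e-10,
        max_iter=options.qp_max_iter,
        polishing=True,
        adaptive_rho_interval=options.qp_adaptive_rho_interval,
    )
    res = solver.solve(raise_error=False)
    status = res.info.status
    if "infeasible" in status:
        return FluxState(status="infeasible", solver_meta=f"osqp: {status}")
    if "solved" not in status:
        return FluxStateError.raise_for(status)  # pragma: no cover
    v = np.asarray(res.x[:n], dtype=float)
    # clip round-off outside the box so downstream invariant checks hold
    v = np.clip(v, lb - TOL_BOUND, ub + TOL_BOUND)
    distance = float(np.sum((v - ref) ** 2))
    fluxes = dict(zip(rxn_ids, v))
    return FluxState(
        fluxes=fluxes,
        objective_value=distance,
        status="optimal",
        solver_meta=f"osqp {status} it={res.info.iter}",
    )


class FluxStateError(RuntimeError):
    """A QP terminated without a usable status (iteration limit etc.)."""

    @staticmethod
    def raise_for(status: str) -> FluxState:
        raise FluxStateError(f"QP solver terminated with status {status!r}")
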