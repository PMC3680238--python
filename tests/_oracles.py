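"""Independent brute-force oracles used to check the solvers.

These deliberately avoid the code paths under test: FBA is checked
against exhaustive vertex enumeration of the flux polytope, MOMA
against dense grid search and random-feasible-point minimality, and
GPR evaluation against direct recursive truth evaluation.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.optimize import linprog

import fluxscreen as fs


def random_small_network(rng: np.random.Generator, max_reactions: int = 8):
    """A random bounded flux polytope {S v = 0, lb <= v <= ub}.

    Always feasible (0 is inside the box) and bounded (finite box).
    Returns (S, lb, ub).
    """
    n = int(rng.integers(3, max_reactions + 1))
    m = int(rng.integers(1, max(2, n - 1)))
    S = rng.integers(-2, 3, size=(m, n)).astype(float)
    lb = -rng.uniform(0.0, 10.0, size=n)
    ub = rng.uniform(0.0, 10.0, size=n)
    return S, lb, ub


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                       tol: float = 1e-9) -> np.ndarray:
    """All vertices of {S v = 0, lb <= v <= ub} by basis enumeration.

    A vertex has n − rank(S) variables fixed at a bound; enumerate every
    choice of fixed set and bound side, solve for the free variables,
    and keep feasible solutions.  Exponential — only for tiny networks.
    """
    m, n = S.shape
    rank = np.linalg.matrix_rank(S)
    n_fixed = n - rank
    vertices = []
    for fixed in combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        for sides in product((0, 1), repeat=n_fixed):
            v = np.zeros(n)
            for j, side in zip(fixed, sides):
                v[j] = ub[j] if side else lb[j]
            b = -S[:, fixed] @ v[list(fixed)]
            sol, residual, rk, _ = np.linalg.lstsq(A, b, rcond=None)
            v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                vertices.append(np.clip(v, lb, ub))
    return np.array(vertices)


def brute_force_lp_max(S, lb, ub, c: np.ndarray) -> float:
    """max c.v over the polytope via vertex enumeration."""
    vertices = enumerate_vertices(S, lb, ub)
    assert len(vertices) > 0, "polytope unexpectedly empty"
    return float(max(vertices @ c))


def random_feasible_points(S, lb, ub, rng: np.random.Generator,
                           n_points: int, n_lp: int = 40) -> np.ndarray:
    """Random feasible points: random-objective LP vertices plus their
    convex combinations (cheap way to fill the polytope)."""
    verts = []
    for _ in range(n_lp):
        c = rng.normal(size=len(lb))
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=list(zip(lb, ub)), method="highs")
        assert res.status == 0
        verts.append(res.x)
    verts = np.array(verts)
    points = [verts]
    need = n_points - len(verts)
    if need > 0:
        w = rng.dirichlet(np.ones(len(verts)), size=need)
        points.append(w @ verts)
    return np.vstack(points)[:n_points]


def gpr_truth_table_eval(rule_text: str, knocked_out: set[str]) -> bool:
    """Direct evaluation of a gene rule with python's own boolean ops,
    independent of the package parser's AST walk."""
    import re

    expr = rule_text
    for gene in sorted(set(re.findall(r"[^\s()]+", rule_text)) - {"and", "or"},
                       key=len, reverse=True):
        expr = re.sub(rf"(?<![\w.]){re.escape(gene)}(?![\w.])",
                      str(gene not in knocked_out), expr)
    return bool(eval(expr))  # noqa: S307 - test oracle on generated input


def to_cobra(model: fs.MetabolicModel, constraints=None):
    """Convert to a cobrapy model (independent FBA/pFBA oracle)."""
    from cobra import Metabolite as CM
    from cobra import Model as CModel
    from cobra import Reaction as CR

    cm = CModel(model.name or "model")
    mets = {mid: CM(mid, compartment=met.compartment)
            for mid, met in model.metabolites.items()}
    lb, ub = model.bounds_arrays(constraints)
    rxns = [CR(r.id, lower_bound=lb[j], upper_bound=ub[j])
            for j, r in enumerate(model.reactions.values())]
    cm.add_reactions(rxns)
    for cr, rxn in zip(rxns, model.reactions.values()):
        cr.add_metabolites({mets[k]: v for k, v in rxn.stoichiometry.items()})
    if model.objective_id:
        cm.objective = model.objective_id
    return cm
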