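"""LP relaxation of the expression-constrained flux-activity model.

For one cell line, enzymatic reactions are partitioned into highly expressed
(R_H), lowly expressed (R_L) and undetermined sets from gene expression.
The model searches a steady-state flux distribution that maximizes agreement
with those states.  Each reaction i in R_H gets continuous indicators
y_i⁺, y_i⁻ ∈ [0, 1] — the likelihood that the reaction carries a significant
flux (≥ ε forward, ≤ −ε backward); each reaction in R_L gets y_i⁺ ∈ [0, 1],
the likelihood it carries (almost) zero flux.  The LP is

    maximize   Σ_{i∈R_H} (y_i⁺ + y_i⁻) + Σ_{i∈R_L} y_i⁺
    subject to S·v = 0
               lb_i ≤ v_i ≤ ub_i
               v_i + y_i⁺·(lb_i − ε) ≥ lb_i          (i ∈ R_H)
               v_i + y_i⁻·(ub_i + ε) ≤ ub_i          (i ∈ R_H)
               lb_i·(1 − y_i⁺) ≤ v_i ≤ ub_i·(1 − y_i⁺)  (i ∈ R_L)
               0 ≤ y ≤ 1

the continuous relaxation of the mixed-integer activity model: y⁺ = 1 forces
v_i ≥ ε (R_H) or v_i = 0 (R_L).  No coupling y⁺ + y⁻ ≤ 1 is imposed; under
the relaxation both can be fractional simultaneously, which is documented
behaviour.  Flux threshold ε defaults to 1.

LP optima are typically degenerate in v, so by default an optional second
lexicographic pass minimizes Σ|v| at fixed optimal objective (split-variable
LP), making downstream flux profiles deterministic and sparse.

Solved with scipy's HiGHS interface, which is deterministic for a fixed
problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .errors import SolverError, ValidationError
from .expr_states import ReactionStateAssignment
from .metnet import MetabolicNetwork

__all__ = [
    "DEFAULT_EPSILON",
    "FluxLP",
    "FluxSolution",
    "build_lp",
    "solve_flux",
    "activity_call",
    "run_cell_lines",
]

DEFAULT_EPSILON = 1.0

_FEAS_TOL = 1e-9
_CHECK_TOL = 1e-6


@dataclass
class FluxLP:
    """Assembled LP for one cell line.

    Variable layout: ``[v (n_reactions), y⁺ (R_H), y⁻ (R_H), y⁺ (R_L)]``,
    with R_H and R_L in network reaction order.  ``c`` is the *maximization*
    objective.
    """

    net: MetabolicNetwork
    states: ReactionStateAssignment
    epsilon: float
    rh_ids: list[str]
    rl_ids: list[str]
    c: np.ndarray
    A_eq: sparse.csr_matrix
    b_eq: np.ndarray
    A_ub: sparse.csr_matrix
    b_ub: np.ndarray
    bounds: list[tuple[float, float]]

    @property
    def n_variables(self) -> int:
        return len(self.c)

    @property
    def n_constraints(self) -> int:
        """Inequality rows (mass balance counted separately in ``A_eq``)."""
        return self.A_ub.shape[0]


@dataclass
class FluxSolution:
    """Optimal fluxes and activity likelihoods for one cell line."""

    reaction_ids: list[str]
    v: np.ndarray
    y_plus: dict[str, float]   # R_H ∪ R_L
    y_minus: dict[str, float]  # R_H only
    objective: float
    status: str  # optimal | infeasible | unbounded

    def flux_of(self, rid: str) -> float:
        return float(self.v[self.reaction_ids.index(rid)])

    def to_frame(self, states: ReactionStateAssignment | None = None) -> pd.DataFrame:
        rows = []
        for rid, flux in zip(self.reaction_ids, self.v):
            rows.append(
                {
                    "reaction_id": rid,
                    "v": flux,
                    "state": states.state_of(rid)
                    if states is not None and rid in (states.R_H | states.R_L | states.undetermined)
                    else "",
                    "y_plus": self.y_plus.get(rid, float("nan")),
                    "y_minus": self.y_minus.get(rid, float("nan")),
                }
            )
        return pd.DataFrame(rows)


def build_lp(
    net: MetabolicNetwork,
    states: ReactionStateAssignment,
    epsilon: float = DEFAULT_EPSILON,
) -> FluxLP:
    """Assemble the LP for one cell line's state assignment.

    Undetermined reactions (and non-enzymatic ones) contribute only their
    flux variable; they are constrained by mass balance and bounds alone.
    """
    if epsilon <= 0:
        raise ValidationError(f"epsilon must be > 0, got {epsilon}")
    for rid in states.R_H | states.R_L | states.undetermined:
        if rid not in net.reaction_index:
            raise ValidationError(f"state assignment references unknown reaction {rid!r}")
    n = len(net.reactions)
    order = {rid: j for j, rid in enumerate(net.reaction_ids)}
    rh_ids = sorted(states.R_H, key=order.__getitem__)
    rl_ids = sorted(states.R_L, key=order.__getitem__)
    nh, nl = len(rh_ids), len(rl_ids)
    nvar = n + 2 * nh + nl
    lb = net.lower_bounds()
    ub = net.upper_bounds()

    c = np.zeros(nvar)
    c[n:] = 1.0  # maximize the sum of all y

    A_eq = sparse.hstack(
        [sparse.csr_matrix(net.S), sparse.csr_matrix((net.S.shape[0], nvar - n))]
    ).tocsr()
    b_eq = np.zeros(net.S.shape[0])

    rows, cols, vals, rhs = [], [], [], []
    r = 0

    def add(entries: list[tuple[int, float]], b: float) -> None:
        nonlocal r
        for j, a in entries:
            rows.append(r)
            cols.append(j)
            vals.append(a)
        rhs.append(b)
        r += 1

    for h, rid in enumerate(rh_ids):
        j = order[rid]
        yp, ym = n + h, n + nh + h
        # v + y⁺(lb − ε) ≥ lb   →   −v − y⁺(lb − ε) ≤ −lb
        add([(j, -1.0), (yp, -(lb[j] - epsilon))], -lb[j])
        # v + y⁻(ub + ε) ≤ ub
        add([(j, 1.0), (ym, ub[j] + epsilon)], ub[j])
    for l, rid in enumerate(rl_ids):
        j = order[rid]
        yp = n + 2 * nh + l
        # lb(1 − y⁺) ≤ v   →   −v − lb·y⁺ ≤ −lb
        add([(j, -1.0), (yp, -lb[j])], -lb[j])
        # v ≤ ub(1 − y⁺)   →   v + ub·y⁺ ≤ ub
        add([(j, 1.0), (yp, ub[j])], ub[j])

    A_ub = sparse.csr_matrix((vals, (rows, cols)), shape=(r, nvar))
    bounds = [(float(lb[j]), float(ub[j])) for j in range(n)] + [(0.0, 1.0)] * (
        2 * nh + nl
    )
    return FluxLP(
        net=net,
        states=states,
        epsilon=float(epsilon),
        rh_ids=rh_ids,
        rl_ids=rl_ids,
        c=c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=np.array(rhs),
        bounds=bounds,
    )


def _linprog(c, A_ub, b_ub, A_eq, b_eq, bounds):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": _FEAS_TOL},
    )


def solve_flux(lp: FluxLP, stabilize: bool = True) -> FluxSolution:
    """Solve the LP; optionally run the flux-stabilization pass.

    The stabilization pass re-solves with v split into v⁺ − v⁻ and minimizes
    Σ(v⁺ + v⁻) subject to the original constraints plus "objective at its
    optimum", so repeated solves of the same instance return an identical,
    minimal-total-flux vector.  Infeasible/unbounded status is reported, never
    silently zeroed.
    """
    res = _linprog(-lp.c, lp.A_ub, lp.b_ub, lp.A_eq, lp.b_eq, lp.bounds)
    if res.status == 2:
        return _failed(lp, "infeasible")
    if res.status == 3:
        return _failed(lp, "unbounded")
    if not res.success:  # pragma: no cover - solver numerical failure
        raise SolverError(f"LP solve failed: {res.message}")
    objective = float(-res.fun)
    x = res.x

    if stabilize:
        x = _stabilize(lp, objective)

    n = len(lp.net.reactions)
    nh = len(lp.rh_ids)
    v = x[:n]
    y_plus = {rid: float(x[n + h]) for h, rid in enumerate(lp.rh_ids)}
    y_plus.update(
        {rid: float(x[n + 2 * nh + l]) for l, rid in enumerate(lp.rl_ids)}
    )
    y_minus = {rid: float(x[n + nh + h]) for h, rid in enumerate(lp.rh_ids)}
    # clip solver round-off on the relaxed indicators
    y_plus = {k: min(max(val, 0.0), 1.0) for k, val in y_plus.items()}
    y_minus = {k: min(max(val, 0.0), 1.0) for k, val in y_minus.items()}
    return FluxSolution(
        reaction_ids=list(lp.net.reaction_ids),
        v=np.asarray(v, dtype=float),
        y_plus=y_plus,
        y_minus=y_minus,
        objective=objective,
        status="optimal",
    )


def _failed(lp: FluxLP, status: str) -> FluxSolution:
    n = len(lp.net.reactions)
    return FluxSolution(
        reaction_ids=list(lp.net.reaction_ids),
        v=np.full(n, np.nan),
        y_plus={},
        y_minus={},
        objective=float("nan"),
        status=status,
    )


def _stabilize(lp: FluxLP, objective: float) -> np.ndarray:
    """Secondary pass: among objective-optimal points, minimize Σ|v|.

    Variables ``[v, v⁺, v⁻, y...]`` with v = v⁺ − v⁻ (equality rows) and
    v⁺, v⁻ ≥ 0; original constraints kept; the optimal activity objective is
    enforced as Σy ≥ objective − 1e−9.
    """
    n = len(lp.net.reactions)
    ny = lp.n_variables - n
    nvar = n + 2 * n + ny  # v, v+, v-, y
    eye = sparse.identity(n, format="csr")

    def widen(A: sparse.csr_matrix) -> sparse.csr_matrix:
        # original columns [v, y] -> [v, v+, v-, y]
        Av, Ay = A[:, :n], A[:, n:]
        return sparse.hstack(
            [Av, sparse.csr_matrix((A.shape[0], 2 * n)), Ay]
        ).tocsr()

    A_eq = sparse.vstack(
        [
            widen(lp.A_eq),
            sparse.hstack([eye, -eye, eye, sparse.csr_matrix((n, ny))]),
        ]
    ).tocsr()
    b_eq = np.concatenate([lp.b_eq, np.zeros(n)])
    obj_row = sparse.csr_matrix(
        (-lp.c[n:], (np.zeros(ny, dtype=int), np.arange(n + 2 * n, nvar))),
        shape=(1, nvar),
    )
    A_ub = sparse.vstack([widen(lp.A_ub), obj_row]).tocsr()
    b_ub = np.concatenate([lp.b_ub, [-(objective - 1e-9)]])
    c = np.zeros(nvar)
    c[n : n + 2 * n] = 1.0
    bounds = (
        lp.bounds[:n] + [(0.0, None)] * (2 * n) + lp.bounds[n:]
    )
    res = _linprog(c, A_ub, b_ub, A_eq, b_eq, bounds)
    if not res.success:  # pragma: no cover - should not happen at a feasible optimum
        raise SolverError(f"stabilization pass failed: {res.message}")
    x = res.x
    return np.concatenate([x[:n], x[n + 2 * n :]])


def activity_call(v_i: float, epsilon: float = DEFAULT_EPSILON) -> str:
    """Classify one flux value: ``"active"`` iff |v| ≥ ε, else ``"inactive"``.

    The inactive band is the open interval (−ε, ε); the boundary counts as
    active.
    """
    if epsilon <= 0:
        raise ValidationError(f"epsilon must be > 0, got {epsilon}")
    return "active" if abs(v_i) >= epsilon else "inactive"


def run_cell_lines(
    net: MetabolicNetwork,
    state_assignments: list[ReactionStateAssignment],
    epsilon: float = DEFAULT_EPSILON,
    stabilize: bool = True,
    out_dir: str | Path | None = None,
) -> list[tuple[str, FluxSolution]]:
    """Batch solve one LP per cell line; optionally write one flux TSV per
    cell line plus a run log with solver status."""
    results = []
    for states in state_assignments:
        lp = build_lp(net, states, epsilon)
        sol = solve_flux(lp, stabilize=stabilize)
        results.append((states.cell_line, sol))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log_rows = []
        for states, (cell_line, sol) in zip(state_assignments, results):
            sol.to_frame(states).to_csv(
                out_dir / f"flux_{cell_line}.tsv", sep="\t", index=False
            )
            log_rows.append(
                {"cell_line": cell_line, "status": sol.status, "objective": sol.objective}
            )
        pd.DataFrame(log_rows).to_csv(out_dir / "run_log.tsv", sep="\t", index=False)
    return results
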