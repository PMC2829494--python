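"""Reference-flux estimation: FBA, target fitting and iterative centering.

Every stage is a linear program over steady-state fluxes (N v = 0 with box
bounds), solved with HiGHS via :func:`scipy.optimize.linprog`.  L1 objectives
and L1 budget constraints (total flux, distance to a centre, target misfit)
are encoded exactly through positive/negative deviation splitting; no
smoothing is used.

:func:`center_fluxes` implements the minimize-and-centre pipeline that
selects a unique reference flux from the optimal polytope:

1. maximize growth (``Z*``), when an objective is given;
2. minimize the L1 misfit to the known target fluxes (``D*``);
3. minimize the total flux ``Z1 = min sum |v_j|``;
4. iterate flux-variability bounds -> midpoint centre -> box bounds ->
   minimize the L1 distance to the centre -> retain the achieved distance as
   a budget constraint, until the widest bound interval falls below the
   convergence tolerance.

Each stage's optimum is retained as a constraint with a small relative slack
so solver round-off cannot empty the polytope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .errors import InfeasibleProblem, NumericalError, UnboundedProblem

logger = logging.getLogger(__name__)

DEFAULT_BOUND = 1000.0  # mM/s, applied symmetrically to reversible reactions

#: relative slack used when freezing a stage optimum as a constraint
STAGE_SLACK = 1e-6
#: relative slack on accumulated centre-distance constraints
DISTANCE_SLACK = 1e-9


@dataclass
class FluxProblem:
    """A steady-state flux polytope with objective and target data."""

    N: np.ndarray
    reaction_ids: list[str]
    objective: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    targets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        n = self.N.shape[1]
        self.objective = np.asarray(self.objective, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        if not (
            len(self.reaction_ids)
            == self.objective.size
            == self.lower_bounds.size
            == self.upper_bounds.size
            == n
        ):
            raise ValueError("inconsistent flux problem dimensions")
        if np.any(self.lower_bounds > self.upper_bounds):
            raise ValueError("lower bound exceeds upper bound")
        col = {rid: j for j, rid in enumerate(self.reaction_ids)}
        for rid, t in self.targets.items():
            if rid not in col:
                raise ValueError(f"target on unknown reaction {rid!r}")
            if not np.isfinite(t):
                raise ValueError(f"target on {rid!r} is not finite")

    @property
    def n(self) -> int:
        return self.N.shape[1]

    def column(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    def target_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(column indices, target values) for the target set, in id order."""
        items = sorted(self.targets.items())
        idx = np.array([self.column(rid) for rid, _ in items], dtype=int)
        vals = np.array([t for _, t in items], dtype=float)
        return idx, vals


def problem_from_network(
    net,
    objective_reaction: str | None = None,
    targets: Mapping[str, float] | None = None,
    default_bound: float = DEFAULT_BOUND,
) -> FluxProblem:
    """Build a :class:`FluxProblem` from a network.

    Irreversible reactions get bounds [0, default_bound]; reversible ones
    [-default_bound, default_bound].  The objective is the indicator of
    ``objective_reaction`` (zero vector when None).
    """
    from .network import build_stoichiometric_matrix

    N, _, col = build_stoichiometric_matrix(net)
    n = N.shape[1]
    lb = np.array(
        [-default_bound if r.reversible else 0.0 for r in net.reactions]
    )
    ub = np.full(n, default_bound)
    f = np.zeros(n)
    if objective_reaction is not None:
        f[col[objective_reaction]] = 1.0
    return FluxProblem(
        N=N,
        reaction_ids=[r.id for r in net.reactions],
        objective=f,
        lower_bounds=lb,
        upper_bounds=ub,
        targets=dict(targets or {}),
    )


# -- LP assembly -------------------------------------------------------------


@dataclass
class _L1Budget:
    """Constraint sum_{j in idx} |v_j - center_j| <= rhs."""

    idx: np.ndarray
    center: np.ndarray
    rhs: float


class _LPModel:
    """Mutable LP over flux variables v with accumulated side constraints.

    Auxiliary deviation variables are appended per L1 budget constraint and,
    when the objective itself is an L1 distance, per objective term.
    """

    def __init__(self, problem: FluxProblem):
        self.N = problem.N
        self.n = problem.n
        self.lb = problem.lower_bounds.copy()
        self.ub = problem.upper_bounds.copy()
        self.ineq: list[tuple[np.ndarray, float]] = []  # a . v <= b
        self.l1_budgets: list[_L1Budget] = []

    def add_inequality(self, a: np.ndarray, b: float) -> None:
        self.ineq.append((np.asarray(a, dtype=float), float(b)))

    def add_l1_budget(
        self, idx: Sequence[int], center: Sequence[float], rhs: float
    ) -> None:
        self.l1_budgets.append(
            _L1Budget(
                np.asarray(idx, dtype=int),
                np.asarray(center, dtype=float),
                float(rhs),
            )
        )

    def intersect_bounds(self, lo: np.ndarray, hi: np.ndarray) -> None:
        self.lb = np.maximum(self.lb, lo)
        self.ub = np.minimum(self.ub, hi)
        # guard against crossing from round-off in the FVA bounds
        mid = (self.lb + self.ub) / 2.0
        bad = self.lb > self.ub
        self.lb[bad] = mid[bad]
        self.ub[bad] = mid[bad]

    # -- assembly ------------------------------------------------------

    def _assemble(
        self,
        cost_v: np.ndarray,
        l1_objective: tuple[np.ndarray, np.ndarray] | None,
    ):
        n = self.n
        blocks = list(self.l1_budgets)
        obj_block = None
        if l1_objective is not None:
            idx, center = l1_objective
            obj_block = _L1Budget(idx, center, np.inf)
            blocks.append(obj_block)

        offsets: list[int] = []
        ncols = n
        for b in blocks:
            offsets.append(ncols)
            ncols += b.idx.size

        c = np.zeros(ncols)
        c[:n] = cost_v
        if obj_block is not None:
            c[offsets[-1]:] = 1.0

        rows_ub: list[np.ndarray] = []
        rhs_ub: list[float] = []
        for a, b in self.ineq:
            row = np.zeros(ncols)
            row[:n] = a
            rows_ub.append(row)
            rhs_ub.append(b)
        for block, off in zip(blocks, offsets):
            for k, (j, cj) in enumerate(zip(block.idx, block.center)):
                row = np.zeros(ncols)
                row[j] = 1.0
                row[off + k] = -1.0
                rows_ub.append(row)
                rhs_ub.append(cj)
                row = np.zeros(ncols)
                row[j] = -1.0
                row[off + k] = -1.0
                rows_ub.append(row)
                rhs_ub.append(-cj)
            if np.isfinite(block.rhs):
                row = np.zeros(ncols)
                row[off:off + block.idx.size] = 1.0
                rows_ub.append(row)
                rhs_ub.append(block.rhs)

        A_eq = np.zeros((self.N.shape[0], ncols))
        A_eq[:, :n] = self.N
        b_eq = np.zeros(self.N.shape[0])

        bounds = [(self.lb[j], self.ub[j]) for j in range(n)]
        bounds += [(0.0, None)] * (ncols - n)
        A_ub = np.vstack(rows_ub) if rows_ub else None
        b_ub = np.array(rhs_ub) if rows_ub else None
        return c, A_ub, b_ub, A_eq, b_eq, bounds

    def solve(
        self,
        cost_v: np.ndarray | None = None,
        l1_objective: tuple[np.ndarray, np.ndarray] | None = None,
        sense: float = 1.0,
    ) -> tuple[float, np.ndarray]:
        """Minimize ``sense * cost_v . v`` or an L1 distance objective.

        Returns (the minimized objective value, flux witness); callers
        maximizing pass ``sense=-1`` and negate the returned value.
        """
        cost = np.zeros(self.n) if cost_v is None else sense * np.asarray(
            cost_v, dtype=float
        )
        c, A_ub, b_ub, A_eq, b_eq, bounds = self._assemble(cost, l1_objective)
        res = linprog(
            c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
            bounds=bounds, method="highs",
        )
        if res.status == 2:
            raise InfeasibleProblem("linear program infeasible")
        if res.status == 3:
            raise UnboundedProblem("linear program unbounded")
        if res.status != 0:
            raise NumericalError(f"LP solver failure: {res.message}")
        v = res.x[: self.n]
        logger.info("LP solved: status=optimal objective=%.12g", res.fun)
        return float(res.fun), v


# -- public operations -------------------------------------------------------


def solve_fba(problem: FluxProblem) -> tuple[float, np.ndarray]:
    """Maximize f . v over {N v = 0, lb <= v <= ub}.

    Raises :class:`InfeasibleProblem` / :class:`UnboundedProblem` explicitly;
    an unbounded optimum is never reported as a large finite number.
    """
    model = _LPModel(problem)
    z, v = model.solve(cost_v=problem.objective, sense=-1.0)
    return -z, v


def fit_target_fluxes(
    problem: FluxProblem,
    model: _LPModel | None = None,
    norm: str = "l1",
) -> tuple[float, np.ndarray]:
    """Minimize the misfit to the target fluxes over the steady-state polytope.

    The default L1 norm (sum_{j in BM} |v_j - v_j^T|) is an exact LP via
    deviation splitting.  ``norm="l2"`` minimizes the sum of squares with a
    smooth solver (SLSQP), intended for small problems only.  ``model`` lets
    the centering pipeline fit under previously accumulated constraints.
    """
    if not problem.targets:
        raise ValueError("target set is empty")
    if norm == "l2":
        return _fit_target_fluxes_l2(problem)
    if norm != "l1":
        raise ValueError(f"unknown norm {norm!r}")
    if model is None:
        model = _LPModel(problem)
    idx, vals = problem.target_indices()
    return model.solve(l1_objective=(idx, vals))


def _fit_target_fluxes_l2(problem: FluxProblem) -> tuple[float, np.ndarray]:
    from scipy.optimize import minimize

    idx, vals = problem.target_indices()

    def objective(v):
        d = v[idx] - vals
        return float(d @ d)

    def grad(v):
        g = np.zeros(problem.n)
        g[idx] = 2.0 * (v[idx] - vals)
        return g

    v0 = np.clip(np.zeros(problem.n), problem.lower_bounds,
                 problem.upper_bounds)
    res = minimize(
        objective, v0, jac=grad, method="SLSQP",
        bounds=list(zip(problem.lower_bounds, problem.upper_bounds)),
        constraints=[{"type": "eq",
                      "fun": lambda v: problem.N @ v,
                      "jac": lambda v: problem.N}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if not res.success:
        raise NumericalError(f"L2 target fit failed: {res.message}")
    return float(res.fun), res.x


def minimize_total_flux(
    problem: FluxProblem, model: _LPModel | None = None
) -> tuple[float, np.ndarray]:
    """Minimize total flux Z1 = sum_j |v_j| via v = v+ - v- splitting."""
    if model is None:
        model = _LPModel(problem)
    idx = np.arange(problem.n)
    return model.solve(l1_objective=(idx, np.zeros(problem.n)))


def flux_variability(
    problem: FluxProblem, model: _LPModel | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-reaction flux minima and maxima over the constrained polytope.

    Solves 2n LPs.  Any infeasible sub-LP signals an inconsistent constraint
    set and propagates as :class:`InfeasibleProblem`.
    """
    if model is None:
        model = _LPModel(problem)
    n = problem.n
    lo = np.empty(n)
    hi = np.empty(n)
    e = np.zeros(n)
    for j in range(n):
        e[:] = 0.0
        e[j] = 1.0
        lo[j], _ = model.solve(cost_v=e, sense=1.0)
        z, _ = model.solve(cost_v=e, sense=-1.0)
        hi[j] = -z
    # clip round-off inversions
    mask = lo > hi
    mid = (lo + hi) / 2.0
    lo[mask] = mid[mask]
    hi[mask] = mid[mask]
    return lo, hi


@dataclass
class CenteredFluxResult:
    """Outcome of the minimize-and-centre pipeline."""

    v_star: np.ndarray
    reaction_ids: list[str]
    Z_star: float | None
    D_star: float | None
    Z_1: float
    target_misfit: float | None
    iterations: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    converged: bool
    tolerance: float
    residual_width: float

    def flux(self, rid: str) -> float:
        return float(self.v_star[self.reaction_ids.index(rid)])


def center_fluxes(
    problem: FluxProblem,
    tolerance: float = 1e-6,
    max_iterations: int = 50,
    objective_ordering: str = "lexicographic",
) -> CenteredFluxResult:
    """Select the unique centred reference flux v*.

    ``objective_ordering``: "lexicographic" keeps growth optimality (f.v = Z*)
    while fitting targets; "targets-first" fits the targets without that
    constraint and drops the growth stage.
    """
    if objective_ordering not in ("lexicographic", "targets-first"):
        raise ValueError(f"unknown ordering {objective_ordering!r}")
    model = _LPModel(problem)
    has_objective = np.any(problem.objective != 0.0)

    Z_star: float | None = None
    if has_objective and objective_ordering == "lexicographic":
        Z_star, _ = solve_fba(problem)
        slack = STAGE_SLACK * max(1.0, abs(Z_star))
        model.add_inequality(-problem.objective, -(Z_star - slack))
        logger.info("stage Z*: maximal objective %.12g", Z_star)

    D_star: float | None = None
    if problem.targets:
        idx, vals = problem.target_indices()
        D_star, _ = fit_target_fluxes(problem, model)
        slack = STAGE_SLACK * max(1.0, abs(D_star))
        model.add_l1_budget(idx, vals, D_star + slack)
        logger.info("stage D*: minimal target misfit %.12g", D_star)

    Z_1, _ = minimize_total_flux(problem, model)
    slack = STAGE_SLACK * max(1.0, abs(Z_1))
    model.add_l1_budget(
        np.arange(problem.n), np.zeros(problem.n), Z_1 + slack
    )
    logger.info("stage Z1: minimal total flux %.12g", Z_1)

    iterations: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    converged = False
    centre = np.zeros(problem.n)
    width = np.inf
    idx_all = np.arange(problem.n)
    for k in range(max_iterations):
        lo, hi = flux_variability(problem, model)
        centre = (lo + hi) / 2.0
        iterations.append((lo, hi, centre.copy()))
        width = float(np.max(hi - lo)) if problem.n else 0.0
        logger.info("centering iteration %d: max box width %.3g", k + 1, width)
        if width < tolerance:
            converged = True
            break
        model.intersect_bounds(lo, hi)
        d, _ = model.solve(l1_objective=(idx_all, centre))
        model.add_l1_budget(
            idx_all, centre, d * (1.0 + DISTANCE_SLACK) + 1e-12
        )

    v_star = centre
    misfit = None
    if problem.targets:
        idx, vals = problem.target_indices()
        misfit = float(np.sum(np.abs(v_star[idx] - vals)))
    return CenteredFluxResult(
        v_star=v_star,
        reaction_ids=list(problem.reaction_ids),
        Z_star=Z_star,
        D_star=D_star,
        Z_1=Z_1,
        target_misfit=misfit,
        iterations=iterations,
        converged=converged,
        tolerance=tolerance,
        residual_width=width,
    )
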