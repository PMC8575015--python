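"""Panel selection as a mixed-integer linear program.

For a fixed panel size k the model chooses binary gene weights w_l and
per-pair slacks xi_ij to minimize

    (D - Σ_{i<j} d_ij)  +  lambda * Σ_{i<j} xi_ij  -  mu * Σ_l w_l ss_l

subject to   Σ_l w_l = k
             (1/k) d_ij + xi_ij >= (1/n) Σ_l z_ijl     for every pair i<j
             w_l ∈ {0,1},  xi_ij >= 0

where d_ij = Σ_l w_l z_ijl. The first term keeps the total pairwise
cell-type distance of the panel close to that of all genes, the slack term
keeps each normalized pair distance close to its all-gene counterpart, and
the specificity term rewards genes that are individually cell type-specific.
With mu=0 the model is a pure distance-preserving feature selector; with
mu=lambda=0 it reduces to multidimensional-scaling-style feature selection.

The solver is HiGHS via scipy.optimize.milp. Degenerate (or near-degenerate,
below solver tolerance) optima are broken lexicographically: panels whose
objectives agree within TIE_TOL are considered tied and the one with the
smallest gene indices is returned, both here and in the exhaustive oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, Bounds, milp

from .difference import DifferenceTensor, PairwiseDistances, panel_distances

__all__ = [
    "PanelProblem",
    "PanelSolution",
    "SolverOptions",
    "build_mip",
    "solve_mip",
    "exhaustive_oracle",
    "sweep_parameters",
]

# objective differences below this are indistinguishable from solver noise
# (HiGHS primal/dual tolerances are 1e-7); such panels count as tied
TIE_TOL = 1e-7


@dataclass(frozen=True)
class PanelProblem:
    """A selection instance: difference tensor, specificity, k, lambda, mu."""

    zt: DifferenceTensor
    ss_l: np.ndarray
    k: int
    lambda_: float = 100.0
    mu: float = 10.0

    def __post_init__(self) -> None:
        ss = np.asarray(self.ss_l, dtype=float)
        object.__setattr__(self, "ss_l", ss)
        if ss.shape != (self.zt.n,):
            raise ValueError("ss_l length must equal the gene count")
        if not 1 <= self.k <= self.zt.n:
            raise ValueError(f"k={self.k} must satisfy 1 <= k <= n={self.zt.n}")
        if self.lambda_ < 0 or self.mu < 0:
            raise ValueError("lambda_ and mu must be nonnegative")


@dataclass
class SolverOptions:
    """Backend options for the bundled HiGHS solver."""

    time_limit: float | None = None  # seconds
    gap_tol: float = 1e-6
    tie_tol: float = TIE_TOL


@dataclass
class PanelSolution:
    w: np.ndarray
    xi: np.ndarray
    objective: float
    status: str  # optimal | feasible | infeasible | error
    d: PairwiseDistances | None = None
    parameters: dict = field(default_factory=dict)
    message: str = ""
    criteria: dict | None = None

    @property
    def selected(self) -> np.ndarray:
        """Indices of selected genes (w rounded at 0.5)."""
        return np.nonzero(self.w > 0.5)[0]


@dataclass(frozen=True)
class MIPModel:
    """Flat description of the MILP in scipy's c/A form.

    Variables are ordered [w_0..w_{n-1}, xi_0..xi_{P-1}] with P = m(m-1)/2
    pairs in canonical order. The constant term (D) is kept separately so the
    reported objective matches the model's definition.
    """

    c: np.ndarray
    constant: float
    integrality: np.ndarray
    bounds: Bounds
    constraints: tuple[LinearConstraint, ...]
    n: int
    n_pairs: int


def _objective_terms(problem: PanelProblem, w: np.ndarray, xi: np.ndarray) -> float:
    """Recompute the unperturbed objective from a (w, xi) assignment."""
    zp = problem.zt.pair_matrix()
    D = float(zp.sum())
    d = zp @ w
    return (
        D
        - float(d.sum())
        + problem.lambda_ * float(np.sum(xi))
        - problem.mu * float(np.dot(w, problem.ss_l))
    )


def tight_slack(problem: PanelProblem, w: np.ndarray) -> np.ndarray:
    """Slack values at their optimal (tight) level for a given selection."""
    zp = problem.zt.pair_matrix()
    target = zp.sum(axis=1) / problem.zt.n
    return np.maximum(0.0, target - (zp @ w) / problem.k)


def _lexicographic_repair(
    problem: PanelProblem, w: np.ndarray, tol: float = TIE_TOL
) -> np.ndarray:
    """Move an optimal panel to its lexicographically smallest equivalent.

    MILP solvers return an arbitrary optimum when panels tie (duplicate or
    interchangeable genes) and an objective perturbation small enough not to
    distort real optima is invisible below solver tolerances, so ties are
    resolved after the solve: repeatedly swap a selected gene for a
    smaller-index unselected gene whenever the swap does not worsen the
    objective by more than ``tol``. Terminates because each accepted swap
    strictly decreases the selected index sum.
    """
    zp = problem.zt.pair_matrix()
    target = zp.sum(axis=1) / problem.zt.n
    D = float(zp.sum())

    def objective(wv: np.ndarray) -> float:
        d = zp @ wv
        xi = np.maximum(0.0, target - d / problem.k)
        return (D - float(d.sum()) + problem.lambda_ * float(xi.sum())
                - problem.mu * float(wv @ problem.ss_l))

    w = w.copy()
    best = objective(w)
    improved = True
    while improved:
        improved = False
        selected = np.nonzero(w > 0.5)[0][::-1]  # largest index first
        unselected = np.nonzero(w < 0.5)[0]
        for s in selected:
            for t in unselected:
                if t >= s:
                    break
                w2 = w.copy()
                w2[s], w2[t] = 0.0, 1.0
                obj2 = objective(w2)
                if obj2 <= best + tol:
                    w, best = w2, min(best, obj2)
                    improved = True
                    break
            if improved:
                break
    return w


def build_mip(problem: PanelProblem) -> MIPModel:
    """Assemble the MILP: n binaries, m(m-1)/2 slacks, 1 + m(m-1)/2 rows.

    d_ij is substituted inline so the model is linear in w; the objective's
    gene coefficients therefore read -(Σ_{i<j} z_ijl) - mu*ss_l and the
    constant term is D.
    """
    zt, n, k = problem.zt, problem.zt.n, problem.k
    zp = zt.pair_matrix()  # (P, n)
    P = zp.shape[0]
    c = np.concatenate(
        [
            -zp.sum(axis=0) - problem.mu * problem.ss_l,
            np.full(P, problem.lambda_),
        ]
    )
    integrality = np.concatenate([np.ones(n), np.zeros(P)])
    bounds = Bounds(
        lb=np.zeros(n + P),
        ub=np.concatenate([np.ones(n), np.full(P, np.inf)]),
    )
    card = LinearConstraint(
        np.concatenate([np.ones(n), np.zeros(P)])[None, :], lb=k, ub=k
    )
    # (1/k) Σ_l w_l z_ijl + xi_ij >= (1/n) Σ_l z_ijl
    A = np.hstack([zp / k, np.eye(P)])
    pair_rows = LinearConstraint(A, lb=zp.sum(axis=1) / n, ub=np.inf)
    return MIPModel(
        c=c,
        constant=float(zp.sum()),
        integrality=integrality,
        bounds=bounds,
        constraints=(card, pair_rows),
        n=n,
        n_pairs=P,
    )


def solve_mip(
    problem: PanelProblem,
    options: SolverOptions | None = None,
    relax: bool = False,
) -> PanelSolution:
    """Solve the panel MILP (or its [0,1] continuous relaxation).

    Returns status ``optimal`` when HiGHS proves optimality within the gap
    tolerance, ``feasible`` when a time limit stops the search early, and
    ``error`` with the backend message otherwise (the model is always
    feasible for 1 <= k <= n).
    """
    options = options or SolverOptions()
    model = build_mip(problem)
    milp_opts: dict = {"mip_rel_gap": options.gap_tol}
    if options.time_limit is not None:
        milp_opts["time_limit"] = options.time_limit
    integrality = np.zeros_like(model.integrality) if relax else model.integrality
    res = milp(
        c=model.c,
        integrality=integrality,
        bounds=model.bounds,
        constraints=model.constraints,
        options=milp_opts,
    )
    params = {"k": problem.k, "lambda": problem.lambda_, "mu": problem.mu, "relaxed": relax}
    if res.x is None:
        status = "infeasible" if res.status == 2 else "error"
        return PanelSolution(
            w=np.zeros(problem.zt.n),
            xi=np.zeros(model.n_pairs),
            objective=np.nan,
            status=status,
            parameters=params,
            message=res.message,
        )
    w = res.x[: model.n]
    if not relax:
        w = np.round(w)
        w = _lexicographic_repair(problem, w, tol=options.tie_tol)
    # re-derive the slack at its tight value for the returned w: solver xi
    # carries feasibility-tolerance noise that lambda would amplify in the
    # reported objective
    xi = tight_slack(problem, w)
    objective = _objective_terms(problem, w, xi)
    status = "optimal" if res.status == 0 else "feasible"
    return PanelSolution(
        w=w,
        xi=xi,
        objective=objective,
        status=status,
        d=panel_distances(problem.zt, w),
        parameters=params,
        message=res.message,
    )


def exhaustive_oracle(
    problem: PanelProblem,
    max_subsets: int = 10**6,
    tie_tol: float = TIE_TOL,
) -> PanelSolution:
    """Global optimum by enumerating every k-subset (small instances only).

    For each subset the slack takes its tight value
    max(0, (1/n)Σ_l z_ijl − (1/k)Σ_{l∈panel} z_ijl). Subsets within
    ``tie_tol`` of the optimum count as tied and the lexicographically
    smallest wins — the same rule the MILP path applies — so the two paths
    return identical panels on degenerate instances.
    """
    from math import comb

    n, k = problem.zt.n, problem.k
    if comb(n, k) > max_subsets:
        raise ValueError(f"C({n},{k}) exceeds the enumeration limit {max_subsets}")
    zp = problem.zt.pair_matrix()
    target = zp.sum(axis=1) / n
    D = float(zp.sum())

    def objective_of(idx: np.ndarray) -> float:
        d = zp[:, idx].sum(axis=1)
        xi = np.maximum(0.0, target - d / k)
        return (D - float(d.sum()) + problem.lambda_ * float(xi.sum())
                - problem.mu * float(problem.ss_l[idx].sum()))

    best_obj = min(
        objective_of(np.array(s)) for s in itertools.combinations(range(n), k)
    )
    # combinations() enumerates subsets in lexicographic order: the first
    # one within the tie tolerance is the lexicographically smallest
    for subset in itertools.combinations(range(n), k):
        if objective_of(np.array(subset)) <= best_obj + tie_tol:
            break
    w = np.zeros(n)
    w[list(subset)] = 1.0
    xi = tight_slack(problem, w)
    return PanelSolution(
        w=w,
        xi=xi,
        objective=_objective_terms(problem, w, xi),
        status="optimal",
        d=panel_distances(problem.zt, w),
        parameters={"k": k, "lambda": problem.lambda_, "mu": problem.mu, "oracle": True},
    )


def sweep_parameters(
    zt: DifferenceTensor,
    ss_l: np.ndarray,
    k_values: Iterable[int],
    lambda_values: Iterable[float],
    mu_values: Iterable[float],
    options: SolverOptions | None = None,
    c1_threshold: float = 0.5,
    z_threshold: float = 0.5,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Grid sweep over (k, lambda, mu); one row per grid point.

    Each row records the selected panel, the unperturbed objective, the
    solver status and the three accuracy criteria. Solver errors are
    recorded in the row and the sweep continues.
    """
    from .evaluate import criteria_for_panel

    rows = []
    for k in k_values:
        for lam in lambda_values:
            for mu in mu_values:
                try:
                    sol = solve_mip(PanelProblem(zt, ss_l, k, lam, mu), options)
                except Exception as exc:  # pragma: no cover - defensive
                    rows.append(
                        {"k": k, "lambda": lam, "mu": mu, "status": "error",
                         "panel": "", "objective": np.nan,
                         "C1": np.nan, "C2": np.nan, "C3": np.nan,
                         "message": str(exc)}
                    )
                    continue
                if sol.status in ("optimal", "feasible"):
                    crit = criteria_for_panel(
                        zt, sol.w, c1_threshold=c1_threshold, z_threshold=z_threshold
                    )
                    panel = (
                        ",".join(gene_ids[i] for i in sol.selected)
                        if gene_ids is not None
                        else ",".join(map(str, sol.selected))
                    )
                    rows.append(
                        {"k": k, "lambda": lam, "mu": mu, "status": sol.status,
                         "panel": panel, "objective": sol.objective,
                         "C1": crit.C1, "C2": crit.C2, "C3": crit.C3,
                         "message": sol.message}
                    )
                else:
                    rows.append(
                        {"k": k, "lambda": lam, "mu": mu, "status": sol.status,
                         "panel": "", "objective": np.nan,
                         "C1": np.nan, "C2": np.nan, "C3": np.nan,
                         "message": sol.message}
                    )
    return pd.DataFrame(rows)
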