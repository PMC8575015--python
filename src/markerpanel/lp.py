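"""Linear-programming relaxation for high-dimensional inputs.

The binary selection variable is relaxed to w_l >= 0 and the per-pair
topology constraint becomes an equality split into positive/negative slack:

    minimize   Σ_{i<j} (xi+_ij + xi-_ij) + lambda Σ_l w_l - mu Σ_l w_l ss_l
    subject to Σ_l z_ijl - Σ_l w_l z_ijl = xi+_ij - xi-_ij   for every pair
               w_l, xi+_ij, xi-_ij >= 0

The lambda term now plays the panel-size role (an L1 penalty on the weights)
rather than weighting the slack. Because w has no upper bound, the LP is
unbounded when the specificity reward for some gene outruns both the L1
penalty and the worst-case slack cost; this is detected and rejected with
guidance before the solver runs. Basic optimal solutions are vertex-sparse:
at most m(m-1)/2 weights are nonzero, which is what makes the relaxation
usable at genome scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.optimize import linprog

from .difference import DifferenceTensor

__all__ = ["LPSolution", "build_lp", "solve_lp", "discretize_weights", "select_lp"]


@dataclass(frozen=True)
class LPModel:
    """Flat LP description: variables [w (n), xi+ (P), xi- (P)]."""

    c: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    n: int
    n_pairs: int
    lambda_: float
    mu: float


@dataclass
class LPSolution:
    w: np.ndarray
    xi_plus: np.ndarray
    xi_minus: np.ndarray
    objective: float
    status: str  # optimal | unbounded | error
    parameters: dict = field(default_factory=dict)
    message: str = ""

    @property
    def support(self) -> np.ndarray:
        return np.nonzero(self.w > 1e-9)[0]


def build_lp(
    zt: DifferenceTensor, ss_l: np.ndarray, lambda_: float, mu: float
) -> LPModel:
    """Assemble the LP: n + 2*m(m-1)/2 variables, one equality per pair."""
    if lambda_ < 0 or mu < 0:
        raise ValueError("lambda_ and mu must be nonnegative")
    ss_l = np.asarray(ss_l, dtype=float)
    if ss_l.shape != (zt.n,):
        raise ValueError("ss_l length must equal the gene count")
    zp = zt.pair_matrix()  # (P, n)
    P, n = zp.shape
    # equality rewritten as  Σ_l w_l z_ijl + xi+ - xi- = Σ_l z_ijl
    A_eq = np.hstack([zp, np.eye(P), -np.eye(P)])
    b_eq = zp.sum(axis=1)
    c = np.concatenate([lambda_ - mu * ss_l, np.ones(P), np.ones(P)])
    return LPModel(c=c, A_eq=A_eq, b_eq=b_eq, n=n, n_pairs=P, lambda_=lambda_, mu=mu)


def check_bounded(zt: DifferenceTensor, ss_l: np.ndarray, lambda_: float, mu: float) -> None:
    """Reject parameter settings that certifiably make the LP unbounded.

    Growing some w_l forever pays lambda - mu*ss_l per unit plus at most the
    total slack cost D per unit once all xi+ are exhausted; if the reward for
    the best gene exceeds that, no finite optimum exists and lambda must be
    raised.
    """
    D = float(zt.pair_matrix().sum())
    worst = float(mu * np.max(ss_l))
    if worst >= lambda_ + D:
        raise ValueError(
            f"LP is unbounded: mu*max(ss)={worst:.4g} >= lambda + D = "
            f"{lambda_ + D:.4g}; raise lambda or lower mu"
        )


def solve_lp(
    zt: DifferenceTensor,
    ss_l: np.ndarray,
    lambda_: float,
    mu: float = 0.0,
) -> LPSolution:
    """Solve the relaxation with HiGHS; returns a basic (vertex) solution."""
    check_bounded(zt, ss_l, lambda_, mu)
    model = build_lp(zt, ss_l, lambda_, mu)
    res = linprog(
        c=model.c,
        A_eq=model.A_eq,
        b_eq=model.b_eq,
        bounds=(0, None),
        method="highs",
    )
    params = {"lambda": lambda_, "mu": mu}
    if res.status == 3:
        return LPSolution(
            w=np.zeros(model.n), xi_plus=np.zeros(model.n_pairs),
            xi_minus=np.zeros(model.n_pairs), objective=-np.inf,
            status="unbounded", parameters=params,
            message="LP unbounded: raise lambda or lower mu",
        )
    if res.x is None:
        return LPSolution(
            w=np.zeros(model.n), xi_plus=np.zeros(model.n_pairs),
            xi_minus=np.zeros(model.n_pairs), objective=np.nan,
            status="error", parameters=params, message=res.message,
        )
    w = res.x[: model.n]
    xi_plus = res.x[model.n : model.n + model.n_pairs]
    xi_minus = res.x[model.n + model.n_pairs :]
    return LPSolution(
        w=w, xi_plus=xi_plus, xi_minus=xi_minus,
        objective=float(res.fun), status="optimal",
        parameters=params, message=res.message,
    )


def discretize_weights(
    sol: LPSolution,
    mode: str = "top_k",
    k: int | None = None,
    tau: float = 1e-6,
) -> list[int]:
    """Turn continuous weights into an ordered gene-index panel.

    ``top_k`` returns the k largest-weight genes (descending weight, ties by
    gene index); ``threshold`` returns every gene with w > tau in the same
    order. When k exceeds the positive support a warning is raised and the
    support is returned.
    """
    w = np.asarray(sol.w, dtype=float)
    if mode == "top_k":
        if k is None:
            raise ValueError("top_k mode requires k")
        support = np.nonzero(w > 0)[0]
        if k > support.size:
            warnings.warn(
                f"k={k} exceeds the positive support ({support.size}); "
                "returning the full support", stacklevel=2,
            )
            k = support.size
        order = np.lexsort((np.arange(w.size), -w))
        return [int(i) for i in order[:k]]
    if mode == "threshold":
        idx = np.nonzero(w > tau)[0]
        order = np.lexsort((idx, -w[idx]))
        return [int(idx[i]) for i in order]
    raise ValueError(f"unknown mode {mode!r}")


def select_lp(
    zt: DifferenceTensor,
    ss_l: np.ndarray,
    lambda_: float,
    mu: float = 0.0,
    mode: str = "top_k",
    k: int | None = None,
    tau: float = 1e-6,
) -> tuple[LPSolution, list[int]]:
    """Solve the LP and discretize in one call."""
    sol = solve_lp(zt, ss_l, lambda_, mu)
    if sol.status != "optimal":
        return sol, []
    return sol, discretize_weights(sol, mode=mode, k=k, tau=tau)
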