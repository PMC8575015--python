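"""Panel accuracy criteria.

All three criteria are fractions, over the m(m-1)/2 unordered cell-type
pairs, of pairs the panel separates:

* C1 — the raw selected-panel distance d_ij exceeds a threshold T (0.5 by
  default). d_ij is the un-normalized sum over selected genes, so C1 depends
  on the panel size k.
* C2 — at least one selected gene has distinguishability z_ijl above the
  z-threshold (0.5, i.e. fold change above the sigmoid midpoint y0).
* C3 — at least two such genes; C3 <= C2 always, and a single-gene panel
  forces C3 = 0.

Indicators use strict inequality throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .difference import DifferenceTensor, PairwiseDistances, panel_distances

__all__ = [
    "CriteriaResult",
    "criterion1",
    "criterion2",
    "criterion3",
    "criteria_for_panel",
    "accuracy_curve",
]


@dataclass(frozen=True)
class CriteriaResult:
    C1: float
    C2: float
    C3: float
    c1_pass: np.ndarray  # per-pair 0/1 indicators, canonical pair order
    qualifying_counts: np.ndarray  # selected genes with z > threshold, per pair
    c1_threshold: float
    z_threshold: float

    def as_dict(self) -> dict[str, float]:
        return {"C1": self.C1, "C2": self.C2, "C3": self.C3}


def criterion1(d: PairwiseDistances, T: float = 0.5) -> float:
    """Fraction of pairs with selected-panel distance d_ij > T."""
    return float(np.mean(d.d > T))


def _qualifying_counts(
    zt: DifferenceTensor, w: np.ndarray, z_threshold: float
) -> np.ndarray:
    w = np.asarray(w)
    if w.shape != (zt.n,):
        raise ValueError(f"selection vector has shape {w.shape}, expected ({zt.n},)")
    sel = w > 0.5
    return (zt.pair_matrix()[:, sel] > z_threshold).sum(axis=1)


def criterion2(zt: DifferenceTensor, w: np.ndarray, z_threshold: float = 0.5) -> float:
    """Fraction of pairs with >= 1 selected gene above the z-threshold."""
    return float(np.mean(_qualifying_counts(zt, w, z_threshold) >= 1))


def criterion3(zt: DifferenceTensor, w: np.ndarray, z_threshold: float = 0.5) -> float:
    """Fraction of pairs with >= 2 selected genes above the z-threshold."""
    return float(np.mean(_qualifying_counts(zt, w, z_threshold) >= 2))


def criteria_for_panel(
    zt: DifferenceTensor,
    w: np.ndarray,
    c1_threshold: float = 0.5,
    z_threshold: float = 0.5,
) -> CriteriaResult:
    """All three criteria plus per-pair diagnostics for one panel."""
    d = panel_distances(zt, np.asarray(w, dtype=float))
    counts = _qualifying_counts(zt, w, z_threshold)
    return CriteriaResult(
        C1=criterion1(d, c1_threshold),
        C2=float(np.mean(counts >= 1)),
        C3=float(np.mean(counts >= 2)),
        c1_pass=(d.d > c1_threshold).astype(int),
        qualifying_counts=counts,
        c1_threshold=c1_threshold,
        z_threshold=z_threshold,
    )


def accuracy_curve(
    zt: DifferenceTensor,
    ss_l: np.ndarray,
    k_range,
    lambda_: float = 100.0,
    mu: float = 10.0,
    options=None,
    c1_threshold: float = 0.5,
    z_threshold: float = 0.5,
) -> pd.DataFrame:
    """Criteria of the optimal panel at each k (accuracy-vs-k curve)."""
    from .mip import PanelProblem, solve_mip

    rows = []
    for k in k_range:
        sol = solve_mip(PanelProblem(zt, ss_l, int(k), lambda_, mu), options)
        if sol.status in ("optimal", "feasible"):
            crit = criteria_for_panel(zt, sol.w, c1_threshold, z_threshold)
            rows.append({"k": int(k), "C1": crit.C1, "C2": crit.C2, "C3": crit.C3,
                         "status": sol.status})
        else:
            rows.append({"k": int(k), "C1": np.nan, "C2": np.nan, "C3": np.nan,
                         "status": sol.status})
    return pd.DataFrame(rows, columns=["k", "C1", "C2", "C3", "status"])
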