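"""Pairwise cell-type distinguishability from fold changes.

For every unordered pair of cell types (i, j) and every gene l, the symmetric
pseudocounted fold change

    y_ijl = (S_il + 1) / (S_jl + 1)   if S_il > S_jl, else the reciprocal,

is squashed through a sigmoid

    z_ijl = 1 / (1 + exp(-theta * (y_ijl - y0)))

so that z ≈ 0 for fold changes near 1 (gene cannot separate the pair) and
z ≈ 1 for fold changes well above the midpoint y0. With the defaults
theta=10, y0=3 a unit fold change maps to ~2.1e-9.

Selected-panel distances d_ij = Σ_l w_l z_ijl and the all-gene total
D = Σ_{i<j} Σ_l z_ijl are the building blocks of the selection objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "fold_change",
    "sigmoid_difference",
    "panel_distances",
    "pair_index",
    "DifferenceTensor",
    "PairwiseDistances",
]

# z is clamped into this open interval so downstream logs/ratios never see
# exactly 0 or 1; the bound is far below any decision threshold in use.
_Z_CLAMP = 1e-15


def pair_index(m: int) -> list[tuple[int, int]]:
    """Canonical enumeration of the m(m-1)/2 unordered pairs, i < j."""
    return [(i, j) for i in range(m) for j in range(i + 1, m)]


@dataclass(frozen=True)
class DifferenceTensor:
    """Sigmoid-transformed fold changes, shape (m, m, n), entries in (0, 1)."""

    z: np.ndarray
    theta: float
    y0: float

    @property
    def m(self) -> int:
        return self.z.shape[0]

    @property
    def n(self) -> int:
        return self.z.shape[2]

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return pair_index(self.m)

    def pair_matrix(self) -> np.ndarray:
        """Array of shape (n_pairs, n): z restricted to the i<j pairs."""
        idx = np.array(self.pairs)
        return self.z[idx[:, 0], idx[:, 1], :]

    def total(self) -> float:
        """All-gene, all-pair total D."""
        return float(self.pair_matrix().sum())


@dataclass(frozen=True)
class PairwiseDistances:
    """Selected-panel distances d_ij per pair and the all-gene total D."""

    d: np.ndarray  # length m(m-1)/2, ordered as pair_index(m)
    D: float
    pairs: tuple[tuple[int, int], ...]

    def discrepancy(self) -> float:
        """D - Σ_{i<j} d_ij, the total topology discrepancy (always >= 0)."""
        return self.D - float(self.d.sum())


def fold_change(em: ExpressionMatrix) -> np.ndarray:
    """Symmetric pseudocounted fold-change tensor, shape (m, m, n).

    The branch test compares the raw values (``S_il > S_jl``), which is
    equivalent to the raw ratio exceeding 1 for positive values and remains
    defined when either value is zero; the reported ratio always adds a
    pseudocount of 1 to numerator and denominator.
    """
    S = em.S
    hi = np.maximum(S[:, None, :], S[None, :, :])
    lo = np.minimum(S[:, None, :], S[None, :, :])
    return (hi + 1.0) / (lo + 1.0)


def sigmoid_difference(y: np.ndarray, theta: float = 10.0, y0: float = 3.0) -> DifferenceTensor:
    """Transform fold changes into distinguishability scores in (0, 1)."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    y = np.asarray(y, dtype=float)
    if np.any(y < 1):
        raise ValueError("fold changes must be >= 1")
    # exp argument is negated and can overflow for very large y*theta;
    # evaluate in a clipped domain then clamp into the open unit interval.
    arg = np.clip(-theta * (y - y0), -700.0, 700.0)
    z = 1.0 / (1.0 + np.exp(arg))
    z = np.clip(z, _Z_CLAMP, 1.0 - _Z_CLAMP)
    return DifferenceTensor(z=z, theta=float(theta), y0=float(y0))


def difference_tensor(
    em: ExpressionMatrix, theta: float = 10.0, y0: float = 3.0
) -> DifferenceTensor:
    """Convenience: fold changes + sigmoid transform in one call."""
    return sigmoid_difference(fold_change(em), theta=theta, y0=y0)


def panel_distances(zt: DifferenceTensor, w: np.ndarray) -> PairwiseDistances:
    """Pair distances d_ij = Σ_l w_l z_ijl for a selection vector w.

    ``w`` may be binary (a panel) or fractional (a relaxation); D is the
    all-gene total and does not depend on w.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (zt.n,):
        raise ValueError(f"selection vector has shape {w.shape}, expected ({zt.n},)")
    zp = zt.pair_matrix()
    d = zp @ w
    return PairwiseDistances(d=d, D=float(zp.sum()), pairs=tuple(zt.pairs))


def pair_distance_frame(zt: DifferenceTensor, cell_type_ids) -> pd.DataFrame:
    """Square gene-summed distance matrix (for export / external clustering)."""
    full = zt.z.sum(axis=2)
    np.fill_diagonal(full, 0.0)
    ids = list(cell_type_ids)
    return pd.DataFrame(full, index=ids, columns=ids)
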