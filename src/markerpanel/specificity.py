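"""Cell type specificity scores from Jensen–Shannon divergence.

A gene is specific to a cell type when its expression there stands out from a
background summary of its expression everywhere else. For gene l and cell
type j we compare two 2-element probability vectors:

* observed  u = normalize([S_jl + 1, b_l + 1]), where b_l is the third
  quartile of the gene's expression across all cell types (the background);
* idealized v = [1, 0] — all mass on the cell type, none on the background.

Their Jensen–Shannon divergence ds_jl (base-2 logs, so ds ∈ [0, 1]) measures
how far the observed pattern is from perfectly specific; the specificity
score is ss_jl = -log10(ds_jl), and a gene's overall score ss_l is its
maximum over cell types. ds is floored at 1e-12 so ss is finite (capped at
12, far above any realistic score).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "SpecificityTable",
    "observed_ideal_vectors",
    "jsd",
    "specificity_scores",
    "assign_markers",
    "top_genes_per_cell_type",
]

DS_FLOOR = 1e-12


@dataclass(frozen=True)
class SpecificityTable:
    cell_type_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    ds: np.ndarray  # (m, n) JSD values in [DS_FLOOR, 1]
    ss: np.ndarray  # (m, n) -log10(ds)
    ss_l: np.ndarray  # (n,) per-gene maxima over cell types
    background: np.ndarray  # (n,) third-quartile expression per gene

    def to_frame(self) -> pd.DataFrame:
        """Per-gene, per-cell-type specificity scores (genes × cell types)."""
        return pd.DataFrame(
            self.ss.T, index=list(self.gene_ids), columns=list(self.cell_type_ids)
        )


def observed_ideal_vectors(
    em: ExpressionMatrix, j: int, l: int
) -> tuple[np.ndarray, np.ndarray]:
    """The observed and idealized 2-vectors for cell type j, gene l."""
    b = float(np.percentile(em.S[:, l], 75))
    u = np.array([em.S[j, l] + 1.0, b + 1.0])
    return u / u.sum(), np.array([1.0, 0.0])


def jsd(u: np.ndarray, v: np.ndarray) -> float:
    """Jensen–Shannon divergence with base-2 logarithms, in [0, 1].

    JSD(u, v) = 0.5*KL(u||m) + 0.5*KL(v||m) with m = (u+v)/2; terms with
    zero numerator contribute zero. Inputs must be nonnegative and sum to 1.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("probability vectors differ in length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("probability vectors must be nonnegative")
    if abs(u.sum() - 1.0) > 1e-9 or abs(v.sum() - 1.0) > 1e-9:
        raise ValueError("probability vectors must each sum to 1")
    mid = 0.5 * (u + v)

    def kl(p: np.ndarray, q: np.ndarray) -> float:
        mask = p > 0
        return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))

    return 0.5 * kl(u, mid) + 0.5 * kl(v, mid)


def specificity_scores(em: ExpressionMatrix) -> SpecificityTable:
    """Compute ds, ss and the per-gene maxima for the whole matrix.

    Vectorized closed form of the per-(j, l) JSD: with u = [a, 1-a] and
    v = [1, 0], JSD = 1 + 0.5*(a*log2(a) + (1-a)*log2(1-a)) - 0.5*(1+a)*log2(1+a)
    + 0.5*a, where a is the observed vector's first component. The tests
    check this against the explicit two-vector construction.
    """
    S = em.S
    b = np.percentile(S, 75, axis=0)  # (n,) third quartile incl. cell j
    a = (S + 1.0) / (S + 1.0 + b[None, :] + 1.0)  # first component of u
    # JSD([a,1-a],[1,0]) base 2, term-by-term (all a in (0,1) by pseudocount):
    mid1 = 0.5 * (a + 1.0)
    mid2 = 0.5 * (1.0 - a)
    ds = 0.5 * (
        a * np.log2(a / mid1) + (1.0 - a) * np.log2((1.0 - a) / mid2)
    ) + 0.5 * np.log2(1.0 / mid1)
    ds = np.clip(ds, DS_FLOOR, 1.0)
    ss = -np.log10(ds)
    return SpecificityTable(
        cell_type_ids=em.cell_type_ids,
        gene_ids=em.gene_ids,
        ds=ds,
        ss=ss,
        ss_l=ss.max(axis=0),
        background=b,
    )


def assign_markers(spec: SpecificityTable, cutoff: float = 1.3) -> dict[str, list[str]]:
    """Assign each gene to the cell types where its score reaches the cutoff.

    Gene l is a marker for cell type j iff ss_jl >= cutoff; genes below the
    cutoff everywhere are omitted from the mapping.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    out: dict[str, list[str]] = {}
    hit = spec.ss >= cutoff
    for l, g in enumerate(spec.gene_ids):
        js = np.nonzero(hit[:, l])[0]
        if js.size:
            out[g] = [spec.cell_type_ids[j] for j in js]
    return out


def top_genes_per_cell_type(spec: SpecificityTable, k: int) -> list[str]:
    """Single-gene baseline: pool the top-scoring gene of each cell type.

    Walks cell types in order repeatedly taking each one's best not-yet-chosen
    gene (ties by gene order) until k distinct genes are collected. This is a
    comparison utility, not part of the optimization path.
    """
    chosen: list[str] = []
    ranked = np.argsort(-spec.ss, axis=1, kind="stable")  # (m, n) per-type ranking
    depth = 0
    while len(chosen) < k and depth < spec.ss.shape[1]:
        for j in range(spec.ss.shape[0]):
            g = spec.gene_ids[ranked[j, depth]]
            if g not in chosen:
                chosen.append(g)
                if len(chosen) == k:
                    break
        depth += 1
    return chosen
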