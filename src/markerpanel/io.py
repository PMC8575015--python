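"""Input/output and the shared data model.

The central container is :class:`ExpressionMatrix`: one expression profile per
cell type over a common gene set, stored internally as an ``m × n`` array
(``m`` cell types in rows, ``n`` genes in columns) regardless of the on-disk
orientation. Values are arbitrary nonnegative units (FPKM, TPM, counts,
accessibility scores); downstream fold changes use a pseudocount of 1, which
is unit-sensitive, so callers should keep units consistent across runs.

Region identifiers such as ``chr3:93354000-93356000`` are treated as opaque
gene IDs; no coordinate arithmetic is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "RunConfig",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_list",
    "subset_genes",
    "write_panel_report",
    "read_panel_report",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative expression profiles, one row per cell type.

    Parameters
    ----------
    cell_type_ids
        Unique cell-type (tissue/sample) identifiers, length ``m >= 2``.
    gene_ids
        Unique gene identifiers, length ``n >= 1``.
    S
        Array of shape ``(m, n)`` with finite, nonnegative entries;
        ``S[i, l]`` is the expression of gene ``l`` in cell type ``i``.
    """

    cell_type_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    S: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "cell_type_ids", tuple(str(c) for c in self.cell_type_ids))
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        m, n = len(self.cell_type_ids), len(self.gene_ids)
        if S.ndim != 2 or S.shape != (m, n):
            raise ValueError(f"expression array has shape {S.shape}, expected ({m}, {n})")
        if m < 2:
            raise ValueError("at least 2 cell types are required")
        if n < 1:
            raise ValueError("at least 1 gene is required")
        dup = _duplicates(self.cell_type_ids)
        if dup:
            raise ValueError(f"duplicate cell type IDs: {sorted(dup)}")
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ValueError(f"duplicate gene IDs: {sorted(dup)}")
        if not np.all(np.isfinite(S)):
            i, l = np.argwhere(~np.isfinite(S))[0]
            raise ValueError(
                f"non-finite value at cell type {self.cell_type_ids[i]!r}, "
                f"gene {self.gene_ids[l]!r}"
            )
        if np.any(S < 0):
            i, l = np.argwhere(S < 0)[0]
            raise ValueError(
                f"negative value {S[i, l]} at cell type {self.cell_type_ids[i]!r}, "
                f"gene {self.gene_ids[l]!r}"
            )

    @property
    def m(self) -> int:
        return len(self.cell_type_ids)

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Column indices for the given gene IDs (KeyError on a miss)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        """Genes-in-rows DataFrame (genes × cell types), the on-disk default."""
        return pd.DataFrame(
            self.S.T, index=list(self.gene_ids), columns=list(self.cell_type_ids)
        )


@dataclass
class RunConfig:
    """Tunable parameters for a complete run, with the published defaults.

    theta
        Sigmoid steepness for the fold-change transform; larger values push
        the distinguishability of near-unit fold changes toward zero faster.
    y0
        Sigmoid midpoint on the fold-change axis: a fold change of ``y0``
        maps to distinguishability 0.5.
    k
        Panel size (number of selected genes).
    lambda_
        Penalty on the per-pair topology slack.
    mu
        Weight on the summed specificity of selected genes.
    c1_threshold
        Threshold T on the raw selected-panel pair distance for criterion 1.
    z_threshold
        Distinguishability threshold for criteria 2 and 3.
    mi_cutoff
        Mutual-information edge cutoff for the cell-type network.
    specificity_cutoff
        Per-cell-type specificity score cutoff for marker assignment.
    """

    theta: float = 10.0
    y0: float = 3.0
    k: int = 10
    lambda_: float = 100.0
    mu: float = 10.0
    c1_threshold: float = 0.5
    z_threshold: float = 0.5
    mi_cutoff: float = 0.25
    specificity_cutoff: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.y0 <= 1:
            raise ValueError("y0 must exceed 1 (fold changes are >= 1)")
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.lambda_ < 0 or self.mu < 0:
            raise ValueError("lambda_ and mu must be nonnegative")
        if not 0 < self.z_threshold < 1:
            raise ValueError("z_threshold must lie in (0, 1)")
        if self.c1_threshold <= 0:
            raise ValueError("c1_threshold must be positive")
        if self.mi_cutoff < 0 or self.specificity_cutoff < 0:
            raise ValueError("cutoffs must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


def _delimiter_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression_matrix(
    path: str | Path, orientation: str = "genes_in_rows"
) -> ExpressionMatrix:
    """Read a delimited expression matrix (header row + one ID column).

    ``orientation`` says what the file rows are: ``"genes_in_rows"`` (default;
    header = cell types) or ``"cell_types_in_rows"`` (header = genes). The
    returned matrix is always cell types × genes internally.
    """
    if orientation not in ("genes_in_rows", "cell_types_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    bad = df.columns[~df.dtypes.apply(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric cell at row {row!r}, column {col!r} in {path}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ValueError(f"missing/NaN cell at row {row!r}, column {col!r} in {path}")
    if orientation == "genes_in_rows":
        gene_ids, cell_type_ids = list(df.index), list(df.columns)
        S = df.to_numpy(dtype=float).T
    else:
        cell_type_ids, gene_ids = list(df.index), list(df.columns)
        S = df.to_numpy(dtype=float)
    return ExpressionMatrix(tuple(cell_type_ids), tuple(gene_ids), S)


def write_expression_matrix(
    em: ExpressionMatrix, path: str | Path, orientation: str = "genes_in_rows"
) -> None:
    """Write a matrix in the same layouts :func:`read_expression_matrix` reads."""
    df = em.to_frame()
    if orientation == "cell_types_in_rows":
        df = df.T
    elif orientation != "genes_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=_delimiter_for(path), float_format="%.12g")


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one ID per line; '#' starts a comment."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                out.append(entry)
    return out


def subset_genes(em: ExpressionMatrix, gene_list: Sequence[str]) -> ExpressionMatrix:
    """Restrict to the genes in ``gene_list``, preserving the list's order.

    IDs absent from the matrix are reported with a warning; an empty
    intersection is an error.
    """
    if not gene_list:
        raise ValueError("gene_list is empty")
    have = set(em.gene_ids)
    found = [g for g in gene_list if g in have]
    missing = [g for g in gene_list if g not in have]
    if not found:
        raise ValueError(f"no genes from the list are present in the matrix: {missing}")
    if missing:
        warnings.warn(f"{len(missing)} gene(s) not found in matrix: {missing}", stacklevel=2)
    idx = em.gene_index(found)
    return ExpressionMatrix(em.cell_type_ids, tuple(found), em.S[:, idx])


def write_panel_report(solution, spec, path: str | Path) -> None:
    """Write the selected panel as a TSV plus a JSON sidecar.

    TSV columns: gene_id, weight, specificity (gene max), best cell type
    (argmax of the per-cell-type score) and the cell types assigned at the
    specificity cutoff. The sidecar ``<path>.json`` records the objective,
    solver status, parameters and (if present) the accuracy criteria.

    ``solution`` is a solved PanelSolution or LPSolution; ``spec`` the
    SpecificityTable of the same matrix.
    """
    from .specificity import assign_markers  # local import avoids a cycle

    status = getattr(solution, "status", "error")
    if status not in ("optimal", "feasible"):
        raise ValueError(f"cannot report an unsolved problem (status={status!r})")
    w = np.asarray(solution.w, dtype=float)
    gene_ids = list(spec.gene_ids)
    if w.shape[0] != len(gene_ids):
        raise ValueError("solution and specificity table disagree on gene count")
    cutoff = getattr(solution, "specificity_cutoff", 1.3)
    assigned = assign_markers(spec, cutoff)
    order = np.argsort(-w, kind="stable")
    rows = []
    for l in order:
        if w[l] <= 0:
            continue
        g = gene_ids[l]
        best_j = int(np.argmax(spec.ss[:, l]))
        rows.append(
            {
                "gene_id": g,
                "weight": w[l],
                "ss_l": spec.ss_l[l],
                "best_cell_type": spec.cell_type_ids[best_j],
                "assigned_cell_types": ",".join(assigned.get(g, [])),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")
    sidecar = {
        "objective": float(solution.objective),
        "status": status,
        "n_selected": int(np.sum(w > 0)),
        "parameters": getattr(solution, "parameters", {}),
        "criteria": getattr(solution, "criteria", None),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_panel_report(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_panel_report`'s TSV."""
    return pd.read_csv(path, sep="\t")
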