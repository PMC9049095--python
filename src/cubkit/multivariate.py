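"""Correspondence analysis of the gene × codon RSCU matrix and NJ clustering.

:func:`coa` performs a chi-square-metric correspondence analysis via the
generalized SVD, yielding gene and codon coordinates in principal scaling
and per-axis inertia fractions.  :func:`nj_tree` runs neighbor joining on a
gene × gene distance matrix with deterministic tie-breaking and the
negative-branch adjustment, and serializes the result as newick text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "CoaResult",
    "ClusterTree",
    "coa",
    "rscu_distance_matrix",
    "nj_tree",
    "rscu_matrix",
]


def rscu_matrix(rscu_by_gene: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Assemble per-gene RSCU vectors into a genes × codons DataFrame.

    NaN entries (unused families) are replaced by 0, the natural value for a
    codon never observed in that gene.
    """
    df = pd.DataFrame.from_dict(rscu_by_gene, orient="index")
    return df[sorted(df.columns)].fillna(0.0)


@dataclass(frozen=True)
class CoaResult:
    """Gene and codon principal coordinates plus per-axis inertia."""

    gene_coords: pd.DataFrame
    codon_coords: pd.DataFrame
    inertia: np.ndarray
    total_inertia: float

    @property
    def inertia_fractions(self) -> np.ndarray:
        if self.total_inertia == 0:
            return np.zeros_like(self.inertia)
        return self.inertia / self.total_inertia


def coa(table: pd.DataFrame, n_axes: int | None = None) -> CoaResult:
    """Correspondence analysis of a non-negative genes × codons table.

    The table is treated as a contingency-style matrix: row/column profiles
    under the chi-square metric, decomposed by SVD of the standardized
    residual matrix.  Coordinates are returned in principal (not standard)
    scaling; axis signs are canonicalized so the largest-magnitude codon
    loading on each axis is positive.

    All-zero rows or columns are dropped with a warning before analysis.
    """
    X = table.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative entries in COA input")
    row_ok = X.sum(axis=1) > 0
    col_ok = X.sum(axis=0) > 0
    if not row_ok.all():
        warnings.warn(f"dropping {int((~row_ok).sum())} all-zero gene rows from COA")
    if not col_ok.all():
        warnings.warn(f"dropping {int((~col_ok).sum())} all-zero codon columns from COA")
    table = table.loc[row_ok, col_ok]
    X = table.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("fewer than 2 rows or columns after filtering")

    grand = X.sum()
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)

    tol = max(S.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > max(tol, 1e-14)
    U, s, Vt = U[:, keep], s[keep], Vt[keep, :]
    if n_axes is not None:
        U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes, :]

    if s.size == 0:
        empty_g = pd.DataFrame(index=table.index)
        empty_c = pd.DataFrame(index=table.columns)
        return CoaResult(empty_g, empty_c, np.array([]), 0.0)

    F = (U * s) / np.sqrt(r)[:, None]       # gene principal coordinates
    G = (Vt.T * s) / np.sqrt(c)[:, None]    # codon principal coordinates

    # sign canonicalization: largest-|loading| codon positive per axis
    for j in range(s.size):
        i = int(np.argmax(np.abs(G[:, j])))
        if G[i, j] < 0:
            G[:, j] *= -1
            F[:, j] *= -1

    axes = [f"axis{j + 1}" for j in range(s.size)]
    return CoaResult(
        gene_coords=pd.DataFrame(F, index=table.index, columns=axes),
        codon_coords=pd.DataFrame(G, index=table.columns, columns=axes),
        inertia=s**2,
        total_inertia=float((s**2).sum()),
    )


def rscu_distance_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Euclidean gene × gene distances between RSCU vectors."""
    if len(table) < 2:
        raise ValueError("need at least 2 genes")
    d = squareform(pdist(table.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


@dataclass(frozen=True)
class ClusterTree:
    """Unrooted tree over gene labels serialized as newick text."""

    newick: str
    leaves: tuple[str, ...]


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def to_newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{ch.to_newick()}:{bl:.10g}" for ch, bl in self.children)
        return f"({inner})"


def nj_tree(dist: pd.DataFrame) -> ClusterTree:
    """Neighbor joining on a symmetric distance matrix.

    Ties in the Q criterion break deterministically on the sorted label
    pair.  Negative branch lengths are clamped to 0 with the deficit moved
    to the sibling branch, preserving the pair's summed length.
    """
    D = dist.to_numpy(dtype=float).copy()
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("non-symmetric distance matrix")

    nodes = {lab: _Node(label=lab) for lab in labels}
    active = list(labels)
    dmat = {a: {b: D[i, j] for j, b in enumerate(labels)} for i, a in enumerate(labels)}

    counter = 0
    while len(active) > 2:
        n = len(active)
        r = {a: sum(dmat[a][b] for b in active if b != a) for a in active}
        best = None
        best_q = np.inf
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * dmat[a][b] - r[a] - r[b]
                key = tuple(sorted((str(a), str(b))))
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and
                                          (best is None or key < best[1])):
                    best_q = q
                    best = ((a, b), key)
        (a, b), _ = best
        d_ab = dmat[a][b]
        la = d_ab / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = d_ab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        counter += 1
        u = f"__nj{counter}"
        nodes[u] = _Node(children=[(nodes[a], la), (nodes[b], lb)])
        dmat[u] = {}
        for k in active:
            if k in (a, b):
                continue
            duk = (dmat[a][k] + dmat[b][k] - d_ab) / 2
            dmat[u][k] = dmat[k][u] = max(duk, 0.0)
        active = [k for k in active if k not in (a, b)] + [u]

    a, b = active
    d_ab = dmat[a][b]
    na, nb = nodes[a], nodes[b]
    if nb.children:  # hang the other node off the internal one
        na, nb = nb, na
    if na.children:
        na.children.append((nb, max(d_ab, 0.0)))
        root = na
    else:  # two leaves (cannot happen with >=3 taxa, kept for safety)
        root = _Node(children=[(na, d_ab / 2), (nb, d_ab / 2)])
    return ClusterTree(newick=root.to_newick() + ";",
                       leaves=tuple(sorted(str(x) for x in labels)))
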