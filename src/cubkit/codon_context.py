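"""In-frame adjacent codon-pair counting and context classification.

Pairs of consecutive sense codons are pooled across genes into a 61×61
matrix (first codon × second codon), compared to the independence
expectation from the margins, and classified over/under/absent/typical by
adjusted standardized residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_io import CodingSequence, GeneticCode, STANDARD_CODE

__all__ = [
    "CodonPairMatrix",
    "pair_counts",
    "expected_and_residuals",
    "classify_pairs",
    "context_heatmap_matrix",
]

CLASS_CODES = {"over": 1, "typical": 0, "under": -1, "absent": -2}


@dataclass(frozen=True)
class CodonPairMatrix:
    """Observed/expected/residual/class grids over sense-codon pairs.

    All four frames share the alphabetical sense-codon order on both axes
    (rows = first codon of the pair, columns = second).
    """

    observed: pd.DataFrame
    expected: pd.DataFrame | None = None
    residual: pd.DataFrame | None = None
    classes: pd.DataFrame | None = None

    @property
    def total_pairs(self) -> int:
        return int(self.observed.to_numpy().sum())


def pair_counts(
    genes: Sequence[CodingSequence], code: GeneticCode = STANDARD_CODE
) -> CodonPairMatrix:
    """Count in-frame adjacent sense-codon pairs pooled over all genes.

    Pairs never cross gene boundaries; pairs involving the terminal stop or
    an ambiguous codon are excluded.
    """
    if not genes:
        raise ValueError("empty gene set")
    codons = list(code.sense_codons)
    idx = {c: i for i, c in enumerate(codons)}
    obs = np.zeros((len(codons), len(codons)), dtype=np.int64)
    for g in genes:
        sense = g.sense_codons(code)
        for a, b in zip(sense, sense[1:]):
            ia, ib = idx.get(a), idx.get(b)
            if ia is not None and ib is not None:
                obs[ia, ib] += 1
    return CodonPairMatrix(
        observed=pd.DataFrame(obs, index=codons, columns=codons)
    )


def expected_and_residuals(matrix: CodonPairMatrix) -> CodonPairMatrix:
    """Independence expectations and adjusted standardized residuals.

    expected(i,j) = rowsum_i × colsum_j / total;
    residual(i,j) = (obs − exp) / sqrt(exp · (1 − rowsum_i/total) · (1 − colsum_j/total)).
    Cells with expected 0 (or a vanishing variance term) carry NaN residuals.
    """
    obs = matrix.observed.to_numpy(dtype=float)
    total = obs.sum()
    if total <= 0:
        raise ValueError("no codon pairs counted")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    exp = np.outer(rows, cols) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        var = exp * np.outer(1 - rows / total, 1 - cols / total)
        resid = (obs - exp) / np.sqrt(var)
    resid[~np.isfinite(resid)] = np.nan
    ix, cx = matrix.observed.index, matrix.observed.columns
    return replace(
        matrix,
        expected=pd.DataFrame(exp, index=ix, columns=cx),
        residual=pd.DataFrame(resid, index=ix, columns=cx),
    )


def classify_pairs(
    matrix: CodonPairMatrix,
    residual_threshold: float = 3.0,
    min_expected: float = 1.0,
) -> tuple[CodonPairMatrix, dict]:
    """Label every pair cell and summarize class fractions.

    ``absent`` iff observed = 0; ``over``/``under`` need observed > 0,
    |residual| ≥ threshold with matching sign, and expected ≥ ``min_expected``
    (the chi-square approximation is invalid below that, such cells stay
    ``typical`` and are tallied in the summary's warning count).
    """
    if matrix.residual is None:
        matrix = expected_and_residuals(matrix)
    obs = matrix.observed.to_numpy()
    exp = matrix.expected.to_numpy()
    resid = matrix.residual.to_numpy()
    cls = np.full(obs.shape, "typical", dtype=object)
    cls[obs == 0] = "absent"
    eligible = (obs > 0) & (exp >= min_expected) & np.isfinite(resid)
    cls[eligible & (resid >= residual_threshold)] = "over"
    cls[eligible & (resid <= -residual_threshold)] = "under"
    n_low_expected = int(((obs > 0) & (exp < min_expected)).sum())
    if n_low_expected:
        warnings.warn(
            f"{n_low_expected} occupied cells with expected < {min_expected} "
            "excluded from over/under classification"
        )
    n_cells = obs.size
    summary = {
        "n_cells": n_cells,
        "total_pairs": int(obs.sum()),
        "frac_over": float((cls == "over").sum() / n_cells),
        "frac_under": float((cls == "under").sum() / n_cells),
        "frac_absent": float((cls == "absent").sum() / n_cells),
        "frac_typical": float((cls == "typical").sum() / n_cells),
        "n_low_expected": n_low_expected,
    }
    ix, cx = matrix.observed.index, matrix.observed.columns
    return (
        replace(matrix, classes=pd.DataFrame(cls, index=ix, columns=cx)),
        summary,
    )


def context_heatmap_matrix(matrix: CodonPairMatrix) -> pd.DataFrame:
    """Integer class-code grid in alphabetical codon order for plotting.

    Codes: over = +1, typical = 0, under = −1, absent = −2.
    """
    if matrix.classes is None:
        raise ValueError("matrix is not classified")
    order = sorted(matrix.classes.index)
    grid = matrix.classes.loc[order, order].map(CLASS_CODES.__getitem__)
    return grid.astype(int)
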