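"""Neutrality-plot regression and PR2 bias coordinates.

The neutrality fit regresses GC12 on GC3 across genes (slope near 1 points
to mutation pressure sharing one driver across positions, near 0 to
selection decoupling them).  PR2 coordinates place each gene at
(A3/(A3+T3), G3/(G3+C3)) relative to the no-bias center (0.5, 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .composition import CodonCountTable, CompositionProfile
from .sequence_io import GeneticCode, STANDARD_CODE

__all__ = [
    "NeutralityFit",
    "Pr2Point",
    "neutrality_fit",
    "pr2_point",
    "pr2_point_from_counts",
    "fourfold_third_position_counts",
    "pr2_summary",
]


@dataclass(frozen=True)
class NeutralityFit:
    """OLS fit of GC12 on GC3 with the Pearson correlation of the two."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int


def neutrality_fit(profiles: Sequence[CompositionProfile]) -> NeutralityFit:
    """Ordinary least-squares regression of GC12 on GC3 across genes."""
    pts = [(p.GC3, p.GC12) for p in profiles
           if not (math.isnan(p.GC3) or math.isnan(p.GC12))]
    if len(pts) < 3:
        raise ValueError("need at least 3 genes with defined GC12 and GC3")
    x = np.array([a for a, _ in pts])
    y = np.array([b for _, b in pts])
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: GC3 is constant")
    if np.ptp(y) == 0:  # constant response: flat fit, zero correlation
        return NeutralityFit(slope=0.0, intercept=float(y[0]), r=0.0, p=1.0,
                             n=len(pts))
    res = stats.linregress(x, y)
    return NeutralityFit(slope=res.slope, intercept=res.intercept,
                         r=res.rvalue, p=res.pvalue, n=len(pts))


@dataclass(frozen=True)
class Pr2Point:
    """PR2 coordinates; a coordinate is None when its denominator is zero."""

    gene_id: str
    x: float | None  # A3 / (A3 + T3)
    y: float | None  # G3 / (G3 + C3)

    @property
    def defined(self) -> bool:
        return self.x is not None and self.y is not None


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def pr2_point(profile: CompositionProfile) -> Pr2Point:
    """PR2 coordinates from a gene's synonymous third-position counts."""
    return Pr2Point(
        gene_id=profile.gene_id,
        x=_ratio(profile.A3, profile.A3 + profile.T3),
        y=_ratio(profile.G3, profile.G3 + profile.C3),
    )


def fourfold_third_position_counts(
    counts: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> dict[str, int]:
    """Third-position base counts restricted to 4-fold degenerate families.

    The parity-rule literature's stricter convention: only codons whose
    amino acid is encoded by a full NNx quartet contribute.
    """
    out = {b: 0 for b in "ACGT"}
    for aa in code.degeneracy_classes.get(4, ()):
        for codon in code.families[aa]:
            out[codon[2]] += counts.counts.get(codon, 0)
    return out


def pr2_point_from_counts(gene_id: str, third: dict[str, int]) -> Pr2Point:
    """PR2 coordinates from explicit third-position base counts."""
    return Pr2Point(
        gene_id=gene_id,
        x=_ratio(third["A"], third["A"] + third["T"]),
        y=_ratio(third["G"], third["G"] + third["C"]),
    )


def pr2_summary(points: Sequence[Pr2Point]) -> dict:
    """Mean coordinates over defined points and quadrant counts around (0.5, 0.5).

    Quadrants are counted over fully defined points lying strictly off the
    center lines; their counts therefore sum to at most the number of
    defined points.
    """
    xs = [p.x for p in points if p.x is not None]
    ys = [p.y for p in points if p.y is not None]
    if not xs and not ys:
        raise ValueError("all PR2 points undefined")
    quads = {"Q1": 0, "Q2": 0, "Q3": 0, "Q4": 0}
    for p in points:
        if not p.defined or p.x == 0.5 or p.y == 0.5:
            continue
        if p.x > 0.5:
            quads["Q1" if p.y > 0.5 else "Q4"] += 1
        else:
            quads["Q2" if p.y > 0.5 else "Q3"] += 1
    return {
        "mean_x": float(np.mean(xs)) if xs else float("nan"),
        "mean_y": float(np.mean(ys)) if ys else float("nan"),
        "n_defined_x": len(xs),
        "n_defined_y": len(ys),
        "quadrants": quads,
    }
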