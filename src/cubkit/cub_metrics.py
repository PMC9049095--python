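"""Gene-level codon usage bias statistics.

Implements the effective number of codons (ENc) from family homozygosities,
relative synonymous codon usage (RSCU) with over/under-representation
classes, the codon adaptation index (CAI) from relative-adaptiveness
weights, plus GRAVY, aromaticity and pooled amino-acid usage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import CodonCountTable, pool_counts
from .sequence_io import GeneticCode, STANDARD_CODE

__all__ = [
    "EncValue",
    "RscuVector",
    "CaiWeights",
    "ExpressionMetrics",
    "enc",
    "rscu",
    "pooled_rscu",
    "cai",
    "derive_weights",
    "gravy",
    "aromaticity",
    "amino_acid_usage",
    "KYTE_DOOLITTLE",
]

RSCU_OVER = 1.6
RSCU_UNDER = 0.6

ENC_MIN = 20.0
ENC_MAX = 61.0

#: Kyte–Doolittle hydropathy values per residue.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_AROMATIC = frozenset("FYW")


@dataclass(frozen=True)
class EncValue:
    """ENc with the per-degeneracy-class mean homozygosities behind it."""

    enc: float
    family_homozygosities: dict[int, float]
    n_missing_classes: int = 0


def _family_homozygosity(ns: Sequence[int], estimator: str) -> float | None:
    """Homozygosity F of one synonymous family, or None if ineligible."""
    n = sum(ns)
    if estimator == "corrected":
        if n < 2:
            return None
        sum_p2 = sum((x / n) ** 2 for x in ns)
        f = (n * sum_p2 - 1) / (n - 1)
        if f <= 0:  # unusable for 1/F; treated as a missing family
            return None
        return f
    if estimator == "plugin":
        if n < 1:
            return None
        return sum((x / n) ** 2 for x in ns)
    raise ValueError(f"unknown ENc estimator {estimator!r}")


def enc(
    counts: CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    estimator: str = "corrected",
    missing_class_policy: str = "deviation",
) -> EncValue:
    """Effective number of codons from mean family homozygosities.

    Per degenerate family, homozygosity F is estimated from the codon
    fractions p_i (``corrected``: F = (n Σp² − 1)/(n − 1); ``plugin``:
    F = Σp²).  Class means F̄_k over the families of each degeneracy class
    combine as ``2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6``, and the result is capped
    into [20, 61].

    A degeneracy class with no eligible family is imputed: under
    ``"deviation"`` (default) its F̄_k is 1/k shifted by the mean deviation
    of the observed classes from their own 1/k; under ``"theoretical"`` it
    is exactly 1/k.  Both are deterministic.
    """
    class_f: dict[int, float] = {}
    n_missing = 0
    classes = code.degeneracy_classes
    for k, aas in classes.items():
        fs = []
        for aa in aas:
            ns = [counts.counts.get(c, 0) for c in code.families[aa]]
            f = _family_homozygosity(ns, estimator)
            if f is not None:
                fs.append(f)
        if fs:
            class_f[k] = float(np.mean(fs))

    if not class_f:
        raise ValueError(f"sequence too short for ENc: {counts.gene_id!r}")

    if missing_class_policy not in ("deviation", "theoretical"):
        raise ValueError(f"unknown missing-class policy {missing_class_policy!r}")
    mean_dev = float(np.mean([f - 1 / k for k, f in class_f.items()]))
    for k in classes:
        if k not in class_f:
            n_missing += 1
            imputed = 1 / k + (mean_dev if missing_class_policy == "deviation" else 0.0)
            class_f[k] = min(max(imputed, 1e-6), 1.0)

    value = 2.0
    for k, aas in classes.items():
        value += len(aas) / class_f[k]
    value = min(max(value, ENC_MIN), ENC_MAX)
    return EncValue(enc=value, family_homozygosities=dict(sorted(class_f.items())),
                    n_missing_classes=n_missing)


@dataclass(frozen=True)
class RscuVector:
    """Per-codon RSCU values and over/under/typical classes.

    ``values`` maps each degenerate sense codon to k·n_i/Σn (NaN when the
    family is unused); Met/Trp are carried with RSCU fixed at 1 when
    ``include_nondegenerate`` was requested but are never classified.
    """

    values: dict[str, float]
    classes: dict[str, str]

    def n_over(self) -> int:
        return sum(c == "over" for c in self.classes.values())

    def n_under(self) -> int:
        return sum(c == "under" for c in self.classes.values())

    def n_above_one(self) -> int:
        return sum(v > 1 for v in self.values.values() if not math.isnan(v))


def rscu(
    counts: CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    include_nondegenerate: bool = False,
) -> RscuVector:
    """RSCU per codon: observed count over the equal-usage expectation.

    Within a family of size k, RSCU_i = k·n_i / Σ n; values of a family sum
    to k whenever the family is used at all.  Codons with RSCU > 1.6 are
    classed ``over``, < 0.6 ``under``, otherwise ``typical``; unused
    families yield NaN and no class.
    """
    if counts.total_sense == 0:
        raise ValueError(f"no sense codons for {counts.gene_id!r}")
    values: dict[str, float] = {}
    classes: dict[str, str] = {}
    for aa, codons in code.degenerate_families.items():
        k = len(codons)
        total = sum(counts.counts.get(c, 0) for c in codons)
        for c in codons:
            if total == 0:
                values[c] = float("nan")
                continue
            v = k * counts.counts.get(c, 0) / total
            values[c] = v
            if v > RSCU_OVER:
                classes[c] = "over"
            elif v < RSCU_UNDER:
                classes[c] = "under"
            else:
                classes[c] = "typical"
    if include_nondegenerate:
        for aa, codons in code.families.items():
            if len(codons) == 1:
                values[codons[0]] = 1.0
    return RscuVector(values=values, classes=classes)


def pooled_rscu(
    tables: Sequence[CodonCountTable],
    code: GeneticCode = STANDARD_CODE,
) -> RscuVector:
    """RSCU over the codon counts summed across all genes."""
    if not tables:
        raise ValueError("no genes to pool")
    return rscu(pool_counts(tables), code)


@dataclass(frozen=True)
class CaiWeights:
    """Relative adaptiveness w per degenerate sense codon, each in (0, 1].

    Weights are renormalised per family on construction so that every family
    contains at least one codon with w = 1.
    """

    w: dict[str, float]

    @classmethod
    def from_mapping(
        cls, w: Mapping[str, float], code: GeneticCode = STANDARD_CODE
    ) -> "CaiWeights":
        out: dict[str, float] = {}
        for aa, codons in code.degenerate_families.items():
            fam = {c: w[c] for c in codons if c in w}
            if len(fam) != len(codons):
                missing = sorted(set(codons) - set(fam))
                raise ValueError(f"missing CAI weights for {aa} codons {missing}")
            if any(v <= 0 for v in fam.values()):
                raise ValueError(f"non-positive CAI weight in family {aa}")
            m = max(fam.values())
            out.update({c: v / m for c, v in fam.items()})
        return cls(w=out)


def derive_weights(
    reference: CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    floor: float = 0.01,
) -> CaiWeights:
    """Relative adaptiveness from a reference count table: w_i = n_i / max_family n.

    Zero-count codons receive the small ``floor`` weight with a warning; a
    family entirely absent from the reference is an error.
    """
    w: dict[str, float] = {}
    floored: list[str] = []
    for aa, codons in code.degenerate_families.items():
        ns = {c: reference.counts.get(c, 0) for c in codons}
        m = max(ns.values())
        if m == 0:
            raise ValueError(f"reference has zero counts for family {aa}")
        for c, n in ns.items():
            if n == 0:
                w[c] = floor
                floored.append(c)
            else:
                w[c] = n / m
    if floored:
        warnings.warn(
            f"{len(floored)} zero-count reference codons floored at {floor}: "
            + ",".join(sorted(floored))
        )
    return CaiWeights(w=w)


def cai(counts: CodonCountTable, weights: CaiWeights) -> float:
    """Codon adaptation index: geometric mean of w over counted degenerate codons.

    Codons of single-codon families (Met, Trp) are excluded, as are codons
    without a defined weight (none exist for a complete weight table).
    """
    log_sum = 0.0
    n = 0
    for codon, cnt in counts.counts.items():
        wv = weights.w.get(codon)
        if wv is None:
            continue
        if wv <= 0:
            raise ValueError(f"non-positive CAI weight for {codon}")
        log_sum += cnt * math.log(wv)
        n += cnt
    if n == 0:
        raise ValueError(f"no weighted codons in {counts.gene_id!r}")
    return math.exp(log_sum / n)


@dataclass(frozen=True)
class ExpressionMetrics:
    cai: float
    gravy: float
    aromaticity: float

    @property
    def hydropathy_class(self) -> str:
        return "hydrophobic" if self.gravy > 0 else "hydrophilic"


def gravy(protein: str) -> float:
    """Mean Kyte–Doolittle hydropathy over the residues of a protein."""
    if not protein:
        raise ValueError("empty protein")
    try:
        return sum(KYTE_DOOLITTLE[a] for a in protein) / len(protein)
    except KeyError as e:
        raise ValueError(f"unknown residue {e.args[0]!r}") from None


def aromaticity(protein: str) -> float:
    """Fraction of aromatic residues (F, Y, W)."""
    if not protein:
        raise ValueError("empty protein")
    return sum(a in _AROMATIC for a in protein) / len(protein)


def amino_acid_usage(
    tables: Sequence[CodonCountTable],
    code: GeneticCode = STANDARD_CODE,
) -> pd.Series:
    """Pooled amino-acid frequencies over all genes, ranked descending.

    Frequencies sum to 1 over the 20 amino acids; stops are excluded.
    """
    if not tables:
        raise ValueError("no genes")
    pooled = pool_counts(tables)
    usage: dict[str, int] = {aa: 0 for aa in code.families}
    for codon, n in pooled.counts.items():
        usage[code.codon_to_aa[codon]] += n
    total = sum(usage.values())
    if total == 0:
        raise ValueError("no sense codons in pooled set")
    ser = pd.Series({aa: n / total for aa, n in usage.items()}, name="frequency")
    return ser.sort_values(ascending=False, kind="stable")
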