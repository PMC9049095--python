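"""Per-gene nucleotide composition, positional GC content and skews.

All composition statistics are derived from a :class:`CodonCountTable`, the
per-gene count of in-frame sense codons that also underlies every
codon-usage statistic in the package.  Positional GC at the third codon
position (``GC3`` / ``GC3s``) is computed over synonymous codons only
(Met/Trp excluded), matching the 59-codon convention used everywhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_io import CodingSequence, GeneticCode, STANDARD_CODE

__all__ = [
    "CodonCountTable",
    "CompositionProfile",
    "codon_counts",
    "composition_profile",
    "positional_comparisons",
    "correlation_matrix",
    "at_skew",
    "gc_skew",
    "profiles_to_frame",
]

COMPOSITION_COLUMNS = [
    "gene_id", "len_codons", "A", "C", "G", "T", "GC",
    "GC1", "GC2", "GC3", "GC12",
    "A3", "T3", "G3", "C3", "AT3", "GC3s", "at_skew", "gc_skew",
]


@dataclass(frozen=True)
class CodonCountTable:
    """Counts of in-frame sense codons for one gene (or a pooled set).

    The terminal stop codon is tallied separately in ``stop_counts`` and is
    excluded from all sense totals.  Codons containing ambiguous bases are
    skipped at counting time; their number is kept in ``n_skipped``.
    """

    gene_id: str
    counts: dict[str, int]
    stop_counts: dict[str, int] = field(default_factory=dict)
    n_skipped: int = 0

    @property
    def total_sense(self) -> int:
        return sum(self.counts.values())

    def family_counts(self, code: GeneticCode, aa: str) -> dict[str, int]:
        return {c: self.counts.get(c, 0) for c in code.families[aa]}

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        counts = dict(self.counts)
        for c, n in other.counts.items():
            counts[c] = counts.get(c, 0) + n
        stops = dict(self.stop_counts)
        for c, n in other.stop_counts.items():
            stops[c] = stops.get(c, 0) + n
        return CodonCountTable(
            gene_id=f"{self.gene_id}+{other.gene_id}",
            counts=counts,
            stop_counts=stops,
            n_skipped=self.n_skipped + other.n_skipped,
        )


def pool_counts(tables: Sequence[CodonCountTable], gene_id: str = "pooled") -> CodonCountTable:
    """Sum codon counts across genes into a single table."""
    if not tables:
        raise ValueError("no count tables to pool")
    counts: dict[str, int] = {}
    stops: dict[str, int] = {}
    skipped = 0
    for t in tables:
        for c, n in t.counts.items():
            counts[c] = counts.get(c, 0) + n
        for c, n in t.stop_counts.items():
            stops[c] = stops.get(c, 0) + n
        skipped += t.n_skipped
    return CodonCountTable(gene_id=gene_id, counts=counts, stop_counts=stops, n_skipped=skipped)


def codon_counts(seq: CodingSequence, code: GeneticCode = STANDARD_CODE) -> CodonCountTable:
    """Count in-frame codons of a CDS; terminal stop kept apart.

    Codons with ambiguous bases (N etc.) are skipped and tallied in
    ``n_skipped`` — the permissive-policy behaviour; under strict QC such
    genes never reach this point.
    """
    cods = seq.codons()
    stops: dict[str, int] = {}
    if cods and code.is_stop(cods[-1]):
        stops[cods[-1]] = 1
        cods = cods[:-1]
    counts: dict[str, int] = {}
    skipped = 0
    for c in cods:
        if c in code.codon_to_aa:
            counts[c] = counts.get(c, 0) + 1
        elif code.is_stop(c):
            # internal stop: counted apart so sense totals stay clean
            stops[c] = stops.get(c, 0) + 1
        else:
            skipped += 1
    return CodonCountTable(gene_id=seq.id, counts=counts, stop_counts=stops, n_skipped=skipped)


def at_skew(seq: str) -> float:
    """(A - T) / (A + T) over a nucleotide string."""
    a, t = seq.count("A"), seq.count("T")
    return (a - t) / (a + t) if a + t else 0.0


def gc_skew(seq: str) -> float:
    """(G - C) / (G + C) over a nucleotide string."""
    g, c = seq.count("G"), seq.count("C")
    return (g - c) / (g + c) if g + c else 0.0


@dataclass(frozen=True)
class CompositionProfile:
    """Composition summary of one gene.

    ``GC1``/``GC2`` are fractions over all sense codons; ``GC3`` (== ``GC3s``),
    the third-position base counts ``A3``..``C3`` and ``AT3`` are taken over
    synonymous (degenerate) codons only.  Skews are computed on the coding
    strand excluding the terminal stop.
    """

    gene_id: str
    len_codons: int
    A: float
    C: float
    G: float
    T: float
    GC: float
    GC1: float
    GC2: float
    GC3: float
    GC12: float
    A3: int
    T3: int
    G3: int
    C3: int
    AT3: float
    GC3s: float
    at_skew: float
    gc_skew: float

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in COMPOSITION_COLUMNS}


def composition_profile(
    counts: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> CompositionProfile:
    """Derive the per-gene composition profile from a codon count table."""
    if counts.total_sense == 0:
        raise ValueError(f"zero sense codons for {counts.gene_id!r}")

    base_totals = {b: 0 for b in "ACGT"}
    pos_gc = [0, 0]  # GC occurrences at codon positions 1 and 2
    n_sense = 0
    syn3 = {b: 0 for b in "ACGT"}
    degenerate = set(code.degenerate_codons)
    for codon, n in counts.counts.items():
        n_sense += n
        for b in codon:
            base_totals[b] += n
        for pos in (0, 1):
            if codon[pos] in "GC":
                pos_gc[pos] += n
        if codon in degenerate:
            syn3[codon[2]] += n

    n_bases = sum(base_totals.values())
    fr = {b: base_totals[b] / n_bases for b in "ACGT"}
    gc1 = pos_gc[0] / n_sense
    gc2 = pos_gc[1] / n_sense
    n_syn = sum(syn3.values())
    if n_syn:
        gc3s = (syn3["G"] + syn3["C"]) / n_syn
        at3 = (syn3["A"] + syn3["T"]) / n_syn
    else:
        gc3s = float("nan")
        at3 = float("nan")

    a, t = base_totals["A"], base_totals["T"]
    g, c = base_totals["G"], base_totals["C"]
    return CompositionProfile(
        gene_id=counts.gene_id,
        len_codons=n_sense,
        A=fr["A"], C=fr["C"], G=fr["G"], T=fr["T"],
        GC=fr["G"] + fr["C"],
        GC1=gc1, GC2=gc2, GC3=gc3s, GC12=(gc1 + gc2) / 2,
        A3=syn3["A"], T3=syn3["T"], G3=syn3["G"], C3=syn3["C"],
        AT3=at3, GC3s=gc3s,
        at_skew=(a - t) / (a + t) if a + t else 0.0,
        gc_skew=(g - c) / (g + c) if g + c else 0.0,
    )


def profiles_to_frame(profiles: Iterable[CompositionProfile]) -> pd.DataFrame:
    """Stack composition profiles into a DataFrame with the canonical columns."""
    df = pd.DataFrame([p.to_row() for p in profiles])
    return df[COMPOSITION_COLUMNS]


def positional_comparisons(profiles: Sequence[CompositionProfile]) -> dict:
    """Fractions of genes with G3>A3 / G3=A3 / A3>G3 and GC3s vs AT3 likewise.

    Comparisons use the integer third-position counts, so the equality bins
    are exact.  Each triple sums to 1.
    """
    if not profiles:
        raise ValueError("empty profile collection")
    n = len(profiles)
    g_gt = sum(p.G3 > p.A3 for p in profiles)
    g_eq = sum(p.G3 == p.A3 for p in profiles)
    gc_cnt = [(p.G3 + p.C3, p.A3 + p.T3) for p in profiles]
    gc_gt = sum(gc > at for gc, at in gc_cnt)
    gc_eq = sum(gc == at for gc, at in gc_cnt)
    return {
        "G3_vs_A3": (g_gt / n, g_eq / n, (n - g_gt - g_eq) / n),
        "GC3s_vs_AT3": (gc_gt / n, gc_eq / n, (n - gc_gt - gc_eq) / n),
        "n_genes": n,
    }


def correlation_matrix(
    table: pd.DataFrame,
    columns: Sequence[str] | None = None,
    method: str = "pearson",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlation coefficients and two-sided p-values.

    Parameters
    ----------
    table:
        Per-gene metrics (one row per gene).
    columns:
        Numeric columns to correlate; defaults to every numeric column.
    method:
        ``"pearson"`` (default) or ``"spearman"``.

    Returns ``(r, p)`` as symmetric DataFrames with unit diagonal.  Constant
    columns yield NaN entries with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    sub = table[list(columns)].astype(float)
    if len(sub) < 3:
        raise ValueError("need at least 3 genes for correlations")
    k = len(columns)
    r = np.eye(k)
    p = np.zeros((k, k))
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i in range(k):
        for j in range(i + 1, k):
            x, y = sub.iloc[:, i].values, sub.iloc[:, j].values
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"constant column in pair ({columns[i]}, {columns[j]}); "
                    "correlation undefined"
                )
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = corr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = list(columns)
    return pd.DataFrame(r, index=idx, columns=idx), pd.DataFrame(p, index=idx, columns=idx)
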