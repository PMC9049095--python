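"""Synthetic coding-sequence sets with controlled compositional structure.

Three generative regimes cover the pipeline's needs:

* ``mutation_only`` — every codon position draws from one GC-parameterized
  nucleotide pool per gene, so GC12 and GC3 share a single driver (the
  neutrality-plot null of pure mutation pressure).
* ``selection`` — the amino-acid sequence has a fixed composition while the
  synonymous third-position GC level varies per gene, decoupling GC3 from
  GC12.
* ``pair_bias`` — a first-order codon chain enriching configured adjacent
  codon pairs, a positive control for the context classifier.

All randomness flows from one integer seed; per-gene substreams are derived
deterministically from (seed, gene index), so identical specs produce
byte-identical FASTA output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_io import CodingSequence, GeneticCode, STANDARD_CODE

__all__ = [
    "RegimeSpec",
    "GeneSet",
    "generate",
    "generate_mutation_regime",
    "generate_selection_regime",
    "generate_pair_biased",
    "ec_like_spec",
    "write_fasta",
    "write_truth",
]

_BASE_ORDER = "ACGT"


@dataclass(frozen=True)
class RegimeSpec:
    """Parameters of one synthetic gene set."""

    n_genes: int = 82
    length_range: tuple[int, int] = (300, 3000)  # sense codons incl. start
    regime: str = "mutation_only"  # mutation_only | selection | mixed | pair_bias
    gc_range: tuple[float, float] = (0.35, 0.69)
    gc3_range: tuple[float, float] = (0.30, 0.90)
    bias_concentration: float = 200.0
    pair_bias: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.bias_concentration <= 0:
            raise ValueError("bias_concentration must be > 0")
        for name, rng in (("gc_range", self.gc_range), ("gc3_range", self.gc3_range)):
            lo, hi = rng
            if not (0 < lo <= hi < 1):
                raise ValueError(f"{name} must lie strictly inside (0, 1)")
        lo, hi = self.length_range
        if not (2 <= lo <= hi):
            raise ValueError("length_range must satisfy 2 <= lo <= hi")
        for (a, b), m in self.pair_bias.items():
            if m <= 0:
                raise ValueError(f"enrichment for pair ({a},{b}) must be > 0")


@dataclass(frozen=True)
class GeneSet:
    """Generated genes plus the ground-truth table behind them."""

    genes: list[CodingSequence]
    truth: pd.DataFrame  # gene_id, regime, gc_target, gc3_target, length


def _gene_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _codon_lookup(code: GeneticCode) -> tuple[np.ndarray, np.ndarray]:
    """All 64 codons as strings and a boolean stop mask, base-4 indexed."""
    codons = np.array(
        ["".join((_BASE_ORDER[a], _BASE_ORDER[b], _BASE_ORDER[c]))
         for a in range(4) for b in range(4) for c in range(4)]
    )
    stops = np.array([c in code.stop_codons for c in codons])
    return codons, stops


def _draw_pool_codons(
    rng: np.random.Generator, n: int, p: np.ndarray, code: GeneticCode
) -> list[str]:
    """Draw n codons with iid per-position bases, rejecting stop codons."""
    codons, stops = _codon_lookup(code)
    out: list[str] = []
    while len(out) < n:
        need = n - len(out)
        draws = rng.choice(4, size=(int(need * 1.2) + 8, 3), p=p)
        idx = draws[:, 0] * 16 + draws[:, 1] * 4 + draws[:, 2]
        ok = codons[idx[~stops[idx]]]
        out.extend(ok[:need].tolist())
    return out


def _pool_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _draw_stop(rng: np.random.Generator, p: np.ndarray, code: GeneticCode) -> str:
    stops = sorted(code.stop_codons)
    w = np.array([np.prod([p[_BASE_ORDER.index(b)] for b in s]) for s in stops])
    if w.sum() == 0:
        w = np.ones(len(stops))
    return stops[rng.choice(len(stops), p=w / w.sum())]


def _finish_gene(gene_id, body, stop):
    return CodingSequence(id=gene_id, sequence="ATG" + "".join(body) + stop)


def _pool_gc_for_target(target: float) -> float:
    """Pool GC parameter whose post-stop-rejection expected GC hits target.

    Rejecting stop codons (AT-rich: TAA/TAG/TGA) enriches the surviving
    codons in GC, so the raw pool parameter must be solved for numerically.
    """
    from scipy.optimize import brentq

    def conditional_gc(g):
        a, c = (1 - g) / 2, g / 2
        p_stop = a**3 + 2 * a**2 * c
        return (3 * g - 2 * a**2 * c) / (3 * (1 - p_stop))

    lo, hi = 1e-4, 1 - 1e-4
    if target <= conditional_gc(lo):
        return lo
    if target >= conditional_gc(hi):
        return hi
    return float(brentq(lambda g: conditional_gc(g) - target, lo, hi,
                        xtol=1e-12))


def _mutation_gene(rng, spec: RegimeSpec, gene_id: str, code: GeneticCode):
    gc = rng.uniform(*spec.gc_range)
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    p = _pool_probs(_pool_gc_for_target(gc))
    body = _draw_pool_codons(rng, length - 1, p, code)
    gene = _finish_gene(gene_id, body, _draw_stop(rng, p, code))
    return gene, {"gene_id": gene_id, "regime": "mutation_only",
                  "gc_target": gc, "gc3_target": gc, "length": length}


#: Fixed amino-acid sampling weights for the selection regime (Met is
#: supplied by the start codon; Trp is non-degenerate and carries no
#: synonymous signal).  The purine-ending two-fold families (K, Q, E) are
#: up-weighted and Ile down-weighted so that at a third-position GC level of
#: 0.5 the aggregate synonymous third positions satisfy A3 = T3 exactly and
#: G3 ~ C3 — the genetic code alone would otherwise skew the PR2 center.
_AA_WEIGHTS = {"K": 17 / 9, "Q": 17 / 9, "E": 17 / 9, "I": 0.5}


def _selection_aa_probs(code: GeneticCode) -> tuple[list[str], np.ndarray]:
    aas = sorted(code.degenerate_families)
    w = np.array([_AA_WEIGHTS.get(aa, 1.0) for aa in aas])
    return aas, w / w.sum()


def _family_base_weights(codons: Sequence[str], gc3: float) -> np.ndarray:
    """Within-family codon weights from a third-position base pool.

    Bases G and C each carry probability gc3/2, A and T each (1-gc3)/2,
    renormalised over the endings the family actually offers.
    """
    q = {"A": (1 - gc3) / 2, "T": (1 - gc3) / 2,
         "G": gc3 / 2, "C": gc3 / 2}
    w = np.array([q[c[2]] for c in codons])
    return w / w.sum()


def _selection_gene(rng, spec: RegimeSpec, gene_id: str, code: GeneticCode):
    gc3 = rng.uniform(*spec.gc3_range)
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    aas, aa_p = _selection_aa_probs(code)
    aa_draws = rng.choice(len(aas), size=length - 1, p=aa_p)
    # per-gene codon distribution per family: Dirichlet around the
    # GC3-targeting base weights; lower concentration = stronger skew
    fam_probs: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for aa in aas:
        codons = code.families[aa]
        base = _family_base_weights(codons, gc3)
        alpha = spec.bias_concentration * len(codons) * np.clip(base, 1e-3, None)
        fam_probs[aa] = (codons, rng.dirichlet(alpha))
    body = []
    for ai in aa_draws:
        codons, probs = fam_probs[aas[ai]]
        body.append(codons[rng.choice(len(codons), p=probs)])
    gene = _finish_gene(gene_id, body, _draw_stop(rng, _pool_probs(0.5), code))
    return gene, {"gene_id": gene_id, "regime": "selection",
                  "gc_target": float("nan"), "gc3_target": gc3, "length": length}


def _pair_gene(rng, spec: RegimeSpec, gene_id: str, code: GeneticCode):
    gc = rng.uniform(*spec.gc_range)
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    p = _pool_probs(gc)
    sense = sorted(code.sense_codons)
    pi = np.array([np.prod([p[_BASE_ORDER.index(b)] for b in c]) for c in sense])
    pi /= pi.sum()
    index = {c: i for i, c in enumerate(sense)}
    rows_with_bias = {a for (a, _b) in spec.pair_bias}
    trans: dict[str, np.ndarray] = {}
    for a in rows_with_bias:
        row = pi.copy()
        for (x, b), mult in spec.pair_bias.items():
            if x == a:
                row[index[b]] *= mult
        trans[a] = row / row.sum()
    body = ["ATG"]
    for _ in range(length - 1):
        prev = body[-1]
        dist = trans.get(prev, pi)
        body.append(sense[rng.choice(len(sense), p=dist)])
    gene = _finish_gene(gene_id, body[1:], _draw_stop(rng, p, code))
    return gene, {"gene_id": gene_id, "regime": "pair_bias",
                  "gc_target": gc, "gc3_target": gc, "length": length}


_GENERATORS = {
    "mutation_only": _mutation_gene,
    "selection": _selection_gene,
    "pair_bias": _pair_gene,
}


def generate(spec: RegimeSpec, code: GeneticCode = STANDARD_CODE) -> GeneSet:
    """Generate a gene set under the spec's regime (dispatching per gene).

    Under ``mixed``, even-indexed genes follow the mutation regime and
    odd-indexed genes the selection regime.
    """
    genes: list[CodingSequence] = []
    rows = []
    for i in range(spec.n_genes):
        if spec.regime == "mixed":
            kind = "mutation_only" if i % 2 == 0 else "selection"
        elif spec.regime in _GENERATORS:
            kind = spec.regime
        else:
            raise ValueError(f"unknown regime {spec.regime!r}")
        if kind == "pair_bias" and not spec.pair_bias:
            raise ValueError("pair_bias regime requires a non-empty pair_bias map")
        rng = _gene_rng(spec.seed, i)
        gene, truth = _GENERATORS[kind](rng, spec, f"gene{i:04d}", code)
        genes.append(gene)
        rows.append(truth)
    return GeneSet(genes=genes, truth=pd.DataFrame(rows))


def generate_mutation_regime(spec: RegimeSpec, code: GeneticCode = STANDARD_CODE) -> GeneSet:
    if spec.regime != "mutation_only":
        raise ValueError("spec.regime must be 'mutation_only'")
    return generate(spec, code)


def generate_selection_regime(spec: RegimeSpec, code: GeneticCode = STANDARD_CODE) -> GeneSet:
    if spec.regime != "selection":
        raise ValueError("spec.regime must be 'selection'")
    return generate(spec, code)


def generate_pair_biased(spec: RegimeSpec, code: GeneticCode = STANDARD_CODE) -> GeneSet:
    if spec.regime != "pair_bias":
        raise ValueError("spec.regime must be 'pair_bias'")
    if not spec.pair_bias:
        raise ValueError("pair_bias map is empty")
    return generate(spec, code)


def ec_like_spec(seed: int = 0) -> RegimeSpec:
    """The default emulation preset: 82 GC-rich genes, mixed regime.

    Mirrors a GC-rich human disease gene set: overall GC around 0.52,
    gene-level GC3 spanning roughly 0.3–0.9, lengths 300–3000 codons.
    """
    return RegimeSpec(
        n_genes=82,
        length_range=(300, 3000),
        regime="mixed",
        gc_range=(0.35, 0.69),
        gc3_range=(0.30, 0.90),
        seed=seed,
    )


def write_fasta(genes: Sequence[CodingSequence], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


def write_truth(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False)
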