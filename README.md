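# cubkit

A codon-usage-bias (CUB) analysis toolkit for sets of coding sequences
(CDS). Given a multi-FASTA of CDS, cubkit validates the sequences and
computes:

- **Composition** — per-gene base fractions, positional GC (GC1, GC2,
  GC3/GC3s over synonymous positions, GC12), third-position base counts,
  AT/GC skews, positional comparisons and a correlation matrix.
- **Bias metrics** — effective number of codons (ENc, corrected or plugin
  family-homozygosity estimators, capped into [20, 61]), RSCU with
  over (>1.6) / under (<0.6) representation classes, CAI from relative
  adaptiveness weights (self-derived from the lowest-ENc decile or a
  user-supplied table), GRAVY, aromaticity and amino-acid usage.
- **Evolutionary-force diagnostics** — neutrality plot regression (GC12 on
  GC3) and PR2 bias coordinates A3/(A3+T3) vs G3/(G3+C3), with a 4-fold
  degenerate convention available.
- **Multivariate structure** — correspondence analysis of the gene × 59
  codon RSCU matrix (chi-square metric, principal coordinates, per-axis
  inertia) and a neighbor-joining tree of Euclidean RSCU distances in
  newick format.
- **Codon-pair context** — pooled 61×61 adjacent sense-codon pair counts,
  independence expectations, adjusted standardized residuals and
  over/under/absent/typical classification.
- **Synthetic data** — a seeded CDS generator with mutation-pressure,
  selection, mixed and pair-enriched regimes plus ground-truth tables, so
  the entire pipeline is testable offline.

## Command line

```sh
# generate an 82-gene GC-rich demo set
cubkit simulate --preset ec-like --seed 1 -o demo/

# run every stage: QC, composition, metrics, RSCU, correlations,
# neutrality, PR2, COA, NJ tree, codon-pair context + manifest
cubkit run-all -i demo/synthetic.fasta -o demo/out

# one-page report recomputed from the bundle
cubkit summarize -o demo/out
```

Individual stages are available as subcommands (`qc`, `compose`, `metrics`,
`rscu`, `neutrality`, `pr2`, `coa`, `cluster`, `context`). Common flags:
`--strict/--permissive` QC policy, `--min-codons`, `--seed`. All tables are
TSV; the tree is newick; the run manifest is JSON with input digests.
Reruns with identical inputs and config are byte-identical.

## Python API

```python
from cubkit.sequence_io import read_fasta, apply_qc
from cubkit.composition import codon_counts, composition_profile
from cubkit.cub_metrics import enc, rscu

genes, failed = apply_qc(read_fasta("genes.fasta"))
counts = [codon_counts(g) for g in genes]
print(enc(counts[0]).enc, rscu(counts[0]).n_over())
```

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` checks the analytic limits (ENc = 20 at extreme
bias, ENc = 61 at uniform usage, RSCU = 1 at equal usage, PR2 center at
(0.5, 0.5)), equivalence against independent brute-force oracles for ENc,
RSCU, CAI, COA, NJ and pair residuals, parameter recovery of the synthetic
regimes, and classifier power/null behaviour.

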