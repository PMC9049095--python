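"""End-to-end orchestration: run every analysis stage and write the table set.

:func:`run_all` takes a :class:`RunConfig`, reads the input FASTA file(s),
applies QC, and emits — in dependency order — the QC table, composition
table, per-gene metrics, pooled RSCU, correlation matrices, neutrality fit,
PR2 table, correspondence-analysis outputs, the NJ tree and the codon-pair
context tables, plus a machine-readable run manifest.  Outputs are pure
functions of (inputs, config); no timestamps are written, so reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import __version__
from . import codon_context, composition, cub_metrics, evolutionary_forces, multivariate
from .sequence_io import STANDARD_CODE, apply_qc, read_fasta, write_qc_table

__all__ = ["RunConfig", "run_all", "summarize", "STAGE_FILES"]

STAGE_FILES = {
    "qc": "qc.tsv",
    "composition": "composition.tsv",
    "metrics": "metrics.tsv",
    "rscu": "rscu_pooled.tsv",
    "correlation": "correlation_r.tsv",
    "neutrality": "neutrality.tsv",
    "pr2": "pr2.tsv",
    "coa": "coa_inertia.tsv",
    "cluster": "tree.nwk",
    "context": "pair_summary.tsv",
}

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a pipeline run; serializes losslessly to/from JSON."""

    inputs: tuple[str, ...]
    outdir: str
    strict: bool = True
    min_codons: int = 30
    alternative_starts: tuple[str, ...] = ()
    correlation_method: str = "pearson"  # pearson | spearman
    enc_estimator: str = "corrected"  # corrected | plugin
    cai_weights: str = "self"  # "self" or path to a codon\tw TSV
    pr2_convention: str = "synonymous"  # synonymous | fourfold
    coa_axes: int | None = None
    pair_residual_threshold: float = 3.0
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError(f"bad correlation_method {self.correlation_method!r}")
        if self.enc_estimator not in ("corrected", "plugin"):
            raise ValueError(f"bad enc_estimator {self.enc_estimator!r}")
        if self.pr2_convention not in ("synonymous", "fourfold"):
            raise ValueError(f"bad pr2_convention {self.pr2_convention!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["inputs"] = tuple(d["inputs"])
        d["alternative_starts"] = tuple(d.get("alternative_starts", ()))
        return cls(**d)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _load_weights(path: str, code) -> cub_metrics.CaiWeights:
    tab = pd.read_csv(path, sep="\t")
    return cub_metrics.CaiWeights.from_mapping(
        dict(zip(tab["codon"], tab["w"])), code
    )


def _self_weights(count_tables, enc_values, code) -> cub_metrics.CaiWeights:
    """Reference weights from the pooled 10% lowest-ENc genes of the input."""
    order = np.argsort([e.enc for e in enc_values], kind="stable")
    k = max(1, math.ceil(len(order) * 0.10))
    pooled = composition.pool_counts([count_tables[i] for i in order[:k]],
                                     gene_id="low_enc_reference")
    return cub_metrics.derive_weights(pooled, code)


CORRELATION_COLUMNS = ["GC", "GC1", "GC2", "GC3", "GC12", "AT3", "GC3s",
                       "at_skew", "gc_skew", "enc", "cai", "gravy", "aromaticity"]


def run_all(config: RunConfig) -> dict[str, str]:
    """Run the full analysis; returns a mapping of stage name to output path."""
    code = STANDARD_CODE
    if config.alternative_starts:
        code = code.with_start_codons(("ATG",) + tuple(config.alternative_starts))
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)
    paths: dict[str, str] = {}
    stage_rows: dict[str, int] = {}

    def _stage(name):
        if config.verbosity:
            print(f"[cubkit] stage: {name}")

    # ---- QC ----------------------------------------------------------------
    _stage("qc")
    seqs = []
    for p in config.inputs:
        seqs.extend(read_fasta(p))
    passed, failed = apply_qc(seqs, code, config.min_codons, strict=config.strict)
    write_qc_table(passed + failed, out("qc.tsv"))
    paths["qc"] = out("qc.tsv")
    stage_rows["qc"] = len(seqs)
    if not passed:
        raise RuntimeError("stage qc: no sequences passed QC")

    # ---- composition -------------------------------------------------------
    _stage("composition")
    count_tables = [composition.codon_counts(s, code) for s in passed]
    profiles = [composition.composition_profile(t, code) for t in count_tables]
    comp_df = composition.profiles_to_frame(profiles)
    _write(comp_df, out("composition.tsv"))
    paths["composition"] = out("composition.tsv")
    stage_rows["composition"] = len(comp_df)

    # ---- per-gene metrics --------------------------------------------------
    _stage("metrics")
    enc_values = [cub_metrics.enc(t, code, estimator=config.enc_estimator)
                  for t in count_tables]
    if config.cai_weights == "self":
        weights = _self_weights(count_tables, enc_values, code)
    else:
        weights = _load_weights(config.cai_weights, code)
    rows = []
    from .sequence_io import translate
    for s, t, e in zip(passed, count_tables, enc_values):
        protein = translate(s, code)
        g = cub_metrics.gravy(protein)
        rows.append({
            "gene_id": s.id,
            "enc": e.enc,
            "cai": cub_metrics.cai(t, weights),
            "gravy": g,
            "aromaticity": cub_metrics.aromaticity(protein),
            "hydropathy_class": "hydrophobic" if g > 0 else "hydrophilic",
        })
    metrics_df = pd.DataFrame(rows)
    _write(metrics_df, out("metrics.tsv"))
    wtab = pd.DataFrame(sorted(weights.w.items()), columns=["codon", "w"])
    _write(wtab, out("cai_weights.tsv"))
    paths["metrics"] = out("metrics.tsv")
    stage_rows["metrics"] = len(metrics_df)

    # ---- pooled RSCU -------------------------------------------------------
    _stage("rscu")
    pooled = cub_metrics.pooled_rscu(count_tables, code)
    rscu_rows = []
    for codon in sorted(pooled.values):
        rscu_rows.append({
            "codon": codon,
            "amino_acid": code.codon_to_aa[codon],
            "count": sum(t.counts.get(codon, 0) for t in count_tables),
            "rscu": pooled.values[codon],
            "class": pooled.classes.get(codon, ""),
        })
    rscu_df = pd.DataFrame(rscu_rows)
    _write(rscu_df, out("rscu_pooled.tsv"))
    paths["rscu"] = out("rscu_pooled.tsv")
    stage_rows["rscu"] = len(rscu_df)

    # ---- correlations ------------------------------------------------------
    _stage("correlation")
    merged = comp_df.merge(metrics_df, on="gene_id")
    cols = [c for c in CORRELATION_COLUMNS if c in merged.columns]
    if len(merged) >= 3:
        r, p = composition.correlation_matrix(merged, cols, config.correlation_method)
    else:  # too few genes: complete bundle with all-NaN matrices
        nanm = pd.DataFrame(np.nan, index=cols, columns=cols)
        r, p = nanm, nanm.copy()
    _write(r, out("correlation_r.tsv"), index=True)
    _write(p, out("correlation_p.tsv"), index=True)
    # BH-adjusted p-values over the upper triangle, reported alongside raw p
    q = p.copy()
    iu = np.triu_indices(len(cols), k=1)
    raw = p.to_numpy()[iu]
    ok = np.isfinite(raw)
    adj = np.full_like(raw, np.nan)
    if ok.any():
        adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
    qm = q.to_numpy()
    qm[iu] = adj
    qm[(iu[1], iu[0])] = adj
    np.fill_diagonal(qm, 0.0)
    _write(pd.DataFrame(qm, index=cols, columns=cols), out("correlation_q.tsv"),
           index=True)
    paths["correlation"] = out("correlation_r.tsv")
    stage_rows["correlation"] = len(cols)

    # ---- neutrality --------------------------------------------------------
    _stage("neutrality")
    try:
        fit = evolutionary_forces.neutrality_fit(profiles)
        fit_row = dataclasses.asdict(fit)
    except ValueError:  # <3 genes or constant GC3: placeholder row
        fit_row = {"slope": np.nan, "intercept": np.nan, "r": np.nan,
                   "p": np.nan, "n": len(profiles)}
    _write(pd.DataFrame([fit_row]), out("neutrality.tsv"))
    paths["neutrality"] = out("neutrality.tsv")
    stage_rows["neutrality"] = int(fit_row["n"])

    # ---- PR2 ---------------------------------------------------------------
    _stage("pr2")
    if config.pr2_convention == "synonymous":
        points = [evolutionary_forces.pr2_point(p) for p in profiles]
    else:
        points = [
            evolutionary_forces.pr2_point_from_counts(
                t.gene_id, evolutionary_forces.fourfold_third_position_counts(t, code))
            for t in count_tables
        ]
    summ = evolutionary_forces.pr2_summary(points)
    pr2_rows = [{
        "gene_id": pt.gene_id,
        "x": "" if pt.x is None else pt.x,
        "y": "" if pt.y is None else pt.y,
        "x_defined": pt.x is not None,
        "y_defined": pt.y is not None,
    } for pt in points]
    pr2_rows.append({"gene_id": "__mean__", "x": summ["mean_x"], "y": summ["mean_y"],
                     "x_defined": True, "y_defined": True})
    _write(pd.DataFrame(pr2_rows), out("pr2.tsv"))
    paths["pr2"] = out("pr2.tsv")
    stage_rows["pr2"] = len(points)

    # ---- correspondence analysis ------------------------------------------
    _stage("coa")
    per_gene_rscu = {
        t.gene_id: cub_metrics.rscu(t, code).values for t in count_tables
    }
    rmat = multivariate.rscu_matrix(per_gene_rscu)
    try:
        coa_res = multivariate.coa(rmat, n_axes=config.coa_axes)
        _write(coa_res.gene_coords, out("coa_genes.tsv"), index=True)
        _write(coa_res.codon_coords, out("coa_codons.tsv"), index=True)
        inertia_df = pd.DataFrame({
            "axis": [f"axis{i + 1}" for i in range(len(coa_res.inertia))],
            "inertia": coa_res.inertia,
            "fraction": coa_res.inertia_fractions,
        })
        n_coa = len(coa_res.gene_coords)
    except ValueError:  # <2 genes: complete bundle with an empty inertia table
        inertia_df = pd.DataFrame(columns=["axis", "inertia", "fraction"])
        n_coa = 0
    _write(inertia_df, out("coa_inertia.tsv"))
    paths["coa"] = out("coa_inertia.tsv")
    stage_rows["coa"] = n_coa

    # ---- cluster tree ------------------------------------------------------
    _stage("cluster")
    if len(rmat) >= 3:
        dist = multivariate.rscu_distance_matrix(rmat)
        tree = multivariate.nj_tree(dist)
        with open(out("tree.nwk"), "w") as fh:
            fh.write(tree.newick + "\n")
        paths["cluster"] = out("tree.nwk")
        stage_rows["cluster"] = len(tree.leaves)
    else:
        stage_rows["cluster"] = 0

    # ---- codon-pair context ------------------------------------------------
    _stage("context")
    pm = codon_context.pair_counts(passed, code)
    pm = codon_context.expected_and_residuals(pm)
    pm, pair_summary = codon_context.classify_pairs(
        pm, residual_threshold=config.pair_residual_threshold)
    long = pm.observed.stack().rename("observed").to_frame()
    long["expected"] = pm.expected.stack()
    long["residual"] = pm.residual.stack()
    long["class"] = pm.classes.stack()
    long.index.names = ["codon1", "codon2"]
    _write(long.reset_index(), out("codon_pairs.tsv"))
    _write(pd.DataFrame([pair_summary]), out("pair_summary.tsv"))
    _write(codon_context.context_heatmap_matrix(pm), out("context_grid.tsv"),
           index=True)
    paths["context"] = out("pair_summary.tsv")
    stage_rows["context"] = pair_summary["total_pairs"]

    # ---- manifest ----------------------------------------------------------
    manifest = {
        "tool": "cubkit",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {p: _sha256(p) for p in config.inputs},
        "stage_rows": stage_rows,
    }
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = out("manifest.json")
    return paths


def summarize(outdir: str) -> str:
    """One-page text summary recomputed from the bundle's tables."""
    def _need(name: str) -> str:
        p = os.path.join(outdir, STAGE_FILES[name])
        if not os.path.exists(p):
            raise FileNotFoundError(f"incomplete bundle: missing stage {name!r} ({p})")
        return p

    comp = pd.read_csv(_need("composition"), sep="\t")
    metrics = pd.read_csv(_need("metrics"), sep="\t")
    rscu_df = pd.read_csv(_need("rscu"), sep="\t")
    fit = pd.read_csv(_need("neutrality"), sep="\t").iloc[0]
    pr2 = pd.read_csv(_need("pr2"), sep="\t")
    inertia = pd.read_csv(_need("coa"), sep="\t")
    pairs = pd.read_csv(_need("context"), sep="\t").iloc[0]

    n = len(metrics)
    enc_mean = metrics["enc"].mean()
    enc_sd = metrics["enc"].std(ddof=1) if n > 1 else float("nan")
    sd_txt = f"{enc_sd:.3f}" if n > 1 else "n/a"
    mean_row = pr2[pr2["gene_id"] == "__mean__"].iloc[0]
    ranked = rscu_df.dropna(subset=["rscu"]).sort_values(
        ["rscu", "codon"], ascending=[False, True])
    top = ", ".join(f"{r.codon}({r.rscu:.2f})" for r in ranked.head(3).itertuples())
    bottom = ", ".join(f"{r.codon}({r.rscu:.2f})" for r in ranked.tail(3).itertuples())
    ax = inertia["fraction"].tolist()
    ax1 = f"{100 * ax[0]:.1f}%" if len(ax) > 0 else "n/a"
    ax2 = f"{100 * ax[1]:.1f}%" if len(ax) > 1 else "n/a"

    lines = [
        "cubkit run summary",
        "==================",
        f"genes analysed          : {n}",
        f"mean GC                 : {100 * comp['GC'].mean():.2f}%",
        f"ENc mean +/- sd         : {enc_mean:.3f} +/- {sd_txt}",
        f"ENc range               : {metrics['enc'].min():.3f} .. {metrics['enc'].max():.3f}",
        f"top RSCU codons         : {top}",
        f"bottom RSCU codons      : {bottom}",
        f"neutrality slope        : {fit['slope']:.4f} (r={fit['r']:.3f}, p={fit['p']:.3g}, n={int(fit['n'])})",
        f"PR2 mean (x, y)         : ({mean_row['x']:.4f}, {mean_row['y']:.4f})",
        f"COA axis1/axis2 inertia : {ax1} / {ax2}",
        f"pair classes over/under/absent : "
        f"{100 * pairs['frac_over']:.2f}% / {100 * pairs['frac_under']:.2f}% / "
        f"{100 * pairs['frac_absent']:.2f}%",
    ]
    return "\n".join(lines) + "\n"
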