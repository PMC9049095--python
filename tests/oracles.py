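"""Independent brute-force implementations used as oracles in tests.

Everything here is written from the definitions alone, in plain loops,
without importing the package's computation code paths.
"""

from __future__ import annotations

import math

import numpy as np


def enc_oracle(counts: dict[str, int], code, estimator: str = "corrected",
               missing_policy: str = "deviation") -> float:
    """ENc from the per-family definition, coded with explicit loops."""
    per_class_fs: dict[int, list[float]] = {}
    sizes: dict[int, int] = {}
    for aa, codons in code.families.items():
        k = len(codons)
        if k == 1:
            continue
        sizes[k] = sizes.get(k, 0) + 1
        ns = [counts.get(c, 0) for c in codons]
        n = sum(ns)
        if estimator == "corrected":
            if n < 2:
                continue
            s = sum((x / n) ** 2 for x in ns)
            f = (n * s - 1) / (n - 1)
            if f <= 0:
                continue
        else:
            if n < 1:
                continue
            f = sum((x / n) ** 2 for x in ns)
        per_class_fs.setdefault(k, []).append(f)

    means = {k: sum(v) / len(v) for k, v in per_class_fs.items()}
    if not means:
        raise ValueError("no eligible family")
    dev = sum(f - 1 / k for k, f in means.items()) / len(means)
    total = 2.0
    for k, n_fam in sizes.items():
        if k in means:
            f = means[k]
        elif missing_policy == "deviation":
            f = min(max(1 / k + dev, 1e-6), 1.0)
        else:
            f = 1 / k
        total += n_fam / f
    return min(max(total, 20.0), 61.0)


def rscu_oracle(counts: dict[str, int], code) -> dict[str, float]:
    out = {}
    for aa, codons in code.families.items():
        if len(codons) == 1:
            continue
        tot = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            out[c] = len(codons) * counts.get(c, 0) / tot if tot else float("nan")
    return out


def cai_oracle(counts: dict[str, int], weights: dict[str, float], code) -> float:
    """Geometric mean of w over the expanded list of degenerate codons."""
    logs = []
    for aa, codons in code.families.items():
        if len(codons) == 1:
            continue
        for c in codons:
            logs.extend([math.log(weights[c])] * counts.get(c, 0))
    return math.exp(sum(logs) / len(logs))


def pearson_oracle(x, y) -> float:
    """Textbook Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def coa_oracle(X: np.ndarray):
    """Correspondence analysis via eigendecomposition (not SVD).

    Returns (row_coords, col_coords, principal_inertias), axes sorted by
    decreasing inertia; axis signs are arbitrary.
    """
    X = np.asarray(X, dtype=float)
    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    ev_r, U = np.linalg.eigh(S @ S.T)
    ev_c, V = np.linalg.eigh(S.T @ S)
    order_r = np.argsort(ev_r)[::-1]
    order_c = np.argsort(ev_c)[::-1]
    ev = np.sort(ev_c)[::-1]
    k = int((ev > 1e-12 * max(ev.max(), 1)).sum())
    k = min(k, min(X.shape) - 1) if min(X.shape) > 1 else k
    U = U[:, order_r[:k]]
    V = V[:, order_c[:k]]
    lam = ev[:k]
    # align left/right eigenvector signs so that S ~ U diag(sqrt(lam)) V^T
    for j in range(k):
        if U[:, j] @ S @ V[:, j] < 0:
            V[:, j] = -V[:, j]
    sv = np.sqrt(lam)
    F = U * sv / np.sqrt(r)[:, None]
    G = V * sv / np.sqrt(c)[:, None]
    return F, G, lam


def nj_oracle_patristic(labels, D: np.ndarray) -> dict[tuple[str, str], float]:
    """Neighbor joining returning leaf-to-leaf path lengths directly.

    Tracks, for every active node, its distance to each original leaf below
    it; no tree structure is ever built.  Uses the same published join and
    branch-length formulas and the sorted-label-pair tie-break plus the
    clamp-deficit-to-sibling rule of the contract.
    """
    labels = list(labels)
    D = np.asarray(D, dtype=float)
    dist = {a: {b: D[i, j] for j, b in enumerate(labels)}
            for i, a in enumerate(labels)}
    below: dict[str, dict[str, float]] = {a: {a: 0.0} for a in labels}
    active = list(labels)
    paths: dict[tuple[str, str], float] = {}
    cnt = 0
    while len(active) > 2:
        n = len(active)
        r = {a: sum(dist[a][b] for b in active if b != a) for a in active}
        best, bq = None, math.inf
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * dist[a][b] - r[a] - r[b]
                key = tuple(sorted((str(a), str(b))))
                if q < bq - 1e-12 or (abs(q - bq) <= 1e-12 and
                                      (best is None or key < best[1])):
                    bq, best = q, ((a, b), key)
        (a, b), _ = best
        dab = dist[a][b]
        la = dab / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        if la < 0:
            lb, la = lb + la, 0.0
        if lb < 0:
            la, lb = la + lb, 0.0
        for x, lx in below[a].items():
            for y, ly in below[b].items():
                paths[tuple(sorted((x, y)))] = lx + la + ly + lb
        cnt += 1
        u = f"u{cnt}"
        below[u] = {**{x: lx + la for x, lx in below[a].items()},
                    **{y: ly + lb for y, ly in below[b].items()}}
        dist[u] = {}
        for k in active:
            if k in (a, b):
                continue
            duk = max((dist[a][k] + dist[b][k] - dab) / 2, 0.0)
            dist[u][k] = dist[k][u] = duk
        active = [k for k in active if k not in (a, b)] + [u]
    a, b = active
    dab = max(dist[a][b], 0.0)
    for x, lx in below[a].items():
        for y, ly in below[b].items():
            paths[tuple(sorted((x, y)))] = lx + dab + ly
    return paths


def pair_expected_residual_oracle(obs: np.ndarray):
    """Independence expectations and adjusted residuals via plain loops."""
    obs = np.asarray(obs, dtype=float)
    n = obs.sum()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    exp = np.empty_like(obs)
    resid = np.empty_like(obs)
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = rows[i] * cols[j] / n
            exp[i, j] = e
            var = e * (1 - rows[i] / n) * (1 - cols[j] / n)
            resid[i, j] = (obs[i, j] - e) / math.sqrt(var) if var > 0 else math.nan
    return exp, resid


def random_count_table(rng: np.random.Generator, code, n_codons: int = 300,
                       alpha: float = 1.0) -> dict[str, int]:
    """Random codon counts over all sense codons (every family occupied)."""
    codons = list(code.sense_codons)
    probs = rng.dirichlet(np.full(len(codons), alpha))
    draws = rng.multinomial(n_codons, probs)
    counts = {c: int(k) for c, k in zip(codons, draws)}
    # guarantee every family is seen at least twice (keeps both ENc
    # estimators on the no-imputation path)
    for aa, fam in code.families.items():
        if sum(counts[c] for c in fam) < 2:
            counts[fam[0]] += 2
    return counts
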