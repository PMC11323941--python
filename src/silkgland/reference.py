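"""Naive reference implementations used as independent cross-checks.

Everything here is written as plain loops over Python scalars, deliberately
avoiding the vectorized code paths of the main modules, so the two routes
can be compared on random instances.
"""
from __future__ import annotations

import math

import numpy as np


def percent_total_spectra_naive(counts: dict[str, dict[str, int]]) -> dict:
    """counts[sample][protein] -> percentages, computed with scalar loops."""
    out = {}
    for sample, row in counts.items():
        total = 0
        for v in row.values():
            total += v
        out[sample] = {p: 100.0 * v / total for p, v in row.items()}
    return out


def nsaf_naive(counts: dict[str, dict[str, int]], lengths: dict[str, float]) -> dict:
    out = {}
    for sample, row in counts.items():
        rates = {p: v / lengths[p] for p, v in row.items()}
        total = sum(rates.values())
        out[sample] = {p: r / total for p, r in rates.items()}
    return out


def motif_counts_naive(seq: str, polya_min: int = 4) -> dict:
    """Sliding-window motif counter with explicit position bookkeeping."""
    seq = seq.upper()
    n = len(seq)
    # poly-A maximal runs
    polya = 0
    i = 0
    while i < n:
        if seq[i] == "A":
            j = i
            while j < n and seq[j] == "A":
                j += 1
            if j - i >= polya_min:
                polya += 1
            i = j
        else:
            i += 1
    # GPGXX first (left to right, non-overlapping)
    blocked = set()
    gpgxx = 0
    i = 0
    while i <= n - 5:
        if seq[i] == "G" and seq[i + 1] == "P" and seq[i + 2] == "G":
            gpgxx += 1
            for j in range(i, i + 5):
                blocked.add(j)
            i += 5
        else:
            i += 1
    # GGX on unblocked positions
    ggx = 0
    i = 0
    while i <= n - 3:
        window_ok = all(j not in blocked for j in (i, i + 1, i + 2))
        if seq[i] == "G" and seq[i + 1] == "G" and window_ok:
            ggx += 1
            i += 3
        else:
            i += 1
    return {"polyA": polya, "GGX": ggx, "GPGXX": gpgxx}


def pearson_naive(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def pearson_matrix_naive(columns: dict[str, list[float]]) -> dict:
    names = list(columns)
    out = {a: {} for a in names}
    for a in names:
        for b in names:
            out[a][b] = pearson_naive(columns[a], columns[b])
    return out


def hypergeom_sf_naive(k: int, M: int, n: int, N: int) -> float:
    """P(X >= k) for drawing N from M with n successes, via math.comb."""
    total = math.comb(M, N)
    p = 0.0
    for x in range(k, min(n, N) + 1):
        p += math.comb(n, x) * math.comb(M - n, N - x) / total
    return p


def welch_t_naive(a, b):
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def tpm_naive(counts: dict[str, float], lengths: dict[str, float]) -> dict:
    rates = {g: c / lengths[g] for g, c in counts.items()}
    total = sum(rates.values())
    return {g: 1e6 * r / total for g, r in rates.items()}


def bh_adjust_naive(pvals: list[float]) -> list[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj


def simplex_grid_fit(signatures: np.ndarray, y: np.ndarray, step: float = 0.01):
    """Exhaustive simplex search for the best-fitting mixture direction.

    Enumerates all 3-type proportion vectors on a grid of the given step,
    fits the optimal nonnegative scale analytically for each candidate, and
    returns the proportions minimizing the residual norm.  An independent
    oracle for NNLS-based deconvolution (3 types only).
    """
    if signatures.shape[1] != 3:
        raise ValueError("grid oracle supports exactly 3 types")
    steps = int(round(1.0 / step))
    best, best_r = None, np.inf
    for i in range(steps + 1):
        for j in range(steps - i + 1):
            k = steps - i - j
            p = np.array([i, j, k], dtype=float) / steps
            v = signatures @ p
            denom = float(v @ v)
            alpha = float(v @ y) / denom if denom > 0 else 0.0
            alpha = max(alpha, 0.0)
            r = float(np.linalg.norm(y - alpha * v))
            if r < best_r - 1e-12:
                best, best_r = p, r
    return best, best_r


def nipals_pls2(X: np.ndarray, Y: np.ndarray, n_components: int = 2,
                max_iter: int = 500, tol: float = 1e-12):
    """Textbook NIPALS PLS2 on centered X, Y; returns scores and loadings."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    T, P, W, Q = [], [], [], []
    for _ in range(n_components):
        u = Y[:, [int(np.argmax(Y.var(axis=0)))]]
        t_old = None
        for _ in range(max_iter):
            w = X.T @ u
            w /= np.linalg.norm(w)
            t = X @ w
            q = Y.T @ t / (t.T @ t).item()
            u = Y @ q / (q.T @ q).item()
            if t_old is not None and np.linalg.norm(t - t_old) < tol:
                break
            t_old = t
        p = X.T @ t / (t.T @ t).item()
        X = X - t @ p.T
        Y = Y - t @ q.T
        T.append(t)
        P.append(p)
        W.append(w)
        Q.append(q)
    return (np.hstack(T), np.hstack(P), np.hstack(W), np.hstack(Q))
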