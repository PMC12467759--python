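"""Independent brute-force / simulation oracles used by the test suite.

Everything here is deliberately written from first principles, sharing no
code path with the package implementation it is used to check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def bh_bruteforce(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """BH adjusted p-values straight from the definition:
    adj(i) = min_{j >= i} p_(j) * m / j, computed with explicit loops."""
    p = np.asarray(p, dtype=float)
    m = p.size if m is None else m
    order = np.argsort(p, kind="stable")
    out = np.empty_like(p)
    for pos, idx in enumerate(order):
        rank = pos + 1
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(pos, p.size)
        ]
        out[idx] = min(1.0, min(candidates))
    return out


def ranksum_permutation_p(x, y, n_perm: int, seed: int) -> float:
    """Two-sided permutation p for the rank-sum of y, by resampling group
    labelings uniformly."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, n_y = pooled.size, len(y)
    w_obs = ranks[len(x):].sum()
    mu = n_y * (n + 1) / 2.0
    rng = np.random.default_rng(seed)
    u = rng.random((n_perm, n))
    idx = np.argsort(u, axis=1)[:, :n_y]
    w = ranks[idx].sum(axis=1)
    return float(np.mean(np.abs(w - mu) >= abs(w_obs - mu) - 1e-9))


def _corr_rows(x_sel: np.ndarray, y_sel: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of matched selections (n_perm, n)."""
    xc = x_sel - x_sel.mean(axis=1, keepdims=True)
    yc = y_sel - y_sel.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    return num / den


def dce_permutation_p(x, y, labels, n_perm: int, seed: int) -> float:
    """Two-sided permutation p for the correlation-difference test: group
    labels are shuffled, the Fisher-z difference statistic is recomputed per
    shuffle, and the observed |Z| is referred to that null."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lab = np.asarray(labels)
    n = x.size
    g1 = np.where(lab)[0]
    n1 = g1.size
    n2 = n - n1
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))

    def z_stat(idx1, idx2):
        r1 = _corr_rows(x[idx1], y[idx1])
        r2 = _corr_rows(x[idx2], y[idx2])
        return (np.arctanh(r1) - np.arctanh(r2)) / se

    z_obs = z_stat(g1[None, :], np.where(~lab)[0][None, :])[0]
    rng = np.random.default_rng(seed)
    u = rng.random((n_perm, n))
    order = np.argsort(u, axis=1)
    z_perm = z_stat(order[:, :n1], order[:, n1:])
    return float(np.mean(np.abs(z_perm) >= abs(z_obs) - 1e-12))


def reference_mcl(adj: np.ndarray, inflation: float = 2.0, n_iter: int = 200):
    """A minimal, independent dense MCL: fixed iteration count, no pruning,
    clusters read directly from the rows of the limit matrix."""
    m = adj.astype(float).copy()
    n = m.shape[0]
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    m[np.diag_indices(n)] = loop
    m = m / m.sum(axis=0)
    for _ in range(n_iter):
        m = m @ m
        m = m**inflation
        m = m / m.sum(axis=0)
    clusters = []
    for i in range(n):
        if m[i, i] > 1e-8:
            members = frozenset(np.nonzero(m[i] > 1e-8)[0]) | {i}
            clusters.append(members)
    merged: list[set] = []
    for c in clusters:
        hit = None
        for mset in merged:
            if mset & c:
                hit = mset
                break
        if hit is None:
            merged.append(set(c))
        else:
            hit.update(c)
    covered = set().union(*merged) if merged else set()
    for i in range(n):
        if i not in covered:
            merged.append({i})
    return {frozenset(c) for c in merged}
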