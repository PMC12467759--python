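"""Per-gene Wilcoxon rank-sum differential expression between the mutant and
wild-type groups, multiple-testing correction, direction calls, and
same-direction cross-dataset intersection.

The rank-sum test is deliberately distribution-free: it is invariant under
any strictly monotone transform of the expression scale, which is what makes
results comparable between an RSEM-quantified sequencing cohort and a
log-scale microarray cohort.  The default p-value uses the normal
approximation with mid-ranks, tie-corrected variance and (optionally)
continuity correction — standard practice at cohort sample sizes; an exact
enumeration over all C(n1+n2, n1) group labelings is available for small n
and serves as the oracle for the approximation.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import GROUP_MUT, GROUP_WT, ExpressionDataset

DIRECTION_UP = "UP"
DIRECTION_DOWN = "DOWN"
DIRECTION_NONE = "NONE"

EXACT_MAX_N = 12  # exact enumeration allowed up to C(12, n1) labelings


def _rank_sum_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by enumerating all group labelings.

    Mid-ranks handle ties.  The two-sided p is twice the smaller one-sided
    tail, capped at 1 — the same convention R's wilcox.test and scipy's
    exact method use, so the exact and asymptotic modes are directly
    comparable.
    """
    pooled = np.concatenate([x, y])
    n = pooled.size
    n_y = y.size
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[x.size:].sum())
    n_ge = n_le = 0
    total = comb(n, n_y)
    for idx in combinations(range(n), n_y):
        w = ranks[list(idx)].sum()
        if w >= w_obs - 1e-9:
            n_ge += 1
        if w <= w_obs + 1e-9:
            n_le += 1
    return w_obs, min(1.0, 2.0 * min(n_ge, n_le) / total)


def wilcoxon_rank_sum(
    x, y, *, mode: str = "approx", continuity: bool = True
) -> tuple[float, float]:
    """Rank-sum test of group WT (``x``) against group MUT (``y``).

    Returns ``(W, p)`` where ``W`` is the rank-sum of ``y`` in the pooled
    mid-ranked data and ``p`` is two-sided.  ``mode="exact"`` enumerates all
    labelings (only for ``len(x)+len(y) <= 12``); ``mode="approx"`` uses the
    tie-corrected normal approximation.  If every pooled value is identical
    the test is degenerate and ``p = 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    n = pooled.size
    if np.ptp(pooled) == 0.0:
        return y.size * (n + 1) / 2.0, 1.0
    if mode == "exact":
        if n > EXACT_MAX_N:
            raise ValueError(f"exact mode limited to n1+n2 <= {EXACT_MAX_N}")
        return _rank_sum_exact(x, y)
    if mode != "approx":
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(
        y, x, alternative="two-sided", method="asymptotic", use_continuity=continuity
    )
    w = float(res.statistic) + y.size * (y.size + 1) / 2.0
    return w, float(res.pvalue)


def adjust_pvalues(p, method: str, m: int | None = None) -> np.ndarray:
    """Bonferroni or Benjamini–Hochberg adjustment with family size ``m``.

    ``m`` may exceed ``len(p)`` (e.g. p-values for a subset of a larger test
    family); unobserved members then count toward the correction exactly as
    in R's ``p.adjust(..., n=m)``.  Output order matches input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else int(m)
    if m < p.size:
        raise ValueError("family size m must be >= len(p)")
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, p.size + 1)
        adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
        out = np.empty_like(adj)
        out[order] = adj
        return out
    raise ValueError(f"unknown method {method!r}")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test raw-p threshold controlling FWER at ``alpha`` over ``m`` tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def run_deg(
    ds: ExpressionDataset,
    method: str = "bonferroni",
    alpha: float = 0.05,
    continuity: bool = True,
) -> pd.DataFrame:
    """Test every gene for differential expression between MUT and WT.

    Returns one row per gene with columns ``gene, W, p, p_bonf, p_bh, p_adj,
    direction, mean_wt, mean_mut, degenerate, significant``.  The correction
    family size is the number of genes tested; ``p_adj`` is the adjusted
    p-value of the requested ``method`` and ``significant`` is
    ``p_adj < alpha``.  Direction is the sign of the mutant-vs-wild-type mean
    difference (ties → NONE).
    """
    xw = ds.group_values(GROUP_WT)
    xm = ds.group_values(GROUP_MUT)
    n_wt, n_mut = xw.shape[1], xm.shape[1]
    if n_wt == 0 or n_mut == 0:
        raise ValueError("both groups must be non-empty")

    degenerate = np.ptp(np.concatenate([xw, xm], axis=1), axis=1) == 0.0
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(
            xm, xw, alternative="two-sided", method="asymptotic",
            use_continuity=continuity, axis=1,
        )
    w = np.asarray(res.statistic, dtype=float) + n_mut * (n_mut + 1) / 2.0
    p = np.asarray(res.pvalue, dtype=float)
    p[degenerate] = 1.0
    w[degenerate] = n_mut * (n_wt + n_mut + 1) / 2.0

    mean_wt = xw.mean(axis=1)
    mean_mut = xm.mean(axis=1)
    direction = np.where(
        mean_mut > mean_wt, DIRECTION_UP,
        np.where(mean_mut < mean_wt, DIRECTION_DOWN, DIRECTION_NONE),
    )
    direction = np.where(degenerate, DIRECTION_NONE, direction)

    m = ds.n_genes
    p_bonf = adjust_pvalues(p, "bonferroni", m)
    p_bh = adjust_pvalues(p, "bh", m)
    p_adj = p_bonf if method == "bonferroni" else p_bh
    if method not in ("bonferroni", "bh"):
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(
        {
            "gene": ds.genes,
            "W": w,
            "p": p,
            "p_bonf": p_bonf,
            "p_bh": p_bh,
            "p_adj": p_adj,
            "direction": direction,
            "mean_wt": mean_wt,
            "mean_mut": mean_mut,
            "degenerate": degenerate,
            "significant": p_adj < alpha,
        }
    )


def intersect_deg(
    a: pd.DataFrame, b: pd.DataFrame, require_same_direction: bool = True
) -> pd.DataFrame:
    """Genes significant in both datasets, optionally with matching direction.

    With ``require_same_direction`` the direction of change must agree and
    genes with direction NONE are excluded — the replication rule for the
    cross-cohort DEG signature.
    """
    sa = a[a["significant"]][["gene", "direction", "p"]]
    sb = b[b["significant"]][["gene", "direction", "p"]]
    merged = sa.merge(sb, on="gene", suffixes=("_a", "_b"))
    if require_same_direction:
        merged = merged[
            (merged["direction_a"] == merged["direction_b"])
            & (merged["direction_a"] != DIRECTION_NONE)
        ]
    merged = merged.sort_values("gene", kind="stable").reset_index(drop=True)
    merged["direction"] = np.where(
        merged["direction_a"] == merged["direction_b"], merged["direction_a"], "MIXED"
    )
    return merged
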