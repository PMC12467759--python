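"""Differential co-expression between groups via Fisher-transformed Pearson
correlations.

For each gene pair the Pearson correlation is computed separately in the
wild-type and mutant groups, variance-stabilised with Fisher's
transformation ``z = atanh(r)``, and the difference is tested against the
standard normal:

    Z = (z_wt - z_mut) / sqrt(1/(N_wt - 3) + 1/(N_mut - 3))

Before pairing, genes are filtered to the top fraction (default 25%) by
pooled expression variance; the correction family is all C(m, 2) pairs of
the filtered panel.  A gain (loss) of co-expression is a positive (negative)
change of r in the mutant group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import GROUP_MUT, GROUP_WT, ExpressionDataset
from .deg import adjust_pvalues

logger = logging.getLogger("dicoex")

CLAMP = 1.0 - 1e-7  # |r| at which atanh would blow up on degenerate input

GAIN = "GAIN"
LOSS = "LOSS"


@dataclass
class VarianceFilterResult:
    """Genes retained by the top-variance pre-filter."""

    selected: list[str]
    variances: pd.Series  # variance per gene, all genes
    fraction: float


def variance_filter(ds: ExpressionDataset, fraction: float = 0.25) -> VarianceFilterResult:
    """Select the top ``ceil(fraction * n_genes)`` genes by pooled variance.

    Variance is computed across all samples (both groups, unbiased n−1
    denominator).  Ties at the cutoff are broken by gene symbol ascending.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    var = ds.values.var(axis=1, ddof=1)
    if np.all(var == 0):
        raise ValueError("all genes have zero variance")
    count = int(np.ceil(fraction * ds.n_genes))
    order = sorted(range(ds.n_genes), key=lambda i: (-var[i], ds.genes[i]))
    selected = sorted(ds.genes[i] for i in order[:count])
    return VarianceFilterResult(
        selected=selected,
        variances=pd.Series(var, index=ds.genes, name="variance"),
        fraction=fraction,
    )


def fisher_z(r):
    """Fisher z-transformation ``z = ½ ln((1+r)/(1−r)) = atanh(r)``.

    Correlations within 1e-7 of ±1 are clamped so degenerate (numerically
    perfect) correlations yield a large finite z instead of ±inf.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("|r| must be <= 1")
    clamped = np.clip(r, -CLAMP, CLAMP)
    n_clamped = int(np.sum(np.abs(r) > CLAMP))
    if n_clamped:
        logger.warning("fisher_z: clamped %d correlation(s) at |r|=%g", n_clamped, CLAMP)
    out = np.arctanh(clamped)
    return float(out) if out.ndim == 0 else out


def dce_z_statistic(r1, n1: int, r2, n2: int):
    """Z statistic and two-sided p for a correlation difference.

    ``(r1, n1)`` are the wild-type correlation and sample count, ``(r2, n2)``
    the mutant ones.  Requires more than 3 samples per group (the Fisher-z
    variance ``1/(N−3)`` is undefined otherwise).  The p-value is computed
    through the log survival function, so it stays accurate far below
    1e-300 (extremely large |Z| underflows float64 and is reported as 0.0).
    """
    n1, n2 = int(n1), int(n2)
    if n1 <= 3 or n2 <= 3:
        raise ValueError("each group needs more than 3 samples")
    z1 = fisher_z(r1)
    z2 = fisher_z(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    logp = np.log(2.0) + stats.norm.logsf(np.abs(z))
    p = np.minimum(1.0, np.exp(logp))
    if np.ndim(z) == 0:
        return float(z), float(p)
    return z, p


def bonferroni_pair_threshold(alpha: float, n_genes_filtered: int) -> float:
    """Raw-p threshold at FWER ``alpha`` over all C(m, 2) gene pairs."""
    if n_genes_filtered < 2:
        raise ValueError("need at least 2 genes to form a pair")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / comb(n_genes_filtered, 2)


def _group_correlation(x: np.ndarray, block_size: int) -> np.ndarray:
    """Pearson correlation matrix of the rows of ``x``, computed in row
    blocks so the standardized copy, not the full outer product workspace,
    bounds memory."""
    n = x.shape[1]
    xs = x - x.mean(axis=1, keepdims=True)
    sd = xs.std(axis=1, ddof=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    xs = xs / (sd_safe[:, None] * np.sqrt(n))
    m = x.shape[0]
    corr = np.empty((m, m))
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        corr[start:stop] = xs[start:stop] @ xs.T
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr


def run_dce(
    ds: ExpressionDataset,
    fraction: float = 0.25,
    method: str = "bonferroni",
    alpha: float = 0.05,
    block_size: int = 1024,
) -> pd.DataFrame:
    """Test all gene pairs of the variance-filtered panel for differential
    co-expression.

    Genes with zero variance within either group are excluded before pairing
    (their correlation is undefined); the correction family size stays
    ``C(m, 2)`` for the ``m`` filtered genes.  Returns one row per pair with
    columns ``gene_a, gene_b, r_wt, r_mut, z_wt, z_mut, Z, n_wt, n_mut, p,
    p_bonf, p_bh, p_adj, delta_direction, significant`` with
    ``gene_a < gene_b`` lexicographically.
    """
    if method not in ("bonferroni", "bh"):
        raise ValueError(f"unknown method {method!r}")
    n_wt, n_mut = ds.group_sizes()
    if n_wt <= 3 or n_mut <= 3:
        raise ValueError("each group needs more than 3 samples")

    panel = variance_filter(ds, fraction).selected
    m_family = comb(len(panel), 2)
    idx = [ds.genes.index(g) for g in panel]
    xw = ds.values[idx][:, ds.group_mask(GROUP_WT)]
    xm = ds.values[idx][:, ds.group_mask(GROUP_MUT)]
    ok = (xw.std(axis=1) > 0) & (xm.std(axis=1) > 0)
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        logger.warning(
            "run_dce: excluded %d gene(s) with zero within-group variance", n_excluded
        )
    genes = np.asarray(panel)[ok]  # panel is sorted, so genes stay sorted
    xw, xm = xw[ok], xm[ok]
    if genes.size < 2:
        raise ValueError("fewer than 2 usable genes after filtering")

    cw = _group_correlation(xw, block_size)
    cm = _group_correlation(xm, block_size)
    iu, ju = np.triu_indices(genes.size, k=1)
    r_wt = cw[iu, ju]
    r_mut = cm[iu, ju]
    z, p = dce_z_statistic(r_wt, n_wt, r_mut, n_mut)

    p_bonf = adjust_pvalues(p, "bonferroni", m_family)
    p_bh = adjust_pvalues(p, "bh", m_family)
    p_adj = p_bonf if method == "bonferroni" else p_bh
    return pd.DataFrame(
        {
            "gene_a": genes[iu],  # iu < ju and genes sorted => gene_a < gene_b
            "gene_b": genes[ju],
            "r_wt": r_wt,
            "r_mut": r_mut,
            "z_wt": fisher_z(r_wt),
            "z_mut": fisher_z(r_mut),
            "Z": z,
            "n_wt": n_wt,
            "n_mut": n_mut,
            "p": p,
            "p_bonf": p_bonf,
            "p_bh": p_bh,
            "p_adj": p_adj,
            "delta_direction": np.where(r_mut >= r_wt, GAIN, LOSS),
            "significant": p_adj < alpha,
        }
    )


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    """Ensure gene_a < gene_b on every row (idempotent)."""
    df = df.copy()
    swap = df["gene_a"] > df["gene_b"]
    if swap.any():
        a = df.loc[swap, "gene_a"].to_numpy()
        df.loc[swap, "gene_a"] = df.loc[swap, "gene_b"].to_numpy()
        df.loc[swap, "gene_b"] = a
    return df


def overlap_pairs(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pairs significant in both datasets, matched on the canonical pair key.

    Each overlap row carries both datasets' correlations and p-values
    (suffixes ``_a``/``_b``).
    """
    cols = ["gene_a", "gene_b", "r_wt", "r_mut", "p", "p_adj", "delta_direction"]
    sa = _canonical(a[a["significant"]])[cols]
    sb = _canonical(b[b["significant"]])[cols]
    out = sa.merge(sb, on=["gene_a", "gene_b"], suffixes=("_a", "_b"))
    return out.sort_values(["gene_a", "gene_b"], kind="stable").reset_index(drop=True)


def direction_consistent_pairs(
    a: pd.DataFrame,
    b: pd.DataFrame,
    strict_alpha: float = 0.05,
    nominal_alpha: float = 0.05,
) -> pd.DataFrame:
    """Relaxed replication: same direction of correlation change in both
    datasets, corrected-significant in one and nominally significant
    (raw p < ``nominal_alpha``) in the other."""
    cols = ["gene_a", "gene_b", "r_wt", "r_mut", "p", "p_adj", "delta_direction"]
    merged = _canonical(a)[cols].merge(
        _canonical(b)[cols], on=["gene_a", "gene_b"], suffixes=("_a", "_b")
    )
    same_dir = merged["delta_direction_a"] == merged["delta_direction_b"]
    a_strict = merged["p_adj_a"] < strict_alpha
    b_strict = merged["p_adj_b"] < strict_alpha
    cross = (a_strict & (merged["p_b"] < nominal_alpha)) | (
        b_strict & (merged["p_a"] < nominal_alpha)
    )
    out = merged[same_dir & cross]
    return out.sort_values(["gene_a", "gene_b"], kind="stable").reset_index(drop=True)


def genes_from_pairs(pairs) -> list[str]:
    """Sorted unique union of the genes appearing in a pair table or list."""
    if isinstance(pairs, pd.DataFrame):
        if pairs.empty:
            return []
        genes = set(pairs["gene_a"]) | set(pairs["gene_b"])
    else:
        genes = {g for pair in pairs for g in pair}
    return sorted(genes)
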