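"""Over-representation analysis of a gene list against GMT gene-set
collections.

The test is the one-sided (upper-tail) hypergeometric: for a universe of N
genes, a term with K members, and a query of n genes of which k hit the
term, p = P(X >= k) with X ~ Hypergeom(N, K, n).  The tail is summed in log
space, so very small p-values keep full relative accuracy.  Benjamini–
Hochberg FDR is applied per collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .deg import adjust_pvalues

logger = logging.getLogger("dicoex")


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against."""

    sets: dict[str, set[str]]
    universe: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sets:
            raise ValueError("empty collection")
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        self.universe = set(self.universe)

    def with_universe(self, universe) -> "GeneSetCollection":
        """A copy restricted to a caller-supplied background universe."""
        return GeneSetCollection(
            sets={k: set(v) for k, v in self.sets.items()},
            universe=set(universe),
            descriptions=dict(self.descriptions),
        )


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_p(k: int, big_k: int, n: int, big_n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``k`` = query∩term hits, ``big_k`` = term size, ``n`` = query size,
    ``big_n`` = universe size, all counted within the universe.  Exact tail
    sum in log space.
    """
    if not (0 <= k <= min(big_k, n) <= big_n) or big_k > big_n or n > big_n:
        raise ValueError(f"inconsistent counts k={k}, K={big_k}, n={n}, N={big_n}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(big_k, n) + 1)
    log_terms = (
        _log_comb(big_k, i) + _log_comb(big_n - big_k, n - i) - _log_comb(big_n, n)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def enrich(
    query,
    collection: GeneSetCollection,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in every term of the
    collection, with BH FDR across the collection's terms.

    Query genes outside the universe are dropped with a warning.  Returns
    one row per term (``term, description, k, K, n, N, p, fdr,
    significant``), sorted by FDR then p then term name.
    """
    query = set(query)
    universe = collection.universe
    inside = query & universe
    if len(inside) < len(query):
        logger.warning(
            "enrich: dropped %d query gene(s) outside the universe",
            len(query) - len(inside),
        )
    if not inside:
        raise ValueError("no query genes left after intersecting with the universe")
    big_n = len(universe)
    n = len(inside)
    rows = []
    for term, members in collection.sets.items():
        members_in = members & universe
        if not members_in:
            continue
        k = len(inside & members_in)
        rows.append(
            {
                "term": term,
                "description": collection.descriptions.get(term, ""),
                "k": k,
                "K": len(members_in),
                "n": n,
                "N": big_n,
                "p": hypergeometric_p(k, len(members_in), n, big_n),
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = adjust_pvalues(df["p"].to_numpy(), "bh")
    df["significant"] = df["fdr"] < alpha_fdr
    return df.sort_values(["fdr", "p", "term"], kind="stable").reset_index(drop=True)
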