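"""Integration of the differential-expression and differential-co-expression
results: the DEG∩DCE gene set that seeds network clustering, cross-dataset
intersection of enriched terms, and export of ranked up/down signatures in
the GRP format used by connectivity-map style queries.
"""

from __future__ import annotations

import logging

import pandas as pd

from .dataio import write_grp
from .deg import DIRECTION_DOWN, DIRECTION_UP

logger = logging.getLogger("dicoex")


def deg_dce_overlap(common_degs, dce_genes) -> pd.DataFrame:
    """Genes in both the replicated-DEG list and the DCE gene union.

    ``common_degs`` is either the DataFrame produced by
    :func:`dicoex.deg.intersect_deg` (direction provenance is kept) or a
    plain iterable of gene symbols.  Returns columns ``gene, from_deg,
    from_dce`` (always True) and ``direction`` when available.
    """
    if isinstance(common_degs, pd.DataFrame):
        deg_genes = list(common_degs["gene"])
        directions = dict(zip(common_degs["gene"], common_degs.get("direction", "")))
    else:
        deg_genes = list(common_degs)
        directions = {}
    dce_set = set(dce_genes)
    genes = sorted(g for g in set(deg_genes) if g in dce_set)
    return pd.DataFrame(
        {
            "gene": genes,
            "direction": [directions.get(g, "") for g in genes],
            "from_deg": True,
            "from_dce": True,
        }
    )


def intersect_enriched_terms(terms_a: pd.DataFrame, terms_b: pd.DataFrame) -> pd.DataFrame:
    """Terms significant in both datasets' enrichment results.

    Sorted by the worse (max) of the two FDRs, ascending — the conservative
    replication ordering.
    """
    sa = terms_a[terms_a["significant"]][["term", "fdr"]]
    sb = terms_b[terms_b["significant"]][["term", "fdr"]]
    merged = sa.merge(sb, on="term", suffixes=("_a", "_b"))
    merged["fdr_max"] = merged[["fdr_a", "fdr_b"]].max(axis=1)
    return merged.sort_values(["fdr_max", "term"], kind="stable").reset_index(drop=True)


def export_grp(
    degs: pd.DataFrame,
    up_path,
    down_path,
    top_k: int = 150,
) -> tuple[list[str], list[str]]:
    """Write the top-ranked up- and downregulated genes as GRP files.

    Genes are ranked by ascending raw p within each direction; ties at the
    cut are broken by gene symbol.  If fewer than ``top_k`` genes exist in a
    direction, all are written and a warning is logged.  Returns the two
    gene lists (up, down).
    """
    ranked = degs.sort_values(["p", "gene"], kind="stable")
    out = []
    for direction, path in ((DIRECTION_UP, up_path), (DIRECTION_DOWN, down_path)):
        genes = list(ranked.loc[ranked["direction"] == direction, "gene"][:top_k])
        if len(genes) < top_k:
            logger.warning(
                "export_grp: only %d %s genes available (requested %d)",
                len(genes), direction, top_k,
            )
        write_grp(genes, path)
        out.append(genes)
    return out[0], out[1]
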