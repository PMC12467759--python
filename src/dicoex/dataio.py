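"""Reading and writing of expression matrices, labels, probe maps, GMT gene
sets, interaction-network edge lists, and result tables.

All downstream statistics operate on :class:`ExpressionDataset`, a validated
gene×sample matrix with a binary group label (``MUT``/``WT``) per sample.
Expression values are accepted on whatever monotone scale the platform
produced (RSEM counts, log2 microarray intensities, ...); no internal
transform is applied, since every downstream test is rank- or
correlation-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("dicoex")

GROUP_WT = "WT"
GROUP_MUT = "MUT"
VALID_GROUPS = (GROUP_WT, GROUP_MUT)


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionDataset:
    """A gene×sample expression matrix with per-sample group labels.

    Parameters
    ----------
    platform_id
        Short label for the measurement platform / cohort.
    genes
        Row identifiers (gene symbols after probe collapsing, or probe IDs
        before).
    samples
        Column identifiers.
    values
        ``(len(genes), len(samples))`` float matrix on the platform's native
        scale.
    labels
        Per-sample group, each ``"WT"`` or ``"MUT"``; both groups must be
        non-empty.
    """

    platform_id: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise DataError("duplicate gene/probe identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise DataError("duplicate sample identifiers")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.labels) != len(self.samples):
            raise DataError("one group label required per sample")
        bad = sorted(set(self.labels) - set(VALID_GROUPS))
        if bad:
            raise DataError(f"unknown group labels: {bad}")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains non-finite values")
        for g in VALID_GROUPS:
            if g not in self.labels:
                raise DataError(f"group {g} has no samples")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_mask(self, group: str) -> np.ndarray:
        """Boolean sample mask for ``group`` (``"WT"`` or ``"MUT"``)."""
        if group not in VALID_GROUPS:
            raise DataError(f"unknown group {group!r}")
        lab = np.asarray(self.labels)
        return lab == group

    def group_values(self, group: str) -> np.ndarray:
        """Sub-matrix (genes × group samples) for one group."""
        return self.values[:, self.group_mask(group)]

    def group_sizes(self) -> tuple[int, int]:
        """(n_wt, n_mut)."""
        lab = np.asarray(self.labels)
        return int(np.sum(lab == GROUP_WT)), int(np.sum(lab == GROUP_MUT))


@dataclass
class ProbeMap:
    """Many-to-one probe → gene symbol mapping."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # dict keys enforce "no probe maps to more than one gene" by
        # construction; reading code guards against conflicting duplicates.
        self.mapping = dict(self.mapping)


def read_expression(
    matrix_path, labels_path, platform_id: str = "dataset"
) -> ExpressionDataset:
    """Read an expression matrix TSV plus a labels TSV.

    The matrix has a header row of sample IDs and one row per gene/probe
    (first column = identifier).  The labels file has columns ``sample_id``
    and ``group`` (values ``MUT``/``WT``).  Rows with any non-numeric entry
    are dropped with a logged count.  Samples present in the matrix but
    absent from the labels file are an error.
    """
    mat = pd.read_csv(
        matrix_path, sep="\t", index_col=0, float_precision="round_trip"
    )
    if mat.index.has_duplicates:
        raise DataError(f"{matrix_path}: duplicate row identifiers")
    if mat.columns.has_duplicates:
        raise DataError(f"{matrix_path}: duplicate sample identifiers")

    def parse_exact(cell):
        # python's float() is correctly rounded; pandas' fast to_numeric
        # parser is not, and full precision must survive a round trip
        try:
            return float(cell)
        except (TypeError, ValueError):
            return np.nan

    num = mat.apply(
        lambda col: col if col.dtype.kind == "f" else col.map(parse_exact)
    )
    bad_rows = num.isna().any(axis=1)
    if bad_rows.any():
        logger.warning(
            "%s: dropped %d row(s) with non-numeric entries",
            matrix_path,
            int(bad_rows.sum()),
        )
        num = num.loc[~bad_rows]
    if num.empty:
        raise DataError(f"{matrix_path}: no numeric rows")

    lab = pd.read_csv(labels_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in lab.columns:
            raise DataError(f"{labels_path}: missing column {col!r}")
    if lab["sample_id"].duplicated().any():
        raise DataError(f"{labels_path}: duplicate sample_id entries")
    label_of = dict(zip(lab["sample_id"], lab["group"]))
    missing = [s for s in num.columns if s not in label_of]
    if missing:
        raise DataError(
            f"{labels_path}: samples without labels: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    labels = [label_of[s] for s in num.columns]
    return ExpressionDataset(
        platform_id=platform_id,
        genes=list(num.index),
        samples=list(num.columns),
        values=num.to_numpy(dtype=float),
        labels=labels,
    )


def write_expression(ds: ExpressionDataset, matrix_path, labels_path) -> None:
    """Write a dataset back to the matrix/labels TSV pair read by
    :func:`read_expression`."""
    df = pd.DataFrame(ds.values, index=ds.genes, columns=ds.samples)
    df.index.name = "gene"
    df.to_csv(matrix_path, sep="\t", float_format="%.17g")
    pd.DataFrame({"sample_id": ds.samples, "group": ds.labels}).to_csv(
        labels_path, sep="\t", index=False
    )


def read_probe_map(path) -> ProbeMap:
    """Read a two-column TSV (``probe_id``, ``gene_symbol``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{path}: probe map needs two columns")
    probes = df.iloc[:, 0]
    genes = df.iloc[:, 1]
    mapping: dict[str, str] = {}
    for i, (p, g) in enumerate(zip(probes, genes), start=2):
        if p in mapping and mapping[p] != g:
            raise DataError(f"{path}: line {i}: probe {p!r} maps to multiple genes")
        mapping[p] = g
    return ProbeMap(mapping)


def collapse_probes(ds: ExpressionDataset, pm: ProbeMap) -> ExpressionDataset:
    """Collapse probe-level rows to one row per gene symbol.

    Unmapped probes are dropped (count logged).  When several probes map to
    the same gene the probe with the highest variance across all samples is
    retained — the retained row keeps its original measured values, only the
    identifier changes to the gene symbol.
    """
    mapped_idx = [i for i, p in enumerate(ds.genes) if p in pm.mapping]
    dropped = ds.n_genes - len(mapped_idx)
    if dropped:
        logger.warning(
            "collapse_probes: dropped %d unmapped probe(s) of %d", dropped, ds.n_genes
        )
    if not mapped_idx:
        raise DataError("no probes left after mapping")
    variances = ds.values.var(axis=1, ddof=1) if ds.n_samples > 1 else np.zeros(ds.n_genes)
    best: dict[str, int] = {}  # gene -> row index of max-variance probe
    for i in mapped_idx:
        gene = pm.mapping[ds.genes[i]]
        j = best.get(gene)
        if j is None or variances[i] > variances[j]:
            best[gene] = i
    # keep the original row order of the retained probes
    keep = sorted(best.values())
    gene_of_row = {i: g for g, i in best.items()}
    return ExpressionDataset(
        platform_id=ds.platform_id,
        genes=[gene_of_row[i] for i in keep],
        samples=ds.samples,
        values=ds.values[keep, :],
        labels=ds.labels,
    )


def read_gmt(path):
    """Read a GMT gene-set file into a :class:`~dicoex.enrichment.GeneSetCollection`.

    Each line: ``name<TAB>description<TAB>member1<TAB>member2...``.  The
    collection's default universe is the union of all member genes.
    """
    from .enrichment import GeneSetCollection

    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(
                    f"{path}: line {lineno}: GMT line needs name, description "
                    f"and at least one member"
                )
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise DataError(f"{path}: line {lineno}: empty gene set {name!r}")
            if name in sets:
                raise DataError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    if not sets:
        raise DataError(f"{path}: no gene sets")
    universe = set().union(*sets.values())
    return GeneSetCollection(sets=sets, universe=universe, descriptions=descriptions)


def read_edge_list(path) -> nx.Graph:
    """Read a weighted undirected edge list TSV (``geneA geneB weight``).

    Weights must lie in (0, 1] (interaction confidence).  Self-edges are
    dropped with a warning; malformed lines raise with their line number.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}: line {lineno}: expected geneA, geneB, weight")
            a, b, w_str = parts[0], parts[1], parts[2]
            if lineno == 1 and a.lower() in ("genea", "source", "node1"):
                continue  # optional header
            try:
                w = float(w_str)
            except ValueError as exc:
                raise DataError(f"{path}: line {lineno}: bad weight {w_str!r}") from exc
            if not 0.0 < w <= 1.0:
                raise DataError(f"{path}: line {lineno}: weight {w} outside (0, 1]")
            if a == b:
                logger.warning("%s: line %d: self-edge %s dropped", path, lineno, a)
                continue
            g.add_edge(a, b, weight=w)
    return g


def write_table(records: pd.DataFrame, path) -> None:
    """Write a result table as TSV with header, stable column order, and
    full-precision floats (round-trips to ≥ 12 significant digits)."""
    records.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_grp(genes, path) -> None:
    """Write a GRP signature file: one gene symbol per line."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_grp(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
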