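"""End-to-end orchestration of the two-cohort workflow.

Stage order: differential expression per dataset → same-direction DEG
intersection → differential co-expression per dataset → pair overlap /
direction-consistent pairs / common DCE genes → DEG∩DCE integration (plus
GRP signature export) → per-dataset enrichment with term intersection →
Markov clustering of the integrated genes on the interaction network →
cross-platform classification.  Every stage writes a TSV; a JSON manifest
records inputs, parameters, row counts, package version and seed.

Defaults follow the workflow's standard settings: alpha 0.05 everywhere,
variance fraction 0.25, MCL inflation 2.0, and Bonferroni on the large
first dataset with the explicit BH relaxation on the second (smaller)
dataset — the two-step correction is always stated in the config, never
applied silently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .classify import cross_platform_eval, l1_select
from .dataio import (
    ExpressionDataset,
    collapse_probes,
    read_edge_list,
    read_expression,
    read_gmt,
    read_probe_map,
    write_table,
)
from .dce import (
    direction_consistent_pairs,
    genes_from_pairs,
    overlap_pairs,
    run_dce,
    variance_filter,
)
from .deg import intersect_deg, run_deg
from .enrichment import enrich
from .integrate import deg_dce_overlap, export_grp, intersect_enriched_terms
from .mcl import induced_subgraph, mcl_cluster

logger = logging.getLogger("dicoex")


class PipelineError(RuntimeError):
    """A stage precondition failed; the message names the stage."""


@dataclass
class DatasetConfig:
    matrix: str
    labels: str
    platform_id: str
    probe_map: str | None = None


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run (YAML-serialisable)."""

    out_dir: str
    dataset_a: DatasetConfig
    dataset_b: DatasetConfig | None = None
    seed: int = 0
    alpha: float = 0.05
    deg_method_a: str = "bonferroni"
    deg_method_b: str = "bh"
    dce_fraction: float = 0.25
    dce_method_a: str = "bonferroni"
    dce_method_b: str = "bh"
    nominal_alpha: float = 0.05
    gmt: list[str] = field(default_factory=list)
    enrich_alpha: float = 0.05
    edges: str | None = None
    inflation: float = 2.0
    classify_folds: int = 10
    classify_protocol: str = "refit"
    grp_top_k: int = 150

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["dataset_a"] = DatasetConfig(**raw["dataset_a"])
        if raw.get("dataset_b"):
            raw["dataset_b"] = DatasetConfig(**raw["dataset_b"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _load(dc: DatasetConfig) -> ExpressionDataset:
    ds = read_expression(dc.matrix, dc.labels, platform_id=dc.platform_id)
    if dc.probe_map:
        ds = collapse_probes(ds, read_probe_map(dc.probe_map))
    return ds


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage and return the output manifest.

    Replication stages are skipped with a warning when only one dataset is
    configured.  Failure of the optional mcl or classify stages is logged
    and recorded in the manifest without aborting earlier outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v
            for k, v in asdict(cfg).items()
            if k not in ("dataset_a", "dataset_b", "out_dir")
        },
        "inputs": {
            "dataset_a": asdict(cfg.dataset_a),
            "dataset_b": asdict(cfg.dataset_b) if cfg.dataset_b else None,
        },
        "stages": {},
    }

    def record(stage: str, tables: dict, **extra) -> None:
        entry = {
            "outputs": {name: str(out / name) for name in tables},
            "row_counts": {name: int(len(df)) for name, df in tables.items()},
        }
        entry.update(extra)
        manifest["stages"][stage] = entry
        for name, df in tables.items():
            write_table(df, out / name)

    def fail(stage: str, exc: Exception) -> None:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    two = cfg.dataset_b is not None

    # --- load -------------------------------------------------------------
    try:
        ds_a = _load(cfg.dataset_a)
        ds_b = _load(cfg.dataset_b) if two else None
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        fail("load", exc)

    # --- differential expression -----------------------------------------
    try:
        deg_a = run_deg(ds_a, method=cfg.deg_method_a, alpha=cfg.alpha)
        tables = {"deg_a.tsv": deg_a}
        if two:
            deg_b = run_deg(ds_b, method=cfg.deg_method_b, alpha=cfg.alpha)
            tables["deg_b.tsv"] = deg_b
        record("deg", tables)
    except Exception as exc:
        fail("deg", exc)

    if two:
        try:
            deg_common = intersect_deg(deg_a, deg_b, require_same_direction=True)
            record("deg_intersect", {"deg_common.tsv": deg_common})
        except Exception as exc:
            fail("deg_intersect", exc)
    else:
        logger.warning("single dataset: replication stages skipped")
        deg_common = None

    # --- differential co-expression --------------------------------------
    try:
        dce_a = run_dce(
            ds_a, fraction=cfg.dce_fraction, method=cfg.dce_method_a, alpha=cfg.alpha
        )
        tables = {"dce_a.tsv": dce_a}
        if two:
            dce_b = run_dce(
                ds_b, fraction=cfg.dce_fraction, method=cfg.dce_method_b,
                alpha=cfg.alpha,
            )
            tables["dce_b.tsv"] = dce_b
        record("dce", tables)
    except Exception as exc:
        fail("dce", exc)

    integrated = None
    if two:
        try:
            overlap = overlap_pairs(dce_a, dce_b)
            consistent = direction_consistent_pairs(
                dce_a, dce_b, strict_alpha=cfg.alpha, nominal_alpha=cfg.nominal_alpha
            )
            import pandas as pd

            dce_genes = sorted(
                set(genes_from_pairs(dce_a[dce_a["significant"]]))
                & set(genes_from_pairs(dce_b[dce_b["significant"]]))
            )
            record(
                "dce_overlap",
                {
                    "dce_overlap.tsv": overlap,
                    "dce_consistent.tsv": consistent,
                    "dce_genes.tsv": pd.DataFrame({"gene": dce_genes}),
                },
            )
        except Exception as exc:
            fail("dce_overlap", exc)

        # --- integration + signature export -------------------------------
        try:
            integrated = deg_dce_overlap(deg_common, dce_genes)
            common_set = set(deg_common["gene"])
            deg_for_rank = deg_a[deg_a["gene"].isin(common_set)]
            up, down = export_grp(
                deg_for_rank, out / "signature_up.grp", out / "signature_down.grp",
                top_k=cfg.grp_top_k,
            )
            record(
                "integrate",
                {"integrated_genes.tsv": integrated},
                grp_up=str(out / "signature_up.grp"),
                grp_down=str(out / "signature_down.grp"),
                grp_sizes={"up": len(up), "down": len(down)},
            )
        except Exception as exc:
            fail("integrate", exc)

    # --- enrichment --------------------------------------------------------
    if cfg.gmt:
        try:
            import pandas as pd

            tables = {}
            common_terms = None
            genes_a = genes_from_pairs(dce_a[dce_a["significant"]])
            genes_b = genes_from_pairs(dce_b[dce_b["significant"]]) if two else []
            for gmt_path in cfg.gmt:
                coll = read_gmt(gmt_path)
                stem = Path(gmt_path).stem
                if not genes_a:
                    logger.warning(
                        "enrichment: no significant DCE genes in dataset A; skipped"
                    )
                    break
                # background = genes tested in the DCE stage (the filtered panel)
                uni_a = coll.universe | set(
                    variance_filter(ds_a, cfg.dce_fraction).selected
                )
                enr_a = enrich(genes_a, coll.with_universe(uni_a), cfg.enrich_alpha)
                tables[f"enrichment_a_{stem}.tsv"] = enr_a
                if two and genes_b:
                    uni_b = coll.universe | set(
                        variance_filter(ds_b, cfg.dce_fraction).selected
                    )
                    enr_b = enrich(genes_b, coll.with_universe(uni_b), cfg.enrich_alpha)
                    tables[f"enrichment_b_{stem}.tsv"] = enr_b
                    common = intersect_enriched_terms(enr_a, enr_b)
                    common_terms = (
                        common
                        if common_terms is None
                        else pd.concat([common_terms, common], ignore_index=True)
                    )
            if common_terms is not None:
                tables["enriched_terms_common.tsv"] = common_terms
            if tables:
                record("enrichment", tables)
        except Exception as exc:
            fail("enrichment", exc)
    else:
        logger.warning("no GMT collections configured: enrichment skipped")

    # --- optional: network clustering --------------------------------------
    if cfg.edges and integrated is not None:
        try:
            import pandas as pd

            net = read_edge_list(cfg.edges)
            sub = induced_subgraph(net, list(integrated["gene"]))
            result = mcl_cluster(sub, inflation=cfg.inflation)
            rows = [
                {"cluster": label, "gene": gene, "n_nodes": nc, "n_edges": ec}
                for label, members, nc, ec in zip(
                    result.labels, result.clusters, result.node_counts,
                    result.edge_counts,
                )
                for gene in members
            ]
            record(
                "mcl",
                {"clusters.tsv": pd.DataFrame(rows)},
                n_clusters=len(result.clusters),
                converged=result.converged,
            )
        except Exception as exc:  # optional stage: warn, keep earlier outputs
            logger.warning("stage mcl failed: %s", exc)
            manifest["stages"]["mcl"] = {"error": str(exc)}

    # --- optional: cross-platform classification ---------------------------
    if two:
        try:
            import pandas as pd

            candidates = list(deg_a.loc[deg_a["significant"], "gene"])
            selected, cv_auc = l1_select(
                ds_a, candidates, n_folds=cfg.classify_folds, seed=cfg.seed
            )
            report = cross_platform_eval(
                selected, ds_a, ds_b, protocol=cfg.classify_protocol, seed=cfg.seed
            )
            scores = pd.DataFrame(
                {"sample_id": report.sample_ids, "score": report.scores}
            )
            record(
                "classify",
                {
                    "classifier_scores.tsv": scores,
                    "selected_genes.tsv": pd.DataFrame({"gene": selected}),
                },
                cv_mean_auc=cv_auc,
                auc=report.auc,
                n_selected=len(selected),
                n_mapped=len(report.mapped_genes),
                protocol=report.protocol,
            )
        except Exception as exc:  # optional stage: warn, keep earlier outputs
            logger.warning("stage classify failed: %s", exc)
            manifest["stages"]["classify"] = {"error": str(exc)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
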