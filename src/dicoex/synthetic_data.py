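"""Synthetic two-group, two-platform expression data with planted signals.

The generator emulates the study design the pipeline targets: a large
sequencing-style cohort (~93 wild-type / 415 mutant samples) and a small
microarray-style cohort (~14 / 166), sharing a configurable fraction of
planted differentially expressed genes and differentially co-expressed gene
pairs so that cross-dataset replication stages have a known ground truth.

Planted differential co-expression uses exchangeable correlation blocks: for
a block of k genes, each group's values are drawn from a multivariate normal
whose correlation matrix has a single off-diagonal value (``r_wt`` or
``r_mut``).  Differential expression is a mean shift (in units of the noise
SD) applied to the mutant group.  Generation is a pure function of
``(seed, config, platform_id)``.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataio import GROUP_MUT, GROUP_WT, ExpressionDataset


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class DeGene:
    """A planted differentially expressed gene.

    ``shift`` is the mean difference (MUT − WT) in units of ``noise_sd``;
    ``sign`` (+1/−1) gives the direction, so the applied shift is
    ``sign * shift * noise_sd``.
    """

    index: int
    shift: float
    sign: int = 1

    def __post_init__(self):
        if self.shift < 0:
            raise SimulationError("shift is a magnitude; use sign for direction")
        if self.sign not in (-1, 1):
            raise SimulationError("sign must be +1 or -1")


@dataclass(frozen=True)
class DceBlock:
    """A planted block of co-expressed genes with group-specific correlation."""

    genes: tuple[int, ...]
    r_wt: float
    r_mut: float

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(self.genes) < 2:
            raise SimulationError("a correlation block needs at least 2 genes")
        for r in (self.r_wt, self.r_mut):
            if not -1.0 < r < 1.0:
                raise SimulationError(f"|r| must be < 1, got {r}")


@dataclass
class SimulationConfig:
    """Design of one simulated platform pair.

    ``n_wt``/``n_mut`` are the group sizes of the first (large) platform;
    ``n_wt_second``/``n_mut_second`` those of the second platform when
    :func:`simulate_pair_of_platforms` is used.  ``shared_fraction`` of the
    planted signals (rounded per signal class) is common to both platforms;
    the remainder is relocated to fresh gene indices on the second platform
    so platform-private signals are disjoint.
    """

    seed: int = 0
    n_genes: int = 2000
    n_wt: int = 93
    n_mut: int = 415
    de_spec: list[DeGene] = field(default_factory=list)
    dce_spec: list[DceBlock] = field(default_factory=list)
    shared_fraction: float = 1.0
    marginal: str = "gaussian"
    noise_sd: float = 1.0
    n_wt_second: int = 14
    n_mut_second: int = 166

    def __post_init__(self):
        if self.marginal not in ("gaussian", "lognormal"):
            raise SimulationError(f"unknown marginal {self.marginal!r}")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise SimulationError("shared_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be positive")
        for n in (self.n_wt, self.n_mut, self.n_wt_second, self.n_mut_second):
            if n < 4:
                raise SimulationError("each group needs at least 4 samples")
        block_genes: set[int] = set()
        for blk in self.dce_spec:
            if block_genes & set(blk.genes):
                raise SimulationError("correlation blocks must be disjoint")
            block_genes |= set(blk.genes)
        used = block_genes | {d.index for d in self.de_spec}
        if used and (min(used) < 0 or max(used) >= self.n_genes):
            raise SimulationError("planted signal index outside the gene range")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted signals of one simulated dataset."""

    de_genes: dict[str, str]  # gene symbol -> "UP"/"DOWN"
    dce_pairs: dict[tuple[str, str], tuple[float, float]]  # pair -> (r_wt, r_mut)

    def de_set(self) -> set[str]:
        return set(self.de_genes)

    def pair_set(self) -> set[tuple[str, str]]:
        return set(self.dce_pairs)


def gene_symbol(i: int) -> str:
    return f"G{i:05d}"


def _platform_stream(seed: int, platform_id: str) -> np.random.Generator:
    # substream keyed on (seed, platform_id) so adding a platform never
    # perturbs another platform's draws
    digest = hashlib.sha256(platform_id.encode()).digest()
    key = int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _exchangeable_chol(k: int, r: float) -> np.ndarray:
    c = np.full((k, k), r)
    np.fill_diagonal(c, 1.0)
    # exchangeable correlation is PD iff -1/(k-1) < r < 1
    if r <= -1.0 / (k - 1):
        raise SimulationError(
            f"exchangeable correlation r={r} with block size {k} is not "
            f"positive definite (requires r > {-1.0 / (k - 1):.3f})"
        )
    return np.linalg.cholesky(c)


def _draw_group(
    rng: np.random.Generator, cfg: SimulationConfig, n: int,
    de_spec: list[DeGene], dce_spec: list[DceBlock], group: str,
) -> np.ndarray:
    x = rng.standard_normal((cfg.n_genes, n))
    for blk in dce_spec:
        r = blk.r_wt if group == GROUP_WT else blk.r_mut
        chol = _exchangeable_chol(len(blk.genes), r)
        z = rng.standard_normal((len(blk.genes), n))
        x[list(blk.genes), :] = chol @ z
    x *= cfg.noise_sd
    if group == GROUP_MUT:
        for d in de_spec:
            x[d.index, :] += d.sign * d.shift * cfg.noise_sd
    return x


def _truth(de_spec, dce_spec) -> SyntheticTruth:
    de = {gene_symbol(d.index): ("UP" if d.sign > 0 else "DOWN") for d in de_spec}
    pairs: dict[tuple[str, str], tuple[float, float]] = {}
    for blk in dce_spec:
        syms = sorted(gene_symbol(i) for i in blk.genes)
        for a_i in range(len(syms)):
            for b_i in range(a_i + 1, len(syms)):
                pairs[(syms[a_i], syms[b_i])] = (blk.r_wt, blk.r_mut)
    return SyntheticTruth(de_genes=de, dce_pairs=pairs)


def simulate_dataset(
    cfg: SimulationConfig,
    platform_id: str,
    *,
    n_wt: int | None = None,
    n_mut: int | None = None,
    de_spec: list[DeGene] | None = None,
    dce_spec: list[DceBlock] | None = None,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate one platform's dataset and its truth table.

    The keyword overrides are used by :func:`simulate_pair_of_platforms` to
    realise the second platform's sizes and relocated private signals; plain
    calls use the config values.
    """
    n_wt = cfg.n_wt if n_wt is None else n_wt
    n_mut = cfg.n_mut if n_mut is None else n_mut
    de_spec = cfg.de_spec if de_spec is None else de_spec
    dce_spec = cfg.dce_spec if dce_spec is None else dce_spec
    rng = _platform_stream(cfg.seed, platform_id)
    xw = _draw_group(rng, cfg, n_wt, de_spec, dce_spec, GROUP_WT)
    xm = _draw_group(rng, cfg, n_mut, de_spec, dce_spec, GROUP_MUT)
    x = np.concatenate([xw, xm], axis=1)
    if cfg.marginal == "lognormal":
        x = np.exp(x)
    genes = [gene_symbol(i) for i in range(cfg.n_genes)]
    samples = [f"{platform_id}_WT_{i:04d}" for i in range(n_wt)] + [
        f"{platform_id}_MUT_{i:04d}" for i in range(n_mut)
    ]
    labels = [GROUP_WT] * n_wt + [GROUP_MUT] * n_mut
    ds = ExpressionDataset(
        platform_id=platform_id, genes=genes, samples=samples, values=x, labels=labels
    )
    return ds, _truth(de_spec, dce_spec)


def _relocate_private(cfg: SimulationConfig):
    """Split the planted signals into shared and second-platform specs."""
    k_de = int(round(cfg.shared_fraction * len(cfg.de_spec)))
    k_dce = int(round(cfg.shared_fraction * len(cfg.dce_spec)))
    shared_de, private_de = cfg.de_spec[:k_de], cfg.de_spec[k_de:]
    shared_dce, private_dce = cfg.dce_spec[:k_dce], cfg.dce_spec[k_dce:]

    used = {d.index for d in cfg.de_spec}
    for blk in cfg.dce_spec:
        used |= set(blk.genes)
    free = iter(i for i in range(cfg.n_genes) if i not in used)
    try:
        de_b = list(shared_de) + [replace(d, index=next(free)) for d in private_de]
        dce_b = list(shared_dce) + [
            replace(blk, genes=tuple(next(free) for _ in blk.genes))
            for blk in private_dce
        ]
    except StopIteration:
        raise SimulationError(
            "not enough free genes to relocate platform-private signals"
        ) from None
    return de_b, dce_b


def simulate_pair_of_platforms(
    cfg: SimulationConfig, platform_ids: tuple[str, str] = ("large", "small")
) -> tuple[
    tuple[ExpressionDataset, SyntheticTruth], tuple[ExpressionDataset, SyntheticTruth]
]:
    """Simulate two platforms sharing ``shared_fraction`` of planted signals.

    Shared signals keep identical directions and correlation values on both
    platforms; each platform's private signals occupy gene indices unused by
    any other signal, so private truths are disjoint.
    """
    first = simulate_dataset(cfg, platform_ids[0])
    de_b, dce_b = _relocate_private(cfg)
    second = simulate_dataset(
        cfg,
        platform_ids[1],
        n_wt=cfg.n_wt_second,
        n_mut=cfg.n_mut_second,
        de_spec=de_b,
        dce_spec=dce_b,
    )
    return first, second


def recovery_metrics(truth_items, called_items) -> tuple[float, float]:
    """Sensitivity and false discovery proportion of a called list.

    ``sensitivity = |called ∩ truth| / |truth|`` and
    ``FDP = |called \\ truth| / max(1, |called|)``.  Pair items are
    canonicalised to sorted tuples before comparison.
    """

    def canon(item):
        if isinstance(item, (tuple, list, frozenset, set)):
            return tuple(sorted(item))
        return item

    truth = {canon(t) for t in truth_items}
    called = {canon(c) for c in called_items}
    tp = len(called & truth)
    sens = tp / max(1, len(truth))
    fdp = (len(called) - tp) / max(1, len(called))
    return sens, fdp


def config_from_yaml(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from YAML.

    ``de_spec`` entries are ``[index, shift, sign]`` lists; ``dce_spec``
    entries are ``[[gene indices], r_wt, r_mut]`` lists.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "de_spec" in raw:
        raw["de_spec"] = [DeGene(int(i), float(s), int(sg)) for i, s, sg in raw["de_spec"]]
    if "dce_spec" in raw:
        raw["dce_spec"] = [
            DceBlock(tuple(int(g) for g in genes), float(rw), float(rm))
            for genes, rw, rm in raw["dce_spec"]
        ]
    return SimulationConfig(**raw)


def write_demo_inputs(
    cfg: SimulationConfig,
    out_dir,
    platform_ids: tuple[str, str] = ("large", "small"),
    n_decoy_terms: int = 30,
    decoy_term_size: int = 20,
) -> dict:
    """Materialise a complete, self-contained pipeline input bundle.

    Simulates the two platforms and writes: matrix/label TSVs, truth tables,
    a GMT collection (one term per class of planted genes plus random decoy
    terms), a synthetic interaction network whose edges form cliques over
    the shared planted DE genes (so network clustering has real structure to
    find) with random decoy edges, and a ready-to-run ``pipeline.yaml``.
    Returns the path map.  Everything is a pure function of ``cfg``.
    """
    from pathlib import Path

    import pandas as pd

    from .dataio import write_expression
    from .pipeline import DatasetConfig, PipelineConfig

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (ds_a, truth_a), (ds_b, truth_b) = simulate_pair_of_platforms(cfg, platform_ids)
    paths = {}
    for tag, ds, truth in (("a", ds_a, truth_a), ("b", ds_b, truth_b)):
        paths[f"matrix_{tag}"] = out / f"matrix_{tag}.tsv"
        paths[f"labels_{tag}"] = out / f"labels_{tag}.tsv"
        write_expression(ds, paths[f"matrix_{tag}"], paths[f"labels_{tag}"])
        pd.DataFrame(
            [(g, d) for g, d in sorted(truth.de_genes.items())],
            columns=["gene", "direction"],
        ).to_csv(out / f"truth_de_{tag}.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(a, b, rw, rm) for (a, b), (rw, rm) in sorted(truth.dce_pairs.items())],
            columns=["gene_a", "gene_b", "r_wt", "r_mut"],
        ).to_csv(out / f"truth_dce_{tag}.tsv", sep="\t", index=False)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x6D1C]))
    shared_de = sorted(truth_a.de_set() & truth_b.de_set())
    shared_dce_genes = sorted(
        {g for pair in (truth_a.pair_set() & truth_b.pair_set()) for g in pair}
    )
    universe = [gene_symbol(i) for i in range(cfg.n_genes)]

    gmt_path = out / "gene_sets.gmt"
    with open(gmt_path, "w") as fh:
        if shared_de:
            fh.write("PLANTED_DE\tshared planted DE genes\t" + "\t".join(shared_de) + "\n")
        if shared_dce_genes:
            fh.write(
                "PLANTED_DCE\tshared planted DCE genes\t"
                + "\t".join(shared_dce_genes) + "\n"
            )
        for t in range(n_decoy_terms):
            members = rng.choice(universe, size=decoy_term_size, replace=False)
            fh.write(f"DECOY_{t:03d}\trandom decoy term\t" + "\t".join(members) + "\n")
    paths["gmt"] = gmt_path

    edges_path = out / "network_edges.tsv"
    with open(edges_path, "w") as fh:
        fh.write("geneA\tgeneB\tweight\n")
        # cliques of 5 over the shared DE genes: ground-truth modules
        for start in range(0, len(shared_de) - 1, 5):
            clique = shared_de[start : start + 5]
            for i in range(len(clique)):
                for j in range(i + 1, len(clique)):
                    fh.write(f"{clique[i]}\t{clique[j]}\t0.8\n")
        planted = set(shared_de)
        decoy_pool = [g for g in universe if g not in planted]
        for _ in range(200):
            a, b = rng.choice(len(decoy_pool), size=2, replace=False)
            fh.write(f"{decoy_pool[a]}\t{decoy_pool[b]}\t{rng.uniform(0.2, 0.6):.3f}\n")
    paths["edges"] = edges_path

    pcfg = PipelineConfig(
        out_dir=str(out / "results"),
        dataset_a=DatasetConfig(
            matrix=str(paths["matrix_a"]), labels=str(paths["labels_a"]),
            platform_id=platform_ids[0],
        ),
        dataset_b=DatasetConfig(
            matrix=str(paths["matrix_b"]), labels=str(paths["labels_b"]),
            platform_id=platform_ids[1],
        ),
        seed=cfg.seed,
        gmt=[str(gmt_path)],
        edges=str(edges_path),
    )
    paths["pipeline_config"] = out / "pipeline.yaml"
    pcfg.to_yaml(paths["pipeline_config"])
    return {k: str(v) for k, v in paths.items()}


def default_config(seed: int = 0) -> SimulationConfig:
    """The desk-scale two-platform design used by the bundled pipeline.

    2,000 genes; large platform 93 WT / 415 MUT, small platform 14 WT /
    166 MUT (the WT/MUT splits of the cohorts the generator emulates, at the
    study's proportions); 50 DE genes at a 2-SD shift (25 up, 25 down); 20
    correlation blocks of 2 genes losing co-expression in the mutant group
    (r_wt = 0.9 → r_mut = 0.0).  The block genes are a subset of the DE genes
    so that the mean shift inflates their pooled variance past the variance
    filter, and the DEG∩DCE integration stage has a non-empty truth.
    """
    de = [DeGene(i, 2.0, 1 if i % 2 == 0 else -1) for i in range(50)]
    dce = [DceBlock((2 * j, 2 * j + 1), 0.9, 0.0) for j in range(20)]
    return SimulationConfig(seed=seed, de_spec=de, dce_spec=dce, shared_fraction=0.5)
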