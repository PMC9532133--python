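"""Synthetic study generator with planted ground truth.

Emulates the five pipeline inputs at desk scale (defaults: 2,000 genes, 300
miRNAs, 500 PPI nodes, 9 HF vs 7 healthy miRNA samples, 9/9/9 acute/chronic/
healthy mRNA samples, roughly one tenth of the cohorts the pipeline is aimed
at): log2 expression matrices with planted fold changes and Gaussian noise,
GMT gene sets overlapping the planted features, a miRNA->target pair table, a
scale-free protein-protein interaction graph carrying a seeded connected
disease module, and drug target sets at controlled placement relative to
that module. Every generator is bit-reproducible under a fixed seed, and the
planted truth records exactly what each downstream stage should recover.

Expression is generated directly on the log2 scale (array-like data, no
count model): per-feature Gaussian baselines, additive group shifts for
planted features, i.i.d. Gaussian noise. The coherent study additionally
plants one anchor gene driven by a per-sample latent factor shared with a
co-expressed neighborhood block, so that correlation screens, trend filters,
ROC, and the proximity screen all have a recoverable target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    ConfigurationError,
    ExpressionMatrix,
    GeneSetCollection,
    write_expression,
    write_gmt,
    write_json,
    write_table,
)

BASELINE_MEAN = 7.0  # log2 intensity scale typical of arrays
BASELINE_SD = 2.0


class GenerationError(ConfigurationError):
    pass


@dataclass
class SimulationConfig:
    """Knobs for every synthetic input; defaults are the study conditions."""

    seed: int = 0
    n_features: int = 2000
    group_sizes: dict[str, int] = field(default_factory=lambda: {"HF": 9, "healthy": 7})
    planted_de: list[tuple[str, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    ppi_nodes: int = 500
    # attachment of 1 keeps the graph sparse (a scale-free tree): typical
    # shortest distances then exceed typical ln(degree+1) hub bonuses, so the
    # omega-weighted proximity of a module-targeted drug is identifiable.
    ppi_attach_edges: int = 1
    disease_module_size: int = 20
    drug_specs: list[tuple[str, int, str]] = field(default_factory=list)
    n_gene_sets: int = 12
    set_size_range: tuple[int, int] = (15, 40)
    n_target_pairs: int = 1000

    def validate(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ConfigurationError("every group needs >= 2 samples")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.disease_module_size > self.ppi_nodes:
            raise ConfigurationError("disease_module_size exceeds ppi_nodes")
        if not all(np.isfinite(e) for _, e in self.planted_de):
            raise ConfigurationError("planted log2 effects must be finite")
        if self.set_size_range[0] > self.set_size_range[1]:
            raise ConfigurationError("set_size_range is inverted")
        max_targets = max((n for _, n, _ in self.drug_specs), default=0)
        if self.ppi_nodes < self.disease_module_size + max_targets:
            raise ConfigurationError(
                "ppi_nodes must cover the disease module plus the largest drug"
            )
        for _, _, placement in self.drug_specs:
            if placement not in ("inside_module", "neighbors", "random"):
                raise ConfigurationError(f"unknown drug placement {placement!r}")


@dataclass
class PlantedTruth:
    """What the pipeline should recover from a synthetic study."""

    de_features: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    regulatory_pairs: list[tuple[str, str]] = field(default_factory=list)
    disease_module: list[str] = field(default_factory=list)
    proximal_drug: str | None = None
    anchor_gene: str | None = None
    zero_target_mirna: str | None = None

    def to_json(self) -> dict:
        return asdict(self)


def _feature_ids(prefix: str, n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate_expression(
    config: SimulationConfig,
    contrast_design: dict[str, float],
    feature_prefix: str = "G",
    seed: int | None = None,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Log2 expression with planted additive group shifts.

    ``contrast_design`` maps each group label to an effect multiplier: a
    planted feature with log2 effect e gets its mean shifted by
    e * multiplier in that group. A three-group design with decreasing
    multipliers therefore yields strictly monotone planted group means.
    """
    config.validate()
    missing = [g for g in contrast_design if g not in config.group_sizes]
    if missing:
        raise ConfigurationError(f"design groups absent from group_sizes: {missing}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    features = _feature_ids(feature_prefix, config.n_features)
    fid_index = {f: i for i, f in enumerate(features)}
    for fid, _ in config.planted_de:
        if fid not in fid_index:
            raise ConfigurationError(f"planted feature {fid!r} not among features")

    samples, labels = [], []
    for group in config.group_sizes:  # insertion order is deterministic
        for j in range(config.group_sizes[group]):
            samples.append(f"{group}_{j}")
            labels.append(group)
    groups = pd.Series(labels, index=samples)

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=config.n_features)
    x = np.tile(baseline[:, None], (1, len(samples)))
    shift = np.zeros((config.n_features, len(samples)))
    mult = np.array([contrast_design.get(g, 0.0) for g in labels])
    for fid, effect in config.planted_de:
        shift[fid_index[fid]] = effect * mult
    x = x + shift + rng.normal(0.0, config.noise_sd, size=x.shape)

    values = pd.DataFrame(x, index=features, columns=samples)
    matrix = ExpressionMatrix(values, groups)
    truth = PlantedTruth(
        de_features={
            "planted": [(fid, "up" if e > 0 else "down") for fid, e in config.planted_de]
        }
    )
    return matrix, truth


def _connected_module(graph: nx.Graph, size: int, rng: np.random.Generator) -> list[int]:
    """A connected node subset grown by BFS from a random start."""
    start = int(rng.choice(sorted(graph.nodes())))
    module = [start]
    seen = {start}
    frontier = sorted(graph.neighbors(start))
    while len(module) < size and frontier:
        nxt = int(rng.choice(frontier))
        module.append(nxt)
        seen.add(nxt)
        frontier = sorted(
            {v for u in module for v in graph.neighbors(u)} - seen
        )
    if len(module) < size:
        raise GenerationError("could not grow a connected module of requested size")
    return module


def generate_ppi(
    config: SimulationConfig,
    module_genes: list[str] | None = None,
    gene_labels: list[str] | None = None,
    seed: int | None = None,
    max_retries: int = 5,
) -> tuple[nx.Graph, list[str], dict[str, list[str]]]:
    """Scale-free PPI with a seeded connected disease module and drug targets.

    Returns (graph, module node list, drug_id -> target list). All generated
    edges carry combined_score >= 400 so the medium-confidence STRING filter
    is a pass-through unless a test lowers scores. Node labels default to
    ``P####``; ``module_genes``/``gene_labels`` pin names so the PPI shares
    identifiers with an expression matrix.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    graph = None
    for _ in range(max_retries):
        cand = nx.barabasi_albert_graph(
            config.ppi_nodes, config.ppi_attach_edges,
            seed=int(rng.integers(2**31)),
        )
        if nx.is_connected(cand):
            graph = cand
            break
    if graph is None:
        raise GenerationError("preferential-attachment graph repeatedly disconnected")

    module_ints = _connected_module(graph, config.disease_module_size, rng)

    # relabel: module nodes get module_genes (if given), the rest gene_labels
    n = config.ppi_nodes
    if module_genes is not None and len(module_genes) != len(module_ints):
        raise ConfigurationError("module_genes length must equal disease_module_size")
    default_names = _feature_ids("P", n)
    others = [v for v in sorted(graph.nodes()) if v not in set(module_ints)]
    mapping: dict[int, str] = {}
    if module_genes is None:
        module_genes = [default_names[v] for v in module_ints]
    mapping.update(dict(zip(module_ints, module_genes)))
    if gene_labels is not None:
        if len(gene_labels) < len(others):
            raise ConfigurationError("not enough gene_labels for non-module nodes")
        mapping.update(dict(zip(others, gene_labels)))
    else:
        mapping.update({v: default_names[v] for v in others})
    graph = nx.relabel_nodes(graph, mapping)
    module = [mapping[v] for v in module_ints]

    for u, v in graph.edges():
        graph[u][v]["combined_score"] = int(rng.integers(400, 1000))

    module_set = set(module)
    neighbor_pool = sorted(
        {v for u in module for v in graph.neighbors(u)} - module_set
    )
    outside_pool = sorted(set(graph.nodes()) - module_set)
    drug_targets: dict[str, list[str]] = {}
    for drug_id, n_targets, placement in config.drug_specs:
        if placement == "inside_module":
            pool = sorted(module_set)
        elif placement == "neighbors":
            pool = neighbor_pool
        else:
            pool = outside_pool
        if n_targets > len(pool):
            raise GenerationError(
                f"drug {drug_id}: pool of {len(pool)} nodes < {n_targets} targets"
            )
        drug_targets[drug_id] = sorted(rng.choice(pool, n_targets, replace=False))
    return graph, module, drug_targets


def generate_gene_sets(
    config: SimulationConfig,
    matrix: ExpressionMatrix,
    enriched: dict[str, list[str]] | None = None,
    seed: int | None = None,
) -> GeneSetCollection:
    """Random gene sets plus optional planted-enriched sets.

    ``enriched`` maps set names to gene lists that must appear in the set
    (e.g. a hypoxia-like set seeded with planted up-shifted features); each
    set is padded with random genes up to the configured size range.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.set_size_range
    if hi > len(matrix.feature_ids):
        raise ConfigurationError("requested set sizes exceed n_features")
    all_genes = np.array(matrix.feature_ids)
    sets: dict[str, list[str]] = {}
    enriched = enriched or {}
    for name, core in enriched.items():
        size = int(rng.integers(lo, hi + 1))
        core = list(dict.fromkeys(core))
        pad = max(size - len(core), 0)
        pool = np.array(sorted(set(all_genes) - set(core)))
        extra = list(rng.choice(pool, pad, replace=False)) if pad else []
        sets[name] = core + [str(g) for g in extra]
    i = 0
    while len(sets) < config.n_gene_sets:
        name = f"RANDOM_SET_{i:02d}"
        i += 1
        if name in sets:
            continue
        size = int(rng.integers(lo, hi + 1))
        sets[name] = [str(g) for g in rng.choice(all_genes, size, replace=False)]
    return GeneSetCollection(sets, universe=list(matrix.feature_ids))


def generate_target_pairs(
    config: SimulationConfig,
    mirna_ids: list[str],
    gene_ids: list[str],
    planted_pairs: list[tuple[str, str]] | None = None,
    zero_target_mirna: str | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """miRNA->gene pair table: planted regulatory pairs plus random pairs.

    ``zero_target_mirna`` names a miRNA guaranteed to have no targets,
    mirroring regulators absent from the prediction database.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    planted_pairs = planted_pairs or []
    eligible_m = [m for m in mirna_ids if m != zero_target_mirna]
    pairs = set(planted_pairs)
    if zero_target_mirna is not None and any(m == zero_target_mirna for m, _ in pairs):
        raise ConfigurationError("planted pair uses the designated zero-target miRNA")
    while len(pairs) < len(planted_pairs) + config.n_target_pairs:
        m = str(rng.choice(eligible_m))
        g = str(rng.choice(gene_ids))
        pairs.add((m, g))
    df = pd.DataFrame(sorted(pairs), columns=["mirna", "gene"])
    return df


# ---------------------------------------------------------------------------
# coherent end-to-end study
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    gene_sets: GeneSetCollection
    target_pairs: pd.DataFrame
    ppi: nx.Graph
    drug_targets: dict[str, list[str]]
    truth: PlantedTruth
    config_mirna: SimulationConfig
    config_mrna: SimulationConfig


ENERGY_SETS = ["SULFUR_METABOLISM", "OXIDATIVE_PHOSPHORYLATION", "NITROGEN_METABOLISM"]
INFLAMMATION_SETS = [
    "TLR_SIGNALING", "TCR_SIGNALING", "NFKB_SIGNALING",
    "JAK_STAT_SIGNALING", "BCR_SIGNALING", "IL6_FAMILY",
]
HYPOXIA_SET = "HYPOXIA_LIKE"


def generate_study(
    seed: int = 0,
    n_genes: int = 2000,
    n_mirnas: int = 300,
    noise_sd: float = 1.0,
    effect: float = 2.0,
    n_up: int = 60,
    n_down: int = 40,
    n_de_mirnas: int = 30,
    module_size: int = 20,
    ppi_nodes: int = 500,
    null_drug_count: int = 4,
    n_drug_targets: int = 10,
    n_target_pairs: int = 1000,
) -> StudyData:
    """One coherent synthetic study with a fully recoverable planted truth.

    Plants (i) DE miRNAs (HF vs healthy, two-group), (ii) DE genes shifted in
    both HF groups, (iii) one anchor gene whose mean decreases strictly
    acute > chronic > healthy, driven by a per-sample latent factor shared
    with a 20-gene co-expressed neighborhood block (the future disease
    module), (iv) gene sets whose cores contain block and up-shifted genes so
    composite scores track the latent factor, (v) a target-pair table in
    which the anchor is the most-targeted gene of the DE miRNAs, and (vi) a
    PPI whose disease module carries the block genes, with one drug targeted
    inside the module and the rest placed at random outside.
    """
    root = np.random.SeedSequence(seed)
    s_mirna, s_mrna, s_latent, s_sets, s_pairs, s_ppi = (
        int(c.generate_state(1)[0] % (2**31)) for c in root.spawn(6)
    )

    # --- miRNA side: two groups, planted two-sided shifts -----------------
    mirna_ids = _feature_ids("hsa-mir-", n_mirnas)
    n_up_m = 2 * n_de_mirnas // 3
    planted_m = [(mirna_ids[i], effect) for i in range(n_up_m)] + [
        (mirna_ids[i], -effect) for i in range(n_up_m, n_de_mirnas)
    ]
    cfg_mirna = SimulationConfig(
        seed=s_mirna, n_features=n_mirnas,
        group_sizes={"HF": 9, "healthy": 7},
        planted_de=planted_m, noise_sd=noise_sd,
        n_target_pairs=n_target_pairs,
    )
    mirna_matrix, _ = generate_expression(
        cfg_mirna, {"HF": 1.0, "healthy": 0.0}, feature_prefix="hsa-mir-"
    )

    # --- mRNA side: three groups ------------------------------------------
    gene_ids = _feature_ids("G", n_genes)
    up_genes = gene_ids[:n_up]
    down_genes = gene_ids[n_up:n_up + n_down]
    anchor = gene_ids[n_up + n_down]
    block = gene_ids[n_up + n_down + 1: n_up + n_down + 1 + module_size]
    planted_g = [(g, effect) for g in up_genes] + [(g, -effect) for g in down_genes]
    cfg_mrna = SimulationConfig(
        seed=s_mrna, n_features=n_genes,
        group_sizes={"acute": 9, "chronic": 9, "healthy": 9},
        planted_de=planted_g, noise_sd=noise_sd,
        ppi_nodes=ppi_nodes, disease_module_size=module_size,
        drug_specs=(
            [("DRUG_PLANTED", n_drug_targets, "inside_module")]
            + [(f"DRUG_RANDOM_{i}", n_drug_targets, "random")
               for i in range(null_drug_count)]
        ),
        n_target_pairs=n_target_pairs,
    )
    mrna_matrix, _ = generate_expression(
        cfg_mrna, {"acute": 1.0, "chronic": 1.0, "healthy": 0.0}, feature_prefix="G"
    )

    # overlay the latent anchor/neighborhood structure
    rng = np.random.default_rng(s_latent)
    groups = mrna_matrix.groups
    group_shift = groups.map({"acute": 1.5 * effect, "chronic": 0.75 * effect,
                              "healthy": 0.0}).to_numpy(dtype=float)
    latent = group_shift + rng.normal(0.0, 1.0, size=len(groups))
    vals = mrna_matrix.values
    base = rng.normal(BASELINE_MEAN, BASELINE_SD, size=1 + len(block))
    vals.loc[anchor] = base[0] + latent + rng.normal(0.0, 0.3, size=len(groups))
    for j, g in enumerate(block):
        vals.loc[g] = base[1 + j] + latent + rng.normal(0.0, noise_sd, size=len(groups))

    # --- gene sets ---------------------------------------------------------
    rng_sets = np.random.default_rng(s_sets)
    def core(n_block: int, n_up_g: int) -> list[str]:
        picked_b = [str(g) for g in rng_sets.choice(block, n_block, replace=False)]
        picked_u = [str(g) for g in rng_sets.choice(up_genes, n_up_g, replace=False)]
        return picked_b + picked_u

    enriched = {HYPOXIA_SET: [anchor] + list(block) + core(0, 9)}
    for name in ENERGY_SETS:
        enriched[name] = core(7, 8)
    enriched[INFLAMMATION_SETS[0]] = core(7, 8)
    for name in INFLAMMATION_SETS[1:]:
        enriched[name] = []  # purely random fill
    gene_sets = generate_gene_sets(cfg_mrna, mrna_matrix, enriched=enriched,
                                   seed=s_sets)

    # --- target pairs: anchor is the best-connected DE-miRNA target -------
    de_up_mirnas = [m for m, e in planted_m if e > 0]
    zero_target = de_up_mirnas[-1]
    regulators = de_up_mirnas[:6]
    planted_pairs = [(m, anchor) for m in regulators]
    planted_pairs += [
        (str(rng.choice([m for m in de_up_mirnas if m != zero_target])), str(g))
        for g in list(up_genes[:10]) + list(block[:5])
    ]
    planted_pairs = sorted(set(planted_pairs))
    target_pairs = generate_target_pairs(
        cfg_mirna, mirna_ids, gene_ids, planted_pairs=planted_pairs,
        zero_target_mirna=zero_target, seed=s_pairs,
    )

    # --- PPI and drugs ------------------------------------------------------
    non_module = [g for g in gene_ids if g not in set(block)]
    other_labels = [str(g) for g in
                    np.random.default_rng(s_ppi).choice(
                        non_module, ppi_nodes - module_size, replace=False)]
    ppi, module, drug_targets = generate_ppi(
        cfg_mrna, module_genes=list(block), gene_labels=other_labels, seed=s_ppi
    )

    truth = PlantedTruth(
        de_features={
            "mirna_HF_vs_healthy": [(m, "up" if e > 0 else "down") for m, e in planted_m],
            "mrna_HF_vs_healthy": (
                [(g, "up") for g in up_genes] + [(g, "down") for g in down_genes]
                + [(anchor, "up")] + [(g, "up") for g in block]
            ),
        },
        regulatory_pairs=planted_pairs,
        disease_module=module,
        proximal_drug="DRUG_PLANTED",
        anchor_gene=anchor,
        zero_target_mirna=zero_target,
    )
    return StudyData(
        mirna=mirna_matrix, mrna=mrna_matrix, gene_sets=gene_sets,
        target_pairs=target_pairs, ppi=ppi, drug_targets=drug_targets,
        truth=truth, config_mirna=cfg_mirna, config_mrna=cfg_mrna,
    )


def write_study(study: StudyData, outdir: str | Path) -> dict[str, str]:
    """Write every study table in the plain-text exchange formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_matrix": out / "mirna_matrix.tsv",
        "mirna_groups": out / "mirna_groups.tsv",
        "mrna_matrix": out / "mrna_matrix.tsv",
        "mrna_groups": out / "mrna_groups.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "target_pairs": out / "target_pairs.tsv",
        "ppi": out / "ppi_edges.tsv",
        "drug_targets": out / "drug_targets.tsv",
        "truth": out / "truth.json",
    }
    write_expression(study.mirna, paths["mirna_matrix"], paths["mirna_groups"])
    write_expression(study.mrna, paths["mrna_matrix"], paths["mrna_groups"])
    write_gmt(study.gene_sets, paths["gene_sets"])
    write_table(study.target_pairs, paths["target_pairs"])
    edges = pd.DataFrame(
        [(u, v, int(d["combined_score"])) for u, v, d in
         sorted(study.ppi.edges(data=True))],
        columns=["protein1", "protein2", "combined_score"],
    )
    write_table(edges, paths["ppi"])
    dt = pd.DataFrame(
        [(drug, g) for drug in sorted(study.drug_targets)
         for g in study.drug_targets[drug]],
        columns=["drug_id", "gene"],
    )
    write_table(dt, paths["drug_targets"])
    write_json(study.truth.to_json(), paths["truth"])
    return {k: str(v) for k, v in paths.items()}
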