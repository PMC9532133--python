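"""End-to-end orchestration: DE -> network -> scores -> screens -> proximity.

A single :class:`PipelineConfig` carries every input path and threshold; one
global seed is fanned out per stage through a counter-based seed sequence so
stages are independently reproducible. Outputs are plain TSV/JSON written
with fixed float formatting, so a rerun with the same config and seed is
byte-identical. A manifest records the config hash, the seed, and per-stage
row counts.

:func:`prioritize` runs the gene-selection stages on in-memory inputs;
:func:`run_all` reads files, runs it, adds the proximity screen, and writes
every table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, diagnostics, diffexpr, enrichment, network, proximity
from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    InputError,
    MirnetproxError,
    read_drug_targets,
    read_expression,
    read_gmt,
    read_target_pairs,
    write_gene_list,
    write_json,
    write_table,
)
from .synthetic_data import ENERGY_SETS, HYPOXIA_SET, INFLAMMATION_SETS

logger = logging.getLogger(__name__)


class PipelineError(MirnetproxError):
    """A stage failed; the message names the failing stage."""


@dataclass
class PipelineConfig:
    """Paths, group labels, and the screening thresholds (printed defaults)."""

    # inputs
    mirna_matrix: str = ""
    mirna_groups: str = ""
    mrna_matrix: str = ""
    mrna_groups: str = ""
    gene_sets: str = ""
    target_pairs: str = ""
    ppi: str | None = None
    drug_targets: str | None = None
    outdir: str = "results"
    # group labels
    mirna_case: str = "HF"
    mirna_control: str = "healthy"
    mrna_groups_ordered: list[str] = field(
        default_factory=lambda: ["acute", "chronic", "healthy"]
    )
    mrna_control: str = "healthy"
    # composite score definitions
    hypoxia_set: str = HYPOXIA_SET
    energy_sets: list[str] = field(default_factory=lambda: list(ENERGY_SETS))
    inflammation_sets: list[str] = field(default_factory=lambda: list(INFLAMMATION_SETS))
    # thresholds
    lfc_min: float = 1.0
    mirna_fdr: float = 0.05
    mrna_p: float = 0.05
    ora_p: float = 0.05
    cor_min: float = 0.4
    cor_p: float = 0.05
    neighborhood_r: float = 0.4
    neighborhood_p: float = 0.001
    ppi_min_score: int = 400
    drug_fdr: float = 0.001
    auc_min: float = 0.7
    anova_p: float = 0.05
    null_reps: int = 10000
    ssgsea_alpha: float = 0.25
    null_mode: str = "uniform"
    drug_p_source: str = "empirical"
    seed: int = 0

    def validate_thresholds(self) -> None:
        for name in ("lfc_min", "mirna_fdr", "mrna_p", "ora_p", "cor_min", "cor_p",
                     "neighborhood_r", "neighborhood_p", "ppi_min_score",
                     "drug_fdr", "auc_min", "anova_p", "null_reps"):
            if getattr(self, name) <= 0:
                raise InputError(f"threshold {name} must be positive")

    def validate(self) -> None:
        self.validate_thresholds()
        for name in ("mirna_matrix", "mirna_groups", "mrna_matrix", "mrna_groups",
                     "gene_sets", "target_pairs"):
            if not Path(getattr(self, name)).exists():
                raise InputError(f"input path {name}={getattr(self, name)!r} missing")
        for name in ("ppi", "drug_targets"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise InputError(f"input path {name}={p!r} missing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, index: int) -> int:
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(index,))
        return int(ss.generate_state(1)[0] % (2**31))


def validate_inputs(config: PipelineConfig) -> dict:
    """Cross-check identifier overlap between the input tables.

    Returns a report with ``warnings`` (overlap below 50%) and raises on
    structurally broken inputs (e.g. an empty gene-set file, drug targets
    disjoint from the PPI).
    """
    config.validate()
    mrna = read_expression(config.mrna_matrix, config.mrna_groups)
    mirna = read_expression(config.mirna_matrix, config.mirna_groups)
    sets = read_gmt(config.gene_sets)  # raises naming the file when empty
    pairs = read_target_pairs(config.target_pairs)
    genes = set(mrna.feature_ids)
    warnings: list[str] = []

    def check(name: str, ids: set) -> None:
        if not ids:
            warnings.append(f"{name}: no identifiers")
            return
        frac = len(ids & genes) / len(ids)
        if frac < 0.5:
            warnings.append(f"{name}: only {frac:.0%} of ids overlap the mRNA matrix")

    check("target_pairs.gene", set(pairs["gene"]))
    check("gene_sets", {g for s in sets.sets.values() for g in s})
    frac_m = len(set(pairs["mirna"]) & set(mirna.feature_ids)) / max(len(set(pairs["mirna"])), 1)
    if frac_m < 0.5:
        warnings.append(f"target_pairs.mirna: only {frac_m:.0%} overlap the miRNA matrix")
    if config.ppi is not None:
        graph = network.load_ppi(config.ppi, min_score=config.ppi_min_score)
        check("ppi", set(graph.nodes()))
        if config.drug_targets is not None:
            drugs = read_drug_targets(config.drug_targets)
            tgt = {g for ts in drugs.values() for g in ts}
            if not tgt & set(graph.nodes()):
                raise InputError("drug targets are disjoint from the PPI graph")
    return {"warnings": warnings, "n_genes": len(genes),
            "n_mirnas": len(mirna.feature_ids)}


def prioritize(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    collection: GeneSetCollection,
    pairs: pd.DataFrame,
    config: PipelineConfig,
    outdir: Path | None = None,
) -> dict:
    """Gene-prioritization stages (everything before the proximity screen).

    Returns a bundle with the DE tables, the bipartite network, the composite
    scores, the candidate genes, the selected anchor and its co-expression
    neighborhood. With ``outdir`` each stage table is also written as TSV.
    """
    config.validate_thresholds()
    counts: dict[str, int] = {}

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        if outdir is not None:
            write_table(df, outdir / name, index=index)

    stage = "de_mirna"
    try:
        de_mirna = diffexpr.filter_de(
            diffexpr.moderated_t(mirna, config.mirna_case, config.mirna_control),
            lfc_min=config.lfc_min, alpha=config.mirna_fdr, criterion="fdr",
        )
        de_mirna["contrast"] = f"{config.mirna_case}_vs_{config.mirna_control}"
        emit("de_mirna.tsv", de_mirna)
        de_mirna_ids = diffexpr.significant_features(de_mirna)
        counts[stage] = len(de_mirna_ids)

        stage = "de_mrna"
        ctrl = config.mrna_control
        cases = [g for g in config.mrna_groups_ordered if g != ctrl]
        contrasts: dict[str, pd.DataFrame] = {}
        for case in cases:
            contrasts[f"{case}_vs_{ctrl}"] = diffexpr.filter_de(
                diffexpr.moderated_t(mrna, case, ctrl),
                lfc_min=config.lfc_min, alpha=config.mrna_p, criterion="raw_p",
            )
        pooled = mrna.relabel_groups({g: "HF_pooled" for g in cases})
        contrasts[f"HF_pooled_vs_{ctrl}"] = diffexpr.filter_de(
            diffexpr.moderated_t(pooled, "HF_pooled", ctrl),
            lfc_min=config.lfc_min, alpha=config.mrna_p, criterion="raw_p",
        )
        for name, df in contrasts.items():
            tagged = df.copy()
            tagged["contrast"] = name
            emit(f"de_mrna_{name}.tsv", tagged)

        stage = "merge_contrasts"
        merged = diffexpr.merge_contrasts(contrasts)
        emit("de_merged.tsv", merged)
        de_gene_ids = list(merged["feature"])
        counts[stage] = len(de_gene_ids)

        stage = "ora"
        ora_table = enrichment.ora(de_gene_ids, collection,
                                   universe=mrna.feature_ids, alpha=config.ora_p)
        emit("ora.tsv", ora_table)
        counts[stage] = int(ora_table["significant"].sum()) if len(ora_table) else 0

        stage = "network"
        net = network.build_mirna_mrna(de_mirna_ids, de_gene_ids, pairs)
        if net.n_edges and outdir is not None:
            network.export_network(net, outdir / "network.graphml", fmt="graphml")
            emit("network_degree.tsv", network.degree_table(net))
        counts[stage] = net.n_edges

        stage = "ssgsea"
        scores = enrichment.ssgsea(mrna, collection, alpha=config.ssgsea_alpha)
        scored = scores.copy()
        scored.index.name = "set_name"
        emit("scores.tsv", scored, index=True)
        counts[stage] = len(scores)

        stage = "composite_scores"
        hypoxia = scores.loc[config.hypoxia_set]
        hypoxia.name = "hypoxia"
        energy = association.composite_mean(scores, config.energy_sets,
                                            "energy_metabolism")
        inflammation = {
            name: scores.loc[name] for name in config.inflammation_sets
            if name in scores.index
        }
        comp = pd.DataFrame({"hypoxia": hypoxia, "energy_metabolism": energy}).T
        comp.index.name = "score"
        emit("composite_scores.tsv", comp, index=True)

        stage = "correlation_screens"
        screen_genes = net.gene_nodes if net.gene_nodes else de_gene_ids
        sub = ExpressionMatrix(
            mrna.values.loc[[g for g in screen_genes if g in mrna.values.index]],
            mrna.groups,
        )
        screens: dict[str, pd.DataFrame] = {
            "hypoxia": association.pearson_screen(
                sub, hypoxia, r_min=config.cor_min, p_max=config.cor_p, absolute=True),
            "energy": association.pearson_screen(
                sub, energy, r_min=config.cor_min, p_max=config.cor_p, absolute=True),
        }
        infl_sets: dict[str, set] = {}
        for name, vec in inflammation.items():
            vec = vec.copy()
            vec.name = f"inflammation:{name}"
            scr = association.pearson_screen(
                sub, vec, r_min=config.cor_min, p_max=config.cor_p, absolute=True)
            screens[f"inflammation:{name}"] = scr
            infl_sets[name] = association.significant_genes(scr)
        all_screens = pd.concat(screens.values(), ignore_index=True)
        emit("correlations.tsv", all_screens)
        counts[stage] = int(all_screens["significant"].sum())

        stage = "evidence_intersection"
        inflammation_union: set = set().union(*infl_sets.values()) if infl_sets else set()
        categories = {
            "hypoxia": association.significant_genes(screens["hypoxia"]),
            "energy": association.significant_genes(screens["energy"]),
            "inflammation": inflammation_union,
        }
        candidates = association.evidence_intersection(categories)
        counts[stage] = len(candidates)

        stage = "trend_filter"
        trend = association.trend_anova_filter(
            mrna, candidates, config.mrna_groups_ordered, alpha=config.anova_p)
        emit("trend.tsv", trend)
        trended = list(trend.loc[trend["passes"], "gene"]) if len(trend) else []
        counts[stage] = len(trended)

        stage = "roc"
        if trended:
            pooled_roc = mrna.relabel_groups({g: "HF_pooled" for g in cases})
            roc_matrix = ExpressionMatrix(pooled_roc.values.loc[trended],
                                          pooled_roc.groups)
            roc = diagnostics.per_feature_auc(
                roc_matrix, "HF_pooled", ctrl, auc_min=config.auc_min,
                allow_flip=True)
            emit("roc.tsv", roc)
            final_genes = list(roc.loc[roc["passes"], "feature"])
        else:
            roc = pd.DataFrame()
            final_genes = []
        counts[stage] = len(final_genes)
        emit("candidates.tsv", pd.DataFrame({"gene": final_genes}))

        stage = "anchor_selection"
        p_lookup = dict(zip(merged["feature"], merged["p_value"]))
        in_net = [g for g in final_genes if g in set(net.gene_nodes)]
        anchor = None
        if in_net:
            anchor = min(in_net,
                         key=lambda g: (-net.degree[g], p_lookup.get(g, 1.0), g))
        counts[stage] = int(anchor is not None)

        stage = "neighborhood"
        neighborhood: list[str] = []
        if anchor is not None:
            neighborhood = association.gene_neighborhood(
                mrna, anchor, r_min=config.neighborhood_r,
                p_max=config.neighborhood_p)
            if outdir is not None:
                write_gene_list(neighborhood, outdir / "neighborhood.txt")
        counts[stage] = len(neighborhood)
    except Exception as exc:
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "de_mirna": de_mirna, "de_mirna_ids": de_mirna_ids,
        "contrasts": contrasts, "merged": merged, "de_gene_ids": de_gene_ids,
        "ora": ora_table, "network": net, "scores": scores,
        "composite": comp, "screens": screens, "candidates": candidates,
        "trend": trend, "roc": roc, "candidate_genes": final_genes,
        "anchor_gene": anchor, "disease_genes": neighborhood,
        "stage_counts": counts,
    }


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in order and write provenance-stamped outputs.

    Any stage error aborts with the failing stage named; outputs written so
    far are kept. A missing drug table (or PPI) downgrades the proximity
    stage to a logged skip.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_inputs"
    try:
        mirna = read_expression(config.mirna_matrix, config.mirna_groups)
        mrna = read_expression(config.mrna_matrix, config.mrna_groups)
        collection = read_gmt(config.gene_sets)
        pairs = read_target_pairs(config.target_pairs)
    except Exception as exc:
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    bundle = prioritize(mirna, mrna, collection, pairs, config, outdir=out)
    counts = bundle["stage_counts"]
    anchor = bundle["anchor_gene"]
    neighborhood = bundle["disease_genes"]

    stage = "proximity"
    drug_hits: list[str] = []
    prox_table = pd.DataFrame()
    try:
        if config.ppi is None or config.drug_targets is None:
            logger.warning("proximity stage skipped: PPI or drug table not provided")
            counts[stage] = -1
        elif anchor is None or not neighborhood:
            logger.warning("proximity stage skipped: no anchor/neighborhood")
            counts[stage] = -1
        else:
            graph = network.load_ppi(config.ppi, min_score=config.ppi_min_score)
            disease = [g for g in neighborhood if g in graph]
            if not disease:
                raise InputError("disease gene set is disjoint from the PPI graph")
            drugs = read_drug_targets(config.drug_targets)
            records = proximity.proximity_screen_records(
                graph, disease, drugs, n_reps=config.null_reps,
                seed=config.stage_seed(12), mode=config.null_mode)
            prox_table = proximity.records_table(records)
            pcol = ("p_empirical" if config.drug_p_source == "empirical"
                    else "p_parametric")
            prox_table["fdr"] = diffexpr.bh_adjust(prox_table[pcol])
            write_table(prox_table, out / "proximity.tsv")
            hits = proximity.screen_drugs(records, fdr_max=config.drug_fdr,
                                          p_source=config.drug_p_source)
            drug_hits = list(hits["drug_id"])
            counts[stage] = len(drug_hits)
    except Exception as exc:
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
    bundle["candidate_drugs"] = drug_hits
    bundle["proximity"] = prox_table

    summary = {
        "anchor_gene": anchor,
        "candidate_genes": bundle["candidate_genes"],
        "candidate_drugs": drug_hits,
        "n_de_mirnas": len(bundle["de_mirna_ids"]),
        "n_de_genes": len(bundle["de_gene_ids"]),
        "n_network_edges": bundle["network"].n_edges,
        "n_disease_genes": len(neighborhood),
    }
    write_json(summary, out / "summary.json")
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_counts": counts,
    }
    write_json(manifest, out / "manifest.json")
    bundle["summary"] = summary
    bundle["manifest"] = manifest
    return bundle
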