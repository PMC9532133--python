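"""miRNA-mRNA bipartite regulatory network and PPI ingestion.

The PPI is a STRING-style edge list (protein1, protein2, combined_score)
filtered at a medium-confidence floor (score >= 400, inclusive), made simple
and undirected: self-loops dropped, duplicate edges collapsed keeping the
maximum score. The regulatory network links differential miRNAs to their
differential target genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .io import InputError

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 400


@dataclass
class BipartiteNet:
    """Bipartite miRNA->gene network with per-node degrees."""

    mirna_nodes: list[str]
    gene_nodes: list[str]
    edges: list[tuple[str, str]]
    degree: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.degree:
            deg: dict[str, int] = {n: 0 for n in self.mirna_nodes + self.gene_nodes}
            for m, g in self.edges:
                deg[m] += 1
                deg[g] += 1
            self.degree = deg

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for n in sorted(self.mirna_nodes):
            g.add_node(n, partition="mirna", degree=self.degree[n])
        for n in sorted(self.gene_nodes):
            g.add_node(n, partition="gene", degree=self.degree[n])
        g.add_edges_from(sorted(self.edges))
        return g


def load_ppi(
    source: str | Path | pd.DataFrame,
    min_score: int = DEFAULT_MIN_SCORE,
    aliases: dict[str, str] | None = None,
) -> nx.Graph:
    """Load a STRING-style edge table into a filtered simple graph.

    Edges with combined_score >= min_score are retained (inclusive floor);
    duplicates keep the maximum score; self-loops are dropped. ``aliases``
    optionally maps protein identifiers to gene symbols before filtering.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t")
    if df.shape[1] < 3:
        raise InputError("PPI table needs columns (protein1, protein2, combined_score)")
    graph = nx.Graph()
    for i, row in enumerate(df.itertuples(index=False), 2):  # header = line 1
        a, b, score = row[0], row[1], row[2]
        try:
            score = float(score)
        except (TypeError, ValueError):
            raise InputError(f"PPI line {i}: malformed score {score!r}") from None
        if pd.isna(a) or pd.isna(b):
            raise InputError(f"PPI line {i}: missing node identifier")
        a, b = str(a), str(b)
        if aliases:
            a = aliases.get(a, a)
            b = aliases.get(b, b)
        if a == b or score < min_score:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["combined_score"] = max(graph[a][b]["combined_score"], score)
        else:
            graph.add_edge(a, b, combined_score=score)
    if graph.number_of_edges() == 0:
        raise InputError(f"no PPI edges remain after score >= {min_score} filter")
    return graph


def load_aliases(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def build_mirna_mrna(
    de_mirnas,
    de_genes,
    target_pairs: pd.DataFrame,
) -> BipartiteNet:
    """Restrict the miRNA->target table to differential endpoints.

    miRNAs whose every target fails the DE filter vanish from the node set
    (mirroring regulators with no corresponding target gene); an empty
    network is allowed and logged.
    """
    de_m = set(de_mirnas)
    de_g = set(de_genes)
    edges = sorted(
        {
            (str(m), str(g))
            for m, g in zip(target_pairs["mirna"], target_pairs["gene"])
            if m in de_m and g in de_g
        }
    )
    mirnas = sorted({m for m, _ in edges})
    genes = sorted({g for _, g in edges})
    if not edges:
        logger.warning("miRNA-mRNA network is empty after DE restriction")
    return BipartiteNet(mirna_nodes=mirnas, gene_nodes=genes, edges=edges)


def export_network(net: BipartiteNet, path: str | Path, fmt: str = "graphml") -> None:
    """Write the network as GraphML (with partition/degree attributes) or SIF."""
    if net.n_edges == 0:
        raise InputError("refusing to export an empty network")
    path = Path(path)
    if fmt.lower() == "graphml":
        nx.write_graphml(net.to_graph(), path)
    elif fmt.lower() == "sif":
        with open(path, "w") as fh:
            for m, g in sorted(net.edges):
                fh.write(f"{m}\ttargets\t{g}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def import_network(path: str | Path, fmt: str = "graphml") -> BipartiteNet:
    path = Path(path)
    if fmt.lower() == "graphml":
        g = nx.read_graphml(path)
        mirnas = sorted(n for n, d in g.nodes(data=True) if d.get("partition") == "mirna")
        genes = sorted(n for n, d in g.nodes(data=True) if d.get("partition") == "gene")
        edges = sorted((a, b) if a in set(mirnas) else (b, a) for a, b in g.edges())
        return BipartiteNet(mirna_nodes=mirnas, gene_nodes=genes, edges=edges)
    if fmt.lower() == "sif":
        edges = []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 3:
                    edges.append((parts[0], parts[2]))
        mirnas = sorted({m for m, _ in edges})
        genes = sorted({g for _, g in edges})
        return BipartiteNet(mirna_nodes=mirnas, gene_nodes=genes, edges=sorted(edges))
    raise ValueError(f"unknown format {fmt!r}")


def degree_table(net: BipartiteNet) -> pd.DataFrame:
    rows = [
        {"node": n, "partition": "mirna" if n in set(net.mirna_nodes) else "gene",
         "degree": net.degree[n]}
        for n in sorted(net.degree)
    ]
    return pd.DataFrame(rows)
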