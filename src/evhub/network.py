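"""Global-data branch: interaction-network hub scoring by MCC and degree.

Builds an undirected gene interaction graph from a STRING-style edge list and
ranks genes by Maximal Clique Centrality,

    MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!

with node degree as tie-breaker.  Size-1 "cliques" (isolated nodes) score 0.
On triangle-free graphs every maximal clique is an edge, so MCC reduces to
degree; in clique-rich neighbourhoods the factorial term makes membership in
large cliques dominate, which is what makes MCC a hub statistic rather than a
connectivity count.

Maximal cliques are enumerated with the pivoting Bron-Kerbosch algorithm
(via :func:`networkx.find_cliques`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .targets import TargetMap

logger = logging.getLogger(__name__)


def read_edges(
    path,
    score_min: float = 400,
    columns: tuple[str, str] = ("protein1", "protein2"),
    score_column: str = "combined_score",
    strip_prefix: str | None = None,
) -> nx.Graph:
    """Read a STRING-style TSV edge list into a simple undirected graph.

    Edges with combined score (0-1000 scale) below ``score_min`` are dropped;
    if the score column is absent every edge is kept and a warning logged.
    ``strip_prefix`` removes a taxon prefix such as ``"10090."`` from node
    identifiers.  Reversed duplicate pairs collapse to one undirected edge and
    self-loops are discarded.
    """
    table = pd.read_csv(path, sep=r"\s+", engine="python")
    for col in columns:
        if col not in table.columns:
            raise ValueError(f"edge list is missing required column {col!r}")
    if score_column in table.columns:
        table = table[pd.to_numeric(table[score_column], errors="raise") >= score_min]
    else:
        logger.warning("edge list has no %r column: keeping all edges", score_column)
    graph = nx.Graph()
    for i, (u, v) in enumerate(zip(table[columns[0]], table[columns[1]])):
        u, v = str(u).strip(), str(v).strip()
        if not u or not v:
            raise ValueError(f"malformed edge row at data line {i + 1}")
        if strip_prefix:
            u = u.removeprefix(strip_prefix)
            v = v.removeprefix(strip_prefix)
        if u != v:
            graph.add_edge(u, v)
    return graph


def maximal_cliques(graph: nx.Graph, max_nodes: int = 5000) -> list[set]:
    """All maximal cliques of a simple undirected graph (Bron-Kerbosch with
    pivoting).  Guarded by a node-count ceiling against pathological inputs."""
    if graph.number_of_nodes() > max_nodes:
        raise ValueError(
            f"graph has {graph.number_of_nodes()} nodes, above the {max_nodes} guard"
        )
    if any(u == v for u, v in graph.edges):
        raise ValueError("graph must be simple (no self-loops)")
    return [set(c) for c in nx.find_cliques(graph)]


def mcc_scores(graph: nx.Graph, max_nodes: int = 5000) -> pd.DataFrame:
    """Per-gene MCC score and degree as a (gene, mcc, degree) DataFrame.

    Isolated nodes score 0 — a maximal clique must have size >= 2 to
    contribute its (|C|-1)! term.
    """
    mcc = {v: 0 for v in graph.nodes}
    for clique in maximal_cliques(graph, max_nodes=max_nodes):
        if len(clique) < 2:
            continue
        weight = math.factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += weight
    return pd.DataFrame(
        {
            "gene": list(mcc),
            "mcc": [mcc[v] for v in mcc],
            "degree": [graph.degree(v) for v in mcc],
        }
    )


@dataclass
class HubRanking:
    """Top genes by MCC plus the short candidate list drawn from them."""

    top: pd.DataFrame           # ordered (gene, mcc, degree)
    candidates: list[str]       # first n_candidates genes of the ordering

    @property
    def top_genes(self) -> list[str]:
        return self.top["gene"].tolist()


def rank_hubs(scores: pd.DataFrame, top_k: int = 30, n_candidates: int = 5) -> HubRanking:
    """Order genes by MCC descending (ties: degree descending, then gene id)
    and cut the top_k list plus the first n_candidates hub candidates."""
    ordered = scores.sort_values(
        ["mcc", "degree", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    if top_k > len(ordered):
        logger.warning("top_k=%d exceeds %d scored genes: returning all", top_k, len(ordered))
    top = ordered.head(top_k).reset_index(drop=True)
    return HubRanking(top=top, candidates=top["gene"].head(n_candidates).tolist())


def mirna_hub_links(top_genes, target_map: TargetMap) -> dict[str, int]:
    """Per selected miRNA, how many of its targets fall in the top gene set."""
    top = set(top_genes)
    return {m: len(genes & top) for m, genes in target_map.per_mirna.items()}


# ---------------------------------------------------------------------------
# Cytoscape-interoperable exports


def write_sif(graph: nx.Graph, path, relation: str = "pp") -> None:
    """Simple interaction format: one ``node relation node`` line per edge,
    isolated nodes on their own line."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted((str(a), str(b)))) for a, b in graph.edges):
            fh.write(f"{u}\t{relation}\t{v}\n")
        for v in sorted(str(n) for n in nx.isolates(graph)):
            fh.write(f"{v}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
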