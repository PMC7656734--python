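"""miRNA target mapping and zero-order PPI sub-network / hub-gene analysis.

Target genes with prediction score strictly above 90 are mapped from the
model's miRNAs; the zero-order network keeps only direct interactions (edges
with confidence at or above 900 whose endpoints are both seed genes); hub
genes are nodes of degree >= 5, reported with a flag saying whether every hub
pair is itself directly connected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .exceptions import InputError

log = logging.getLogger(__name__)


@dataclass
class SubNetwork:
    """Edge-induced zero-order network."""

    graph: nx.Graph

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def degrees(self) -> dict:
        return dict(self.graph.degree)


def _check_target_table(table: pd.DataFrame) -> None:
    for col in ("mirna", "gene", "score"):
        if col not in table.columns:
            raise InputError(f"target table lacks column {col!r}")
    if ((table["score"] < 0) | (table["score"] > 100)).any():
        raise InputError("target scores must lie in [0, 100]")


def map_targets(
    mirnas, table: pd.DataFrame, min_score: float = 90.0
) -> set[str]:
    """Union over the queried miRNAs of genes with score > min_score (strict)."""
    _check_target_table(table)
    genes: set[str] = set()
    for mir in mirnas:
        rows = table[table["mirna"] == mir]
        if rows.empty:
            log.info("miRNA %s has no target-table rows", mir)
            continue
        genes.update(rows.loc[rows["score"] > min_score, "gene"])
    return genes


def zero_order_subnetwork(
    seeds, interactome: pd.DataFrame, min_conf: float = 900.0
) -> SubNetwork:
    """Direct interactions only: edges with confidence >= min_conf (inclusive)
    between two seed genes. Isolated seeds are dropped (edge-induced)."""
    for col in ("gene_a", "gene_b", "confidence"):
        if col not in interactome.columns:
            raise InputError(f"interactome lacks column {col!r}")
    seeds = set(seeds)
    kept = interactome[
        (interactome["confidence"] >= min_conf)
        & interactome["gene_a"].isin(seeds)
        & interactome["gene_b"].isin(seeds)
        & (interactome["gene_a"] != interactome["gene_b"])
    ]
    graph = nx.Graph()
    graph.add_weighted_edges_from(
        kept[["gene_a", "gene_b", "confidence"]].itertuples(index=False),
        weight="confidence",
    )
    return SubNetwork(graph=graph)


def find_hubs(net: SubNetwork, min_degree: int = 5) -> tuple[list[str], bool]:
    """Nodes of degree >= min_degree, sorted by descending degree then name,
    plus a flag: True iff every hub pair is directly connected."""
    deg = net.degrees
    hubs = sorted(
        (g for g, d in deg.items() if d >= min_degree),
        key=lambda g: (-deg[g], g),
    )
    adjacent = all(
        net.graph.has_edge(a, b)
        for i, a in enumerate(hubs)
        for b in hubs[i + 1:]
    )
    return hubs, adjacent


# ---------------------------------------------------------------------------
# file I/O


def read_target_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    _check_target_table(table)
    return table


def read_interactome(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_subnetwork(net: SubNetwork, edge_path, graphml_path=None) -> None:
    rows = [
        (a, b, d.get("confidence", ""))
        for a, b, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"]).to_csv(
        edge_path, sep="\t", index=False
    )
    if graphml_path is not None:
        nx.write_graphml(net.graph, graphml_path)
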