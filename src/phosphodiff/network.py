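"""PPI network assembly and hub ranking.

Builds the induced subgraph of a protein-protein interaction edge list on the
union of the pipeline's node sets (DEPs, DPhospho parents, kinases,
phosphatases, TFs, seeds), tags each node with its roles, and ranks nodes by
degree. Edges are undirected and unweighted; an optional confidence-score
floor filters the edge list but scores never weight the degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .model import ValidationError

ROLES = ("DEP", "DPhospho", "kinase", "phosphatase", "TF", "seed")


@dataclass
class AnnotatedNetwork:
    graph: nx.Graph  # node attribute "roles": sorted tuple of role tags

    @property
    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def node_table(self) -> pd.DataFrame:
        rows = [{"node": n, "degree": d, "roles": ",".join(self.graph.nodes[n]["roles"])}
                for n, d in sorted(self.graph.degree())]
        return pd.DataFrame(rows, columns=["node", "degree", "roles"])

    def edge_table(self) -> pd.DataFrame:
        edges = sorted(tuple(sorted(e)) for e in self.graph.edges())
        return pd.DataFrame(edges, columns=["node_a", "node_b"])


def build_network(
    ppi_edges: list[tuple[str, str]] | pd.DataFrame,
    node_sets: dict[str, set[str]],
    min_score: float | None = None,
) -> AnnotatedNetwork:
    """Induced undirected subgraph on the union of the role node sets.

    Self-loops are discarded and duplicate/reversed edges collapse to one.
    Nodes named in any role set but without surviving edges are retained with
    degree zero. Roles may overlap (a node can be both DEP and kinase).
    """
    unknown = set(node_sets) - set(ROLES)
    if unknown:
        raise ValidationError(f"unknown role(s): {', '.join(sorted(unknown))}")
    members = set().union(*node_sets.values()) if node_sets else set()
    if not members:
        raise ValidationError("union of node sets is empty")

    if isinstance(ppi_edges, pd.DataFrame):
        df = ppi_edges
        if min_score is not None and "score" in df.columns:
            df = df.loc[pd.to_numeric(df["score"]) >= min_score]
        edge_iter = zip(df["node_a"], df["node_b"])
    else:
        edge_iter = iter(ppi_edges)

    g = nx.Graph()
    g.add_nodes_from(members)
    for a, b in edge_iter:
        if a == b:
            continue
        if a in members and b in members:
            g.add_edge(a, b)
    for n in g.nodes:
        roles = tuple(sorted(role for role, ids in node_sets.items() if n in ids))
        g.nodes[n]["roles"] = roles
    return AnnotatedNetwork(graph=g)


def rank_hubs(net: AnnotatedNetwork, top_n: int | None = None) -> pd.DataFrame:
    """Nodes by descending degree, ties broken lexicographically."""
    if net.graph.number_of_nodes() == 0:
        raise ValidationError("empty network")
    ranked = sorted(net.graph.degree(), key=lambda nd: (-nd[1], nd[0]))
    if top_n is not None:
        ranked = ranked[: max(top_n, 0)]
    return pd.DataFrame(
        [{"node": n, "degree": d, "roles": ",".join(net.graph.nodes[n]["roles"])}
         for n, d in ranked],
        columns=["node", "degree", "roles"],
    )
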