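"""Complex-level genetic-interaction network construction and export.

Each node is a protein complex; each edge summarizes one between-complex
cluster with its signed count purity (beta), interaction count, mean
epsilon and dominant sign.  Layout and rendering are out of scope — the
exporters store attributes only.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx

from .clusters import ClusterSet
from .scores import PopulationScore

GRAPH_FORMATS = ("sif", "graphml", "json-graph")


def build_complex_graph(between: ClusterSet, scores: PopulationScore,
                        only_highly_monochromatic: bool = False,
                        subsystem_of: dict | None = None) -> nx.Graph:
    """Build the complex graph from between-complex clusters and their scores.

    With ``only_highly_monochromatic`` on, only clusters whose |beta|
    strictly exceeds the population MCI become edges.  ``subsystem_of``
    optionally labels nodes with a subsystem/module name.
    """
    score_by_id = {s.cluster_id: s for s in scores.per_cluster}
    graph = nx.Graph()
    for cluster in between:
        s = score_by_id.get(cluster.id)
        if s is None:
            raise ValueError(f"no score for cluster {cluster.id}")
        if only_highly_monochromatic and not abs(s.beta) > scores.mci:
            continue
        x, y = cluster.complexes
        for node in (x, y):
            if node not in graph:
                label = (subsystem_of or {}).get(node, "")
                graph.add_node(node, subsystem=str(label))
        graph.add_edge(x, y, beta=float(s.beta),
                       beta_strength=float(s.beta_strength),
                       n_total=int(cluster.n_total),
                       mean_epsilon=float(cluster.epsilons.mean()),
                       sign="pos" if s.beta >= 0 else "neg")
    return graph


def write_graph(graph: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Serialize to SIF (``a pos|neg b`` lines), GraphML or json-graph."""
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            for a, b, data in graph.edges(data=True):
                fh.write(f"{a}\t{data.get('sign', 'pos')}\t{b}\n")
            for node in nx.isolates(graph):
                fh.write(f"{node}\n")
    elif format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "json-graph":
        with open(path, "w") as fh:
            json.dump(nx.node_link_data(graph, edges="links"), fh, indent=2)
    else:
        raise ValueError(f"unknown graph format: {format!r}")


def read_graph(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a serialized complex graph (round-trip partner of write_graph)."""
    path = Path(path)
    if format == "sif":
        graph = nx.Graph()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 3:
                    graph.add_edge(parts[0], parts[2], sign=parts[1])
                elif parts[0]:
                    graph.add_node(parts[0])
        return graph
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "json-graph":
        with open(path) as fh:
            return nx.node_link_graph(json.load(fh), edges="links")
    raise ValueError(f"unknown graph format: {format!r}")
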