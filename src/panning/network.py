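"""Paradigmatic covariate network built from the filtered model set.

Every covariate appearing in the final set S*0 becomes a node whose
frequency is the number of retained models containing it; every pair of
covariates sharing a model becomes an edge weighted by the co-membership
count.  The most frequent covariates are the "hubs" — anchor covariates
around which the retained models organise — and each node carries a
position label recording the hub level at which it entered the network
(1 for the hubs themselves, 2 for their direct partners, and so on).
Covariates at the same position form families of interchangeable markers:
swapping one member for another yields a retained model of comparable
predictive power.

Hub levels are assigned greedily: level 1 holds every covariate tying the
maximum frequency (ties are all hubs at once); level k <= d* holds the
yet-unlabelled partners of level k-1, among which the most frequent are
flagged as further hubs when they are shared by at least two models.
Components not reachable from any hub restart the same scheme locally
without the hub flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import networkx as nx

from .risk import CandidateModel

__all__ = ["NetworkNode", "GeneNetwork", "build_network", "export_network", "parse_network"]


class NetworkFormatError(ValueError):
    """Unknown or malformed network serialization format."""


@dataclass(frozen=True)
class NetworkNode:
    id: str
    frequency: int
    hub: bool
    position: int


@dataclass
class GeneNetwork:
    """Nodes with frequencies/hub flags/positions and weighted co-occurrence
    edges over the filtered model set."""

    nodes: List[NetworkNode]
    edges: List[Tuple[str, str, int]]
    d_star: int

    def node_map(self) -> Dict[str, NetworkNode]:
        return {node.id: node for node in self.nodes}

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node.id, frequency=node.frequency, hub=node.hub,
                       position=node.position)
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w)
        return g


def build_network(
    filtered_models: Sequence[CandidateModel],
    feature_ids: Sequence[str] = None,
) -> GeneNetwork:
    """Count node frequencies and co-occurrence edges over the (deduplicated)
    filtered models and assign hub levels.  Invariant to model order."""
    if not filtered_models:
        raise ValueError("cannot build a network from an empty model set")
    unique = {}
    for m in filtered_models:
        unique.setdefault(m.indices, m)
    models = list(unique.values())
    dims = {m.d for m in models}
    if len(dims) != 1:
        raise ValueError("filtered models must all have the same dimension")
    d_star = dims.pop()

    def label(i: int) -> str:
        return str(feature_ids[i]) if feature_ids is not None else str(i + 1)

    freq: Dict[int, int] = {}
    edge_count: Dict[Tuple[int, int], int] = {}
    neighbors: Dict[int, set] = {}
    for m in models:
        for i in m.indices:
            freq[i] = freq.get(i, 0) + 1
            neighbors.setdefault(i, set())
        for a_pos in range(len(m.indices)):
            for b_pos in range(a_pos + 1, len(m.indices)):
                a, b = m.indices[a_pos], m.indices[b_pos]
                edge_count[(a, b)] = edge_count.get((a, b), 0) + 1
                neighbors[a].add(b)
                neighbors[b].add(a)

    position: Dict[int, int] = {}
    hub: Dict[int, bool] = {i: False for i in freq}

    def expand(seed_pool: Iterable[int], flag_hubs: bool) -> None:
        pool = [i for i in seed_pool if i not in position]
        if not pool:
            return
        top = max(freq[i] for i in pool)
        level_nodes = [i for i in pool if freq[i] == top]
        for i in level_nodes:
            position[i] = 1
            hub[i] = flag_hubs
        level = 1
        frontier = level_nodes
        while frontier and level < d_star:
            level += 1
            partners = sorted(
                {j for i in frontier for j in neighbors[i] if j not in position}
            )
            if not partners:
                break
            top = max(freq[j] for j in partners)
            for j in partners:
                position[j] = level
                # deeper hub levels require genuinely shared covariates
                hub[j] = flag_hubs and freq[j] == top and freq[j] >= 2
            frontier = partners

    expand(freq.keys(), flag_hubs=True)
    while len(position) < len(freq):
        expand([i for i in freq if i not in position], flag_hubs=False)

    nodes = [
        NetworkNode(id=label(i), frequency=freq[i], hub=hub[i], position=position[i])
        for i in sorted(freq)
    ]
    edges = [
        (label(a), label(b), w) for (a, b), w in sorted(edge_count.items())
    ]
    return GeneNetwork(nodes=nodes, edges=edges, d_star=d_star)


def export_network(net: GeneNetwork, format: str = "edge_list") -> str:
    """Serialize the network as ``edge_list`` (TSV), ``graphml`` or ``json``."""
    if format == "edge_list":
        lines = ["source\ttarget\tweight"]
        lines += [f"{u}\t{v}\t{w}" for u, v, w in net.edges]
        return "\n".join(lines) + "\n"
    if format == "graphml":
        return "\n".join(nx.generate_graphml(net.to_graph()))
    if format == "json":
        payload = {
            "d_star": net.d_star,
            "nodes": [
                {"id": n.id, "frequency": n.frequency, "hub": n.hub,
                 "position": n.position}
                for n in net.nodes
            ],
            "edges": [{"source": u, "target": v, "weight": w} for u, v, w in net.edges],
        }
        return json.dumps(payload, indent=2)
    raise NetworkFormatError(f"unknown network format {format!r}")


def parse_network(text: str, format: str = "json") -> GeneNetwork:
    """Inverse of :func:`export_network` for the ``json`` and ``edge_list``
    formats (edge lists carry no node attributes; frequencies are dropped)."""
    if format == "json":
        payload = json.loads(text)
        nodes = [
            NetworkNode(id=n["id"], frequency=n["frequency"], hub=n["hub"],
                        position=n["position"])
            for n in payload["nodes"]
        ]
        edges = [(e["source"], e["target"], e["weight"]) for e in payload["edges"]]
        return GeneNetwork(nodes=nodes, edges=edges, d_star=payload["d_star"])
    if format == "edge_list":
        lines = [ln for ln in text.strip().splitlines()[1:] if ln]
        edges = []
        seen = []
        for ln in lines:
            u, v, w = ln.split("\t")
            edges.append((u, v, int(w)))
            for x in (u, v):
                if x not in seen:
                    seen.append(x)
        nodes = [NetworkNode(id=x, frequency=0, hub=False, position=0) for x in seen]
        return GeneNetwork(nodes=nodes, edges=edges, d_star=0)
    raise NetworkFormatError(f"unknown network format {format!r}")
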