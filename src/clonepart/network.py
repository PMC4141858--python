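"""Minimum spanning networks over integer genetic distance matrices.

A minimum spanning network is a minimum spanning tree plus the equal-weight
*alternative* edges that belong to some other MST — the reticulations that
display ambiguity among equally short mutational paths.  Construction is
Kruskal-style: edges are scanned in non-decreasing weight order; within each
weight class, every edge that joins two components still separate at the
start of the class belongs to some MST, the first such edge (in id order)
per merge becomes a tree edge and the rest are flagged alternative.  Edge
lengths are mutation steps (allele differences or nucleotide substitutions);
``expand_step_nodes`` inserts inferred intermediate nodes so every rendered
edge spans exactly one step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .clonal import DistanceMatrix


@dataclass(frozen=True)
class Edge:
    u: str
    v: str
    length: int
    is_alternative: bool = False


@dataclass
class SpanningNetwork:
    """Nodes, edges, and per-node annotations of a spanning network."""

    nodes: list[str]
    edges: list[Edge]
    node_attrs: dict = field(default_factory=dict)  # node -> {attr: value}
    inferred: set = field(default_factory=set)  # step nodes added by expansion

    @property
    def tree_edges(self) -> list[Edge]:
        return [e for e in self.edges if not e.is_alternative]

    @property
    def alternative_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.is_alternative]

    @property
    def tree_weight(self) -> int:
        return sum(e.length for e in self.tree_edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(
                n, inferred=n in self.inferred, **self.node_attrs.get(n, {})
            )
        for e in self.edges:
            g.add_edge(e.u, e.v, length=e.length, alternative=e.is_alternative)
        return g


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        self.parent[self.find(x)] = self.find(y)


def build_msn(matrix: DistanceMatrix | np.ndarray, ids=None) -> SpanningNetwork:
    """Build the minimum spanning network of an integer distance matrix.

    The non-alternative edges form an MST (deterministic under id-ordered
    tie-breaking); alternative edges are exactly the remaining tie-weight
    edges that occur in some other MST.
    """
    if isinstance(matrix, DistanceMatrix):
        ids = list(matrix.ids)
        d = matrix.d
    else:
        d = np.asarray(matrix)
        if ids is None:
            ids = [str(i) for i in range(d.shape[0])]
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two nodes")
    pos = {name: i for i, name in enumerate(ids)}
    all_edges = [
        (int(d[i, j]), ids[i], ids[j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
    all_edges.sort(key=lambda e: (e[0], pos[e[1]], pos[e[2]]))

    uf = _UnionFind(ids)
    edges: list[Edge] = []
    k = 0
    while k < len(all_edges):
        w = all_edges[k][0]
        group = []
        while k < len(all_edges) and all_edges[k][0] == w:
            group.append(all_edges[k])
            k += 1
        # components before any edge of this weight class is applied:
        # an edge of weight w is in some MST iff it crosses them.
        before = {x: uf.find(x) for x in ids}
        for _, u, v in group:
            if before[u] == before[v]:
                continue  # in no MST at this weight
            if uf.find(u) != uf.find(v):
                uf.union(u, v)
                edges.append(Edge(u, v, w, is_alternative=False))
            else:
                edges.append(Edge(u, v, w, is_alternative=True))
    return SpanningNetwork(nodes=list(ids), edges=edges)


def expand_step_nodes(network: SpanningNetwork) -> SpanningNetwork:
    """Replace every edge of length k > 1 by k unit edges through k - 1
    inferred step nodes.  Observed nodes are unchanged; idempotent on
    all-unit networks."""
    nodes = list(network.nodes)
    inferred = set(network.inferred)
    edges: list[Edge] = []
    for e in network.edges:
        if e.length <= 1:
            edges.append(e)
            continue
        chain = [e.u]
        for s in range(1, e.length):
            step = f"step:{e.u}|{e.v}|{s}"
            chain.append(step)
            nodes.append(step)
            inferred.add(step)
        chain.append(e.v)
        for a, b in zip(chain[:-1], chain[1:]):
            edges.append(Edge(a, b, 1, is_alternative=e.is_alternative))
    return SpanningNetwork(
        nodes=nodes,
        edges=edges,
        node_attrs=dict(network.node_attrs),
        inferred=inferred,
    )


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

FORMATS = ("edge_list", "graphml", "dot")


def export_network(network: SpanningNetwork, path, format: str = "edge_list") -> None:
    """Write the network losslessly (nodes, lengths, alternative flags,
    node annotations as attributes)."""
    if format == "edge_list":
        with open(path, "w") as fh:
            fh.write("u\tv\tlength\talternative\n")
            for e in network.edges:
                fh.write(f"{e.u}\t{e.v}\t{e.length}\t{int(e.is_alternative)}\n")
            for n in network.nodes:  # keep isolated/annotation-only nodes
                fh.write(f"#node\t{n}\t{int(n in network.inferred)}\n")
    elif format == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    elif format == "dot":
        with open(path, "w") as fh:
            fh.write("graph msn {\n")
            for n in network.nodes:
                attrs = network.node_attrs.get(n, {})
                extra = "".join(f' {k}="{v}"' for k, v in attrs.items())
                fh.write(f'  "{n}" [inferred={int(n in network.inferred)}{extra}];\n')
            for e in network.edges:
                style = ' style="dashed"' if e.is_alternative else ""
                fh.write(f'  "{e.u}" -- "{e.v}" [label={e.length}{style}];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_edge_list(path) -> SpanningNetwork:
    """Parse back a network written with ``format='edge_list'``."""
    edges: list[Edge] = []
    nodes: list[str] = []
    inferred: set = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("u\tv"):
            raise ValueError("not an edge-list file")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#node":
                nodes.append(parts[1])
                if int(parts[2]):
                    inferred.add(parts[1])
            else:
                u, v, length, alt = parts
                edges.append(Edge(u, v, int(length), bool(int(alt))))
    return SpanningNetwork(nodes=nodes, edges=edges, inferred=inferred)
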