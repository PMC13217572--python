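"""Spectral decomposition of large König graphs into modules.

Genome-scale networks have far too many elementary circuits for exhaustive
enumeration, but their König graphs are sparse and modular.  The network is
therefore recursively bisected with Newman's leading-eigenvector method on
the modularity matrix of the undirected shadow (antiparallel edges merged),
circuits are enumerated exhaustively inside the resulting modules, and
circuits crossing module borders are enumerated with a separate (typically
tighter) length cap while merging sibling modules bottom-up along the
partition tree.  Every circuit is attributed to the lowest tree node whose
vertex set contains it, so the union is duplicate-free, and with both caps
at the component size the result equals plain global enumeration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .circuits import Circuit, CircuitIndex, iter_elementary_circuits
from .konig import KonigGraph, SubgraphHandle, Vertex, as_handle, vertex_id, vertex_kind

logger = logging.getLogger("autocatnet")

__all__ = ["PartitionNode", "PartitionTree", "partition_network", "modular_circuit_enumeration"]

#: eigenvalue / modularity-gain threshold below which a split is rejected
_SPECTRAL_TOL = 1e-10


@dataclass
class PartitionNode:
    """A node of the partition hierarchy; leaves are the modules."""

    vertices: tuple[Vertex, ...]
    children: list["PartitionNode"] = field(default_factory=list)
    parent: "PartitionNode | None" = field(default=None, repr=False, compare=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PartitionTree:
    root: PartitionNode

    def leaves(self) -> list[PartitionNode]:
        out: list[PartitionNode] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend(reversed(n.children))
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        def node_dict(n: PartitionNode) -> dict:
            return {
                "vertices": [f"{vertex_kind(v)}:{vertex_id(v)}" for v in n.vertices],
                "children": [node_dict(c) for c in n.children],
            }

        text = json.dumps(node_dict(self.root), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _undirected_shadow(h: SubgraphHandle) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(sorted(h.vertexset))
    for u, v in sorted(h.e1 | h.e2):
        g.add_edge(u, v)
    return g


def _leading_split(shadow: nx.Graph, nodes: list[Vertex]) -> tuple[list[Vertex], list[Vertex], float] | None:
    """One Newman leading-eigenvector bisection of a vertex group.

    Uses the generalized modularity matrix for subgraph splitting (the group
    row sums are subtracted on the diagonal so that not splitting scores
    zero).  Returns (part1, part2, gain) or None when no positive-gain split
    exists.  The eigenvector sign is fixed so that its first nonzero entry
    is positive, making the output deterministic.
    """
    n = len(nodes)
    m_edges = shadow.number_of_edges()
    if n < 2 or m_edges == 0:
        return None
    index = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for u, v in shadow.edges():
        if u in index and v in index:
            a[index[u], index[v]] = 1.0
            a[index[v], index[u]] = 1.0
    deg = np.array([shadow.degree(v) for v in nodes], dtype=float)
    b = a - np.outer(deg, deg) / (2.0 * m_edges)
    bg = b - np.diag(b.sum(axis=1))
    vals, vecs = np.linalg.eigh(bg)
    lam = float(vals[-1])
    if lam <= _SPECTRAL_TOL:
        return None
    vec = vecs[:, -1]
    nz = np.nonzero(np.abs(vec) > 1e-12)[0]
    if nz.size and vec[nz[0]] < 0:
        vec = -vec
    s = np.where(vec >= 0, 1.0, -1.0)
    gain = float(s @ bg @ s) / (4.0 * m_edges)
    part1 = [v for v, si in zip(nodes, s) if si > 0]
    part2 = [v for v, si in zip(nodes, s) if si < 0]
    if not part1 or not part2 or gain <= _SPECTRAL_TOL:
        return None
    return part1, part2, gain


def partition_network(g: KonigGraph | SubgraphHandle, max_module: int) -> PartitionTree:
    """Recursively bisect a (weakly connected) subgraph into modules.

    Recursion stops when a group has at most ``max_module`` vertices or when
    no split with positive modularity gain exists (non-positive leading
    eigenvalue of the generalized modularity matrix).
    """
    if max_module < 2:
        raise ValueError("max_module must be >= 2")
    h = as_handle(g)
    shadow = _undirected_shadow(h)

    def build(nodes: list[Vertex], parent: PartitionNode | None) -> PartitionNode:
        node = PartitionNode(vertices=tuple(sorted(nodes)), parent=parent)
        if len(nodes) <= max_module:
            return node
        split = _leading_split(shadow, sorted(nodes))
        if split is None:
            return node
        part1, part2, gain = split
        logger.debug("split %d -> %d + %d (gain %.4g)", len(nodes), len(part1), len(part2), gain)
        node.children = [build(part1, node), build(part2, node)]
        return node

    return PartitionTree(root=build(sorted(h.vertexset), None))


def modular_circuit_enumeration(
    g: KonigGraph | SubgraphHandle,
    tree: PartitionTree,
    max_len_intra: int,
    max_len_cross: int,
) -> CircuitIndex:
    """Two-stage circuit enumeration over a partition tree.

    Leaves are enumerated exhaustively up to ``max_len_intra`` vertices;
    then, ascending the tree, each internal node enumerates circuits up to
    ``max_len_cross`` vertices within its merged vertex set, keeping only
    those not confined to a single child (i.e. circuits that use at least
    one cut edge between sibling modules).
    """
    h = as_handle(g)
    parent = h.parent
    collected: dict[tuple[Vertex, ...], Circuit] = {}

    def visit(node: PartitionNode) -> None:
        if node.is_leaf:
            sub = parent.subgraph(set(node.vertices) & h.vertexset, induced=True)
            for c in iter_elementary_circuits(sub, max_len=max_len_intra):
                collected.setdefault(c.vertices, c)
            return
        for child in node.children:
            visit(child)
        child_sets = [frozenset(c.vertices) for c in node.children]
        sub = parent.subgraph(set(node.vertices) & h.vertexset, induced=True)
        for c in iter_elementary_circuits(sub, max_len=max_len_cross):
            if any(c.vertexset <= cs for cs in child_sets):
                continue  # counted at a lower node
            collected.setdefault(c.vertices, c)

    visit(tree.root)
    idx = CircuitIndex()
    for key in sorted(collected, key=lambda vs: (len(vs), vs)):
        idx.add(collected[key])
    return idx
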