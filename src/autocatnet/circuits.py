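"""Elementary circuit enumeration on the König graph.

Elementary circuits (simple directed cycles) of the bipartite graph
alternate between species and reaction vertices, so their length (vertex
count) is even and they use exactly ``length/2`` reactant-to-reaction (E1)
edges.  Every elementary circuit is a fluffle, and circuits are the building
blocks from which all larger fluffles are assembled.

Enumeration delegates to Johnson-style blocked search (networkx
``simple_cycles``, with the bounded-length variant when a cap is given) and
is exposed lazily as a generator so that the direct core-enumeration mode
can filter Metzler circuits without materializing everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx

from .konig import (
    Edge,
    KonigGraph,
    SubgraphHandle,
    Vertex,
    SPECIES,
    as_handle,
    vertex_kind,
)

__all__ = [
    "Circuit",
    "CircuitIndex",
    "iter_elementary_circuits",
    "enumerate_elementary_circuits",
    "is_metzler_circuit",
    "circuit_representatives",
]


def _canonical_rotation(nodes: Sequence[Vertex]) -> tuple[Vertex, ...]:
    """Rotate a cyclic vertex sequence to start at its smallest vertex."""
    i = min(range(len(nodes)), key=nodes.__getitem__)
    return tuple(nodes[i:]) + tuple(nodes[:i])


@dataclass(frozen=True)
class Circuit:
    """An elementary circuit, stored in canonical rotation."""

    vertices: tuple[Vertex, ...]

    def __post_init__(self):
        object.__setattr__(self, "vertices", _canonical_rotation(self.vertices))

    @property
    def length(self) -> int:
        return len(self.vertices)

    @property
    def edges(self) -> tuple[tuple[Vertex, Vertex], ...]:
        vs = self.vertices
        return tuple((vs[i], vs[(i + 1) % len(vs)]) for i in range(len(vs)))

    @property
    def e1edges(self) -> frozenset[Edge]:
        """The reactant-to-reaction edges: the child-selection data."""
        return frozenset((u, v) for u, v in self.edges if vertex_kind(u) == SPECIES)

    @property
    def vertexset(self) -> frozenset[Vertex]:
        return frozenset(self.vertices)

    def key(self) -> frozenset[Edge]:
        return self.e1edges


@dataclass
class CircuitIndex:
    """Circuits plus a map from each E1 edge to the circuits containing it."""

    circuits: list[Circuit] = field(default_factory=list)
    byedge: dict[Edge, set[int]] = field(default_factory=dict)

    def add(self, c: Circuit) -> None:
        idx = len(self.circuits)
        self.circuits.append(c)
        for e in c.e1edges:
            self.byedge.setdefault(e, set()).add(idx)

    def __len__(self) -> int:
        return len(self.circuits)

    def circuits_sharing(self, edges: Iterable[Edge]) -> list[Circuit]:
        hits: set[int] = set()
        for e in edges:
            hits |= self.byedge.get(e, set())
        return [self.circuits[i] for i in sorted(hits)]


def iter_elementary_circuits(
    g: KonigGraph | SubgraphHandle, max_len: int | None = None
) -> Iterator[Circuit]:
    """Lazily yield the distinct elementary circuits with vertex count
    <= ``max_len`` (unlimited when None), one per rotation class.

    The underlying search handles arbitrary digraphs via per-SCC restarts;
    output order is deterministic for a fixed input.
    """
    if max_len is not None and max_len < 2:
        raise ValueError("max_len must be >= 2")
    h = as_handle(g)
    nxg = h.to_nx()
    for cyc in nx.simple_cycles(nxg, length_bound=max_len):
        yield Circuit(tuple(cyc))


def enumerate_elementary_circuits(
    g: KonigGraph | SubgraphHandle, max_len: int | None = None
) -> CircuitIndex:
    """Materialize :func:`iter_elementary_circuits` into a sorted index."""
    circuits = sorted(iter_elementary_circuits(g, max_len), key=lambda c: (c.length, c.vertices))
    idx = CircuitIndex()
    for c in circuits:
        idx.add(c)
    return idx


def is_metzler_circuit(c: Circuit, g: KonigGraph | SubgraphHandle) -> bool:
    """True iff no reactant-to-reaction edge of the host graph is a chord.

    A chord here is an E1 edge of K connecting two non-consecutive circuit
    vertices; reaction-to-product (E2) chords do not disqualify.  Metzler
    circuits have Metzler CS matrices and are the only circuits that can
    participate in autocatalytic cores.
    """
    h = as_handle(g)
    vs = c.vertexset
    own = c.e1edges
    for u, v in h.e1:
        if u in vs and v in vs and (u, v) not in own:
            return False
    return True


def circuit_representatives(idx: CircuitIndex) -> list[Circuit]:
    """One circuit per CS-equivalence class of single circuits.

    Two circuits are CS-equivalent iff they share the same E1 edge set (the
    vertex set is implied, as every circuit vertex is incident to an E1
    edge).  Ties are broken by canonical rotation order, so the output is
    deterministic.
    """
    seen: dict[tuple[frozenset[Vertex], frozenset[Edge]], Circuit] = {}
    for c in sorted(idx.circuits, key=lambda c: (c.length, c.vertices)):
        k = (c.vertexset, c.e1edges)
        if k not in seen:
            seen[k] = c
    return list(seen.values())
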