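"""Assembly of CS-equivalence classes of fluffles from elementary circuits.

A *fluffle* is a directed bipartite subgraph with equally many species and
reaction vertices, species out-degree 1 and reaction in-degree 1, that is a
strong block (strongly connected with 2-connected undirected shadow).
Fluffles are exactly the graphs K(kappa) of child-selections whose CS matrix
has an irreducible Metzler part, so enumerating them enumerates all
candidate irreducible autocatalytic subnetworks.

Two fluffles are *CS-equivalent* iff they share the same set of
reactant-to-reaction (E1) edges; the E1 set is a perfect matching on the
fluffle's vertex set and fully determines the CS matrix.  Classes are
therefore keyed by their frozen E1 edge set alone; the vertex set is
implied.

Assembly proceeds breadth-first: a FIFO queue is seeded with the circuit
representatives, and each queued class is superimposed with every candidate
circuit sharing at least one E1 edge.  The union test is purely
edge/vertex-set based: ``G | C`` is a fluffle iff the vertex overlap is
nonempty and equals the vertices covered by the shared E1 edges.  Duplicate
classes are detected in expected constant time through a hash set of E1
keys.
"""

from __future__ import annotations

import itertools
import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .circuits import Circuit, CircuitIndex
from .crn import CRNError, ValidationError
from .konig import (
    Edge,
    KonigGraph,
    REACTION,
    SPECIES,
    SubgraphHandle,
    Vertex,
    as_handle,
    vertex_kind,
)

logger = logging.getLogger("autocatnet")

__all__ = [
    "GuardError",
    "FluffleClass",
    "union_is_fluffle",
    "canonical_representative",
    "is_fluffle_graph",
    "is_strong_block",
    "is_circuitnet",
    "assemble_classes",
    "count_fluffles",
]


class GuardError(CRNError):
    """Raised when an exponential enumeration is requested without opt-in."""


def _vertices_of(edges: Iterable[Edge]) -> frozenset[Vertex]:
    out: set[Vertex] = set()
    for u, v in edges:
        out.add(u)
        out.add(v)
    return frozenset(out)


@dataclass
class FluffleClass:
    """A CS-equivalence class of fluffles, keyed by its E1 edge set."""

    e1: frozenset[Edge]
    vertexset: frozenset[Vertex]
    predecessors: set[frozenset[Edge]] = field(default_factory=set)
    is_circuit: bool = False
    metzler: bool | None = None
    autocatalytic: bool | None = None
    core: bool | None = None
    reaction_set_minimal: bool | None = None

    @property
    def size(self) -> int:
        """Number of species (= number of reactions) in the class."""
        return len(self.e1)

    @property
    def key(self) -> frozenset[Edge]:
        return self.e1

    def sorted_key(self) -> tuple[Edge, ...]:
        return tuple(sorted(self.e1))


# ---------------------------------------------------------------------------
# Structural predicates
# ---------------------------------------------------------------------------

def is_strong_block(g: nx.DiGraph) -> bool:
    """Strongly connected and 2-connected (undirected shadow has no cut
    vertex)."""
    if g.number_of_nodes() < 2:
        return False
    return nx.is_strongly_connected(g) and nx.is_biconnected(g.to_undirected())


def is_fluffle_graph(g: nx.DiGraph) -> bool:
    """Independent validator of the three fluffle conditions.

    (i) bipartite with equally many species and reaction vertices,
    (ii) species out-degree 1 and reaction in-degree 1,
    (iii) strong block.
    """
    species = [v for v in g if vertex_kind(v) == SPECIES]
    reactions = [v for v in g if vertex_kind(v) == REACTION]
    if not species or len(species) != len(reactions):
        return False
    for u, v in g.edges():
        if vertex_kind(u) == vertex_kind(v):
            return False
    if any(g.out_degree(x) != 1 for x in species):
        return False
    if any(g.in_degree(r) != 1 for r in reactions):
        return False
    return is_strong_block(g)


def union_is_fluffle(
    e1: frozenset[Edge], vertexset: frozenset[Vertex], circuit: Circuit
) -> bool:
    """Decide whether the union of a fluffle (given by its E1 edges and
    vertex set) with an elementary circuit is again a fluffle.

    The criterion is purely set-based: the vertex overlap must be nonempty
    and every shared vertex must be covered by a shared E1 edge.
    """
    overlap = vertexset & circuit.vertexset
    if not overlap:
        return False
    shared = e1 & circuit.e1edges
    return overlap == _vertices_of(shared)


def is_circuitnet(circuits: Sequence[Circuit]) -> bool:
    """Decide whether a set of elementary circuits is a circuitnet, i.e.
    admits an ordering in which every partial union is a strong block.

    Exhaustive search over orderings with memoization on the set of circuits
    already merged; intended for small circuit sets (worked examples,
    validation), not for production enumeration.
    """
    n = len(circuits)
    if n == 0:
        return False
    edge_lists = [list(c.edges) for c in circuits]

    def union_graph(idxs: frozenset[int]) -> nx.DiGraph:
        g = nx.DiGraph()
        for i in sorted(idxs):
            g.add_edges_from(edge_lists[i])
        return g

    target = frozenset(range(n))
    dead: set[frozenset[int]] = set()

    def grow(used: frozenset[int]) -> bool:
        if used == target:
            return True
        if used in dead:
            return False
        for j in range(n):
            if j in used:
                continue
            nxt = used | {j}
            if is_strong_block(union_graph(nxt)) and grow(nxt):
                return True
        dead.add(used)
        return False

    return any(grow(frozenset({i})) for i in range(n))


# ---------------------------------------------------------------------------
# Canonical representatives
# ---------------------------------------------------------------------------

def _check_matching(e1: frozenset[Edge]) -> None:
    xs = [u for u, _ in e1]
    rs = [v for _, v in e1]
    if len(set(xs)) != len(xs) or len(set(rs)) != len(rs):
        raise ValidationError("E1 edge set is not a matching")
    for u, v in e1:
        if vertex_kind(u) != SPECIES or vertex_kind(v) != REACTION:
            raise ValidationError(f"not a reactant-to-reaction edge: ({u}, {v})")


def canonical_representative(
    e1: frozenset[Edge], g: KonigGraph | SubgraphHandle
) -> SubgraphHandle:
    """The canonical fluffle representative K(kappa) of a CS-equivalence
    class: the matching edges plus *all* reaction-to-product edges of the
    host graph among the matched vertices.

    The returned handle is flagged induced iff it equals the induced
    subgraph, i.e. iff no extra reactant-to-reaction edge of the host graph
    runs between matched vertices (equivalently, iff the CS matrix is
    Metzler).
    """
    _check_matching(e1)
    h = as_handle(g)
    verts = _vertices_of(e1)
    e2 = frozenset((r, x) for (r, x) in h.parent.E2 if r in verts and x in verts)
    extra_e1 = any(
        (u, v) not in e1 and u in verts and v in verts for (u, v) in h.parent.E1
    )
    return SubgraphHandle(
        vertexset=verts, e1=e1, e2=e2, induced=not extra_e1, parent=h.parent
    )


# ---------------------------------------------------------------------------
# Breadth-first assembly (FIFO superposition of circuits)
# ---------------------------------------------------------------------------

def assemble_classes(
    reps: Sequence[Circuit],
    g: KonigGraph | SubgraphHandle,
    size_cap: int | None = None,
) -> dict[frozenset[Edge], FluffleClass]:
    """Assemble one representative per CS-equivalence class of fluffles
    reachable by superimposing the given circuit representatives.

    ``size_cap`` bounds the number of species per class (None = unlimited).
    Predecessor links record, for each accepted union ``G' = G | C``, the
    expanded class G and the circuit class of C; they underestimate the full
    Hasse diagram but are sufficient for the containment shortcuts used in
    core identification.

    Returns an insertion-ordered mapping from E1 key to class record.
    """
    idx = CircuitIndex()
    classes: dict[frozenset[Edge], FluffleClass] = {}
    queue: deque[frozenset[Edge]] = deque()

    seeds = sorted(reps, key=lambda c: (c.length, c.vertices))
    for c in seeds:
        if size_cap is not None and len(c.e1edges) > size_cap:
            continue
        key = c.e1edges
        if key not in classes:
            classes[key] = FluffleClass(e1=key, vertexset=c.vertexset, is_circuit=True)
            queue.append(key)
        idx.add(c)

    while queue:
        key = queue.popleft()
        cls = classes[key]
        for c in idx.circuits_sharing(cls.e1):
            if not union_is_fluffle(cls.e1, cls.vertexset, c):
                continue
            new_e1 = cls.e1 | c.e1edges
            if new_e1 == cls.e1:
                continue
            if size_cap is not None and len(new_e1) > size_cap:
                continue
            preds = {p for p in (cls.e1, c.e1edges) if p < new_e1}
            existing = classes.get(new_e1)
            if existing is not None:
                existing.predecessors.update(preds)
            else:
                classes[new_e1] = FluffleClass(
                    e1=new_e1,
                    vertexset=cls.vertexset | c.vertexset,
                    predecessors=preds,
                )
                queue.append(new_e1)
    return classes


# ---------------------------------------------------------------------------
# Exhaustive fluffle counting (opt-in)
# ---------------------------------------------------------------------------

def count_fluffles(
    classes: Iterable[FluffleClass],
    g: KonigGraph | SubgraphHandle,
    opt_in: bool = False,
    size_threshold: int = 6,
) -> int:
    """Count the distinct fluffle *subgraphs* (vertex set plus full edge
    set) across the given CS-equivalence classes.

    Every member of a class shares the class's E1 matching; the members
    differ in which available reaction-to-product edges they retain while
    remaining a strong block, so the count per class enumerates subsets of
    the canonical representative's E2 edges.  This is exponential in the
    class size and refuses to run on classes larger than
    ``size_threshold`` species unless ``opt_in`` is set.
    """
    classes = list(classes)
    big = [c for c in classes if c.size > size_threshold]
    if big and not opt_in:
        raise GuardError(
            f"{len(big)} class(es) exceed size threshold {size_threshold}; "
            "pass opt_in=True to enumerate fluffles exhaustively"
        )
    total = 0
    for cls in classes:
        rep = canonical_representative(cls.e1, g)
        e2 = sorted(rep.e2)
        base = list(cls.e1)
        nodes = sorted(rep.vertexset)
        for k in range(len(e2) + 1):
            for subset in itertools.combinations(e2, k):
                gg = nx.DiGraph()
                gg.add_nodes_from(nodes)
                gg.add_edges_from(base)
                gg.add_edges_from(subset)
                if is_strong_block(gg):
                    total += 1
    return total
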