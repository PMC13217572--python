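"""Bipartite König graph representation of a CRN and its connectivity.

The König graph K(X, R) is a directed bipartite graph on the disjoint union
of species vertices X and reaction vertices R.  E1 holds the
reactant-to-reaction edges (x, r) with ``s-[x,r] > 0``; E2 the
reaction-to-product edges (r, x) with ``s+[x,r] > 0``.  Absence of explicit
catalysts means no digons: (x, r) in E1 excludes (r, x) in E2.

Vertices are represented as ``("S", species_id)`` / ``("R", reaction_id)``
tuples so the two namespaces can never collide and every vertex set has a
deterministic total order.

Stoichiometric coefficients are deliberately not stored on edges: the graph
encodes incidence only, and child-selection matrices are always rebuilt from
the CRN itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .crn import CRN, ValidationError

logger = logging.getLogger("autocatnet")

__all__ = [
    "SPECIES",
    "REACTION",
    "species_vertex",
    "reaction_vertex",
    "vertex_kind",
    "vertex_id",
    "KonigGraph",
    "SubgraphHandle",
    "build_konig",
    "strongly_connected_components",
    "filter_components",
    "write_edgelist_tsv",
    "write_graphml",
]

SPECIES = "S"
REACTION = "R"

Vertex = tuple[str, str]
Edge = tuple[Vertex, Vertex]


def species_vertex(sid: str) -> Vertex:
    return (SPECIES, sid)


def reaction_vertex(rid: str) -> Vertex:
    return (REACTION, rid)


def vertex_kind(v: Vertex) -> str:
    return v[0]


def vertex_id(v: Vertex) -> str:
    return v[1]


class KonigGraph:
    """Directed bipartite König graph of a preprocessed CRN."""

    def __init__(self, crn: CRN):
        crn.assert_no_catalysts()
        self.crn = crn
        g = nx.DiGraph()
        for s in crn.species:
            g.add_node(species_vertex(s.id), kind=SPECIES)
        for r in crn.reactions:
            g.add_node(reaction_vertex(r.id), kind=REACTION)
        e1: set[Edge] = set()
        e2: set[Edge] = set()
        for r in crn.reactions:
            rv = reaction_vertex(r.id)
            for x in r.reactants:
                e1.add((species_vertex(x), rv))
            for x in r.products:
                e2.add((rv, species_vertex(x)))
        for u, v in sorted(e1):
            g.add_edge(u, v, role="e1")
        for u, v in sorted(e2):
            g.add_edge(u, v, role="e2")
        # digons cannot arise after resolve_catalysts, but double-check
        for u, v in e1:
            if (v, u) in e2:
                raise ValidationError(f"digon between {u} and {v}: CRN not preprocessed")
        self.graph = g
        self.E1: frozenset[Edge] = frozenset(e1)
        self.E2: frozenset[Edge] = frozenset(e2)
        self.X: frozenset[Vertex] = frozenset(species_vertex(s.id) for s in crn.species)
        self.R: frozenset[Vertex] = frozenset(reaction_vertex(r.id) for r in crn.reactions)

    def full_handle(self) -> "SubgraphHandle":
        return SubgraphHandle(
            vertexset=frozenset(self.X | self.R),
            e1=self.E1,
            e2=self.E2,
            induced=True,
            parent=self,
        )

    def subgraph(self, vertices: Iterable[Vertex], induced: bool = True,
                 e1: Iterable[Edge] | None = None,
                 e2: Iterable[Edge] | None = None) -> "SubgraphHandle":
        vs = frozenset(vertices)
        unknown = vs - (self.X | self.R)
        if unknown:
            raise ValidationError(f"vertices not in graph: {sorted(unknown)[:3]}")
        if induced:
            e1s = frozenset((u, v) for (u, v) in self.E1 if u in vs and v in vs)
            e2s = frozenset((u, v) for (u, v) in self.E2 if u in vs and v in vs)
        else:
            e1s = frozenset(e1 or ())
            e2s = frozenset(e2 or ())
            for u, v in e1s | e2s:
                if u not in vs or v not in vs:
                    raise ValidationError(f"edge ({u}, {v}) leaves the vertex set")
        return SubgraphHandle(vertexset=vs, e1=e1s, e2=e2s, induced=induced, parent=self)


@dataclass(frozen=True)
class SubgraphHandle:
    """A (not necessarily induced) subgraph of a König graph."""

    vertexset: frozenset[Vertex]
    e1: frozenset[Edge]
    e2: frozenset[Edge]
    induced: bool
    parent: KonigGraph = field(compare=False, repr=False)

    @property
    def species(self) -> frozenset[Vertex]:
        return frozenset(v for v in self.vertexset if vertex_kind(v) == SPECIES)

    @property
    def reactions(self) -> frozenset[Vertex]:
        return frozenset(v for v in self.vertexset if vertex_kind(v) == REACTION)

    def to_nx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for v in sorted(self.vertexset):
            g.add_node(v, kind=vertex_kind(v))
        for u, v in sorted(self.e1):
            g.add_edge(u, v, role="e1")
        for u, v in sorted(self.e2):
            g.add_edge(u, v, role="e2")
        return g


def as_handle(g: KonigGraph | SubgraphHandle) -> SubgraphHandle:
    return g.full_handle() if isinstance(g, KonigGraph) else g


def build_konig(crn: CRN) -> KonigGraph:
    """Build the König graph of a preprocessed (catalyst-free) CRN."""
    return KonigGraph(crn)


def strongly_connected_components(g: KonigGraph | SubgraphHandle) -> list[SubgraphHandle]:
    """Partition into maximal strongly connected induced subgraphs.

    Components are returned in deterministic order, sorted by their smallest
    contained vertex.  Circuits never cross component borders, so all
    downstream enumeration can run per component.
    """
    h = as_handle(g)
    comps = [frozenset(c) for c in nx.strongly_connected_components(h.to_nx())]
    comps.sort(key=lambda c: min(c))
    return [h.parent.subgraph(c & h.vertexset, induced=True) for c in comps]


def filter_components(components: Sequence[SubgraphHandle], min_reactions: int) -> list[SubgraphHandle]:
    """Keep components with at least ``min_reactions`` reaction vertices."""
    if min_reactions < 0:
        raise ValueError("min_reactions must be >= 0")
    return [c for c in components if len(c.reactions) >= min_reactions]


def write_edgelist_tsv(g: KonigGraph | SubgraphHandle, path: str | Path) -> None:
    """Export as TSV: source, source_kind, target, target_kind, role."""
    h = as_handle(g)
    with open(path, "w") as fh:
        fh.write("source\tsource_kind\ttarget\ttarget_kind\trole\n")
        for role, edges in (("e1", h.e1), ("e2", h.e2)):
            for u, v in sorted(edges):
                fh.write(
                    f"{vertex_id(u)}\t{vertex_kind(u)}\t{vertex_id(v)}\t{vertex_kind(v)}\t{role}\n"
                )


def write_graphml(g: KonigGraph | SubgraphHandle, path: str | Path) -> None:
    """Export for inspection in standard graph tools."""
    h = as_handle(g)
    out = nx.DiGraph()
    for v in sorted(h.vertexset):
        out.add_node(f"{vertex_kind(v)}:{vertex_id(v)}", kind=vertex_kind(v))
    for role, edges in (("e1", h.e1), ("e2", h.e2)):
        for u, v in sorted(edges):
            out.add_edge(
                f"{vertex_kind(u)}:{vertex_id(u)}",
                f"{vertex_kind(v)}:{vertex_id(v)}",
                role=role,
            )
    nx.write_graphml(out, str(path))
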