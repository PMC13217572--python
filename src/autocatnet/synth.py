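"""Synthetic reaction networks and a brute-force autocatalysis oracle.

The generators produce small CRNs with known structure for testing: the
three-species Type V core motif, consumption rings, complete alternating
networks, and seeded random networks.  The oracle applies the autocatalysis
definitions literally — enumerate child-selections as matchings in the
reactant-to-reaction edge set, build each CS matrix, and test it with an LP
— independently of the graph pipeline, so that agreement between the two is
a genuine cross-check (in particular of the spectral shortcut used for
Metzler matrices, which the oracle never takes).
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from typing import Iterator, Mapping

import numpy as np
from scipy.optimize import linprog

from .crn import CRN, CRNError, Reaction, Species

__all__ = [
    "GenerationError",
    "make_typeV",
    "make_ring",
    "make_complete_alternating",
    "random_crn",
    "plant",
    "brute_force_autocat",
    "brute_force_fluffle_classes",
    "brute_force_cores",
    "brute_force_count_fluffles",
]

#: matching key type: frozenset of (species_id, reaction_id) pairs
MatchKey = frozenset[tuple[str, str]]


class GenerationError(CRNError):
    """Raised when requested generator constraints are unsatisfiable."""


# ---------------------------------------------------------------------------
# Deterministic motifs
# ---------------------------------------------------------------------------

def make_typeV() -> CRN:
    """The three-species Type V autocatalytic core motif.

    Reaction r_i consumes x_i and produces the other two species, all with
    unit coefficients, so the full child-selection matrix is
    [[-1, 1, 1], [1, -1, 1], [1, 1, -1]].
    """
    xs = ["x1", "x2", "x3"]
    reactions = []
    for i, x in enumerate(xs, start=1):
        others = {y: 1 for y in xs if y != x}
        reactions.append(Reaction(f"r{i}", {x: 1}, others))
    return CRN([Species(x) for x in xs], reactions)


def make_ring(n: int) -> CRN:
    """A consumption ring: r_i converts x_i into x_{i+1} (indices mod n).

    Its unique child-selection matrix is the circulant with -1 on the
    diagonal and +1 on the subdiagonal ring; the Perron root is 0, so the
    ring is never autocatalytic.
    """
    if n < 2:
        raise GenerationError("ring needs at least 2 species")
    xs = [f"x{i}" for i in range(1, n + 1)]
    reactions = [
        Reaction(f"r{i + 1}", {xs[i]: 1}, {xs[(i + 1) % n]: 1}) for i in range(n)
    ]
    return CRN([Species(x) for x in xs], reactions)


def make_complete_alternating(n: int) -> CRN:
    """n species, each with one reaction consuming it and producing every
    other species: the bipartite graph whose circuits are in bijection with
    the directed cycles of the complete digraph on n vertices."""
    if n < 2:
        raise GenerationError("need at least 2 species")
    xs = [f"x{i}" for i in range(1, n + 1)]
    reactions = [
        Reaction(f"r{i + 1}", {xs[i]: 1}, {y: 1 for y in xs if y != xs[i]})
        for i in range(n)
    ]
    return CRN([Species(x) for x in xs], reactions)


def plant(host: CRN, motif: CRN, tag: str = "h") -> CRN:
    """Embed a motif into a host network as a vertex-disjoint component.

    Host species/reaction ids are prefixed with ``tag_`` to guarantee
    disjointness, so the motif's edges appear verbatim in the output.
    """
    species = [Species(s.id, s.name, s.compartment) for s in motif.species]
    species += [Species(f"{tag}_{s.id}", s.name, s.compartment) for s in host.species]
    reactions = [r.copy() for r in motif.reactions]
    for r in host.reactions:
        reactions.append(
            Reaction(
                f"{tag}_{r.id}",
                {f"{tag}_{x}": c for x, c in r.reactants.items()},
                {f"{tag}_{x}": c for x, c in r.products.items()},
                r.reversible,
            )
        )
    return CRN(species, reactions)


# ---------------------------------------------------------------------------
# Random CRNs
# ---------------------------------------------------------------------------

def random_crn(
    n_species: int,
    n_reactions: int,
    density: float,
    seed: int,
    coef_max: int = 1,
) -> CRN:
    """A reproducible random CRN with disjoint reactant/product sides.

    Each (species, reaction) pair independently takes the role reactant or
    product with probability ``density/2`` each; every reaction is then
    guaranteed at least one reactant and one product (drawn uniformly when
    the random roles left a side empty).  Coefficients are 1 by default;
    ``coef_max > 1`` draws uniform integers in [1, coef_max].  The seed
    fully determines the output.
    """
    if not (0 < density <= 1):
        raise GenerationError("density must be in (0, 1]")
    if n_species < 1 or n_reactions < 1:
        raise GenerationError("need at least one species and one reaction")
    if n_species < 2:
        raise GenerationError(
            "cannot build reactions with disjoint nonempty sides from one species"
        )
    rng = np.random.default_rng(seed)
    xs = [f"x{i}" for i in range(1, n_species + 1)]

    def coef() -> int:
        return 1 if coef_max <= 1 else int(rng.integers(1, coef_max + 1))

    reactions = []
    for j in range(1, n_reactions + 1):
        roles = rng.random(n_species)
        reactants = {xs[i]: coef() for i in range(n_species) if roles[i] < density / 2}
        products = {
            xs[i]: coef()
            for i in range(n_species)
            if density / 2 <= roles[i] < density
        }
        if not reactants:
            free = [x for x in xs if x not in products] or sorted(products)
            x = free[int(rng.integers(len(free)))]
            products.pop(x, None)
            reactants[x] = coef()
        if not products:
            # n_species >= 2, so stealing from an all-reactant side is safe
            free = [x for x in xs if x not in reactants] or sorted(reactants)
            x = free[int(rng.integers(len(free)))]
            reactants.pop(x, None)
            products[x] = coef()
        reactions.append(Reaction(f"r{j}", reactants, products))
    return CRN([Species(x) for x in xs], reactions)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def _iter_matchings(
    e1_adj: Mapping[str, list[str]], species_order: list[str], k_max: int
) -> Iterator[MatchKey]:
    """All nonempty matchings of size <= k_max in the species -> reaction
    consumption relation: each species matched to at most one reaction that
    consumes it, each reaction used at most once.  Every matching is emitted
    exactly once (decisions per species are skip-or-match)."""
    n = len(species_order)

    def rec(i: int, used_r: set[str], acc: list[tuple[str, str]]):
        if i == n:
            if acc:
                yield frozenset(acc)
            return
        x = species_order[i]
        yield from rec(i + 1, used_r, acc)
        if len(acc) < k_max:
            for r in e1_adj.get(x, []):
                if r in used_r:
                    continue
                acc.append((x, r))
                used_r.add(r)
                yield from rec(i + 1, used_r, acc)
                acc.pop()
                used_r.remove(r)

    yield from rec(0, set(), [])


def _strongly_connected(adj: Mapping[int, set[int]], n: int) -> bool:
    """Strong connectivity of a digraph on range(n), plain double BFS."""

    def reach(start: int, edges: Mapping[int, set[int]]) -> set[int]:
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in edges.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen

    if n == 0:
        return False
    if len(reach(0, adj)) != n:
        return False
    rev: dict[int, set[int]] = {}
    for u, vs in adj.items():
        for v in vs:
            rev.setdefault(v, set()).add(u)
    return len(reach(0, rev)) == n


def _oracle_matrix(crn: CRN, matching: MatchKey):
    """Exact CS matrix, Metzler part and irreducibility for a matching."""
    kappa = dict(matching)
    order = [s.id for s in crn.species if s.id in kappa]
    rxns = {r.id: r for r in crn.reactions}
    k = len(order)
    a = [
        [
            rxns[kappa[w]].products.get(x, Fraction(0))
            - rxns[kappa[w]].reactants.get(x, Fraction(0))
            for w in order
        ]
        for x in order
    ]
    metz = [
        [a[i][j] if i == j or a[i][j] >= 0 else Fraction(0) for j in range(k)]
        for i in range(k)
    ]
    if k < 2:
        irreducible = False
    else:
        adj: dict[int, set[int]] = {}
        for i in range(k):
            for j in range(k):
                if i != j and metz[i][j] > 0:
                    adj.setdefault(j, set()).add(i)
        irreducible = _strongly_connected(adj, k)
    return a, metz, irreducible


def _oracle_autocat(a) -> bool:
    """Literal autocatalysis test: per-column negative and positive entries,
    and LP feasibility of {v >= 1, A v >= 1}."""
    arr = np.array([[float(c) for c in row] for row in a])
    if not (np.any(arr > 0, axis=0).all() and np.any(arr < 0, axis=0).all()):
        return False
    if not np.any(arr > 0, axis=1).all():
        return False
    res = linprog(
        c=np.zeros(arr.shape[1]),
        A_ub=-arr,
        b_ub=-np.ones(arr.shape[0]),
        bounds=[(1.0, None)] * arr.shape[1],
        method="highs",
    )
    if res.status == 0:
        return True
    if res.status == 2:
        return False
    raise RuntimeError(f"oracle LP failed: status {res.status}")


def brute_force_autocat(
    crn: CRN,
    k_max: int,
    max_species: int = 8,
    max_reactions: int = 12,
) -> dict[MatchKey, bool]:
    """Exhaustive reference: every child-selection (matching in the
    consumption relation) of size <= k_max whose Metzler part is
    irreducible, with an LP-based autocatalysis verdict.

    Uses only the definitions, never the graph pipeline or the spectral
    shortcut.  Refuses networks beyond the configured size guard.
    """
    if len(crn.species) > max_species or len(crn.reactions) > max_reactions:
        raise GenerationError(
            f"network too large for exhaustive search "
            f"({len(crn.species)} species, {len(crn.reactions)} reactions); "
            "raise the guard explicitly to proceed"
        )
    e1_adj = {
        s.id: sorted(r.id for r in crn.reactions if s.id in r.reactants)
        for s in crn.species
    }
    order = [s.id for s in crn.species]
    out: dict[MatchKey, bool] = {}
    for m in _iter_matchings(e1_adj, order, k_max):
        a, _metz, irreducible = _oracle_matrix(crn, m)
        if not irreducible:
            continue
        out[m] = _oracle_autocat(a)
    return out


def brute_force_fluffle_classes(crn: CRN, k_max: int | None = None,
                                max_species: int = 8,
                                max_reactions: int = 12) -> set[MatchKey]:
    """Matchings whose Metzler part is irreducible — exactly the
    CS-equivalence classes of fluffles, by the strong-block/irreducibility
    correspondence.  Same guard as :func:`brute_force_autocat`."""
    cap = k_max if k_max is not None else min(len(crn.species), len(crn.reactions))
    return set(brute_force_autocat(crn, cap, max_species, max_reactions))


def brute_force_cores(crn: CRN, k_max: int,
                      max_species: int = 8, max_reactions: int = 12) -> set[MatchKey]:
    """Reference core set: autocatalytic Metzler verdicts that are minimal
    under strict matching inclusion among all autocatalytic verdicts."""
    verdicts = brute_force_autocat(crn, k_max, max_species, max_reactions)
    autocat = {m for m, ok in verdicts.items() if ok}
    metzler: set[MatchKey] = set()
    for m in autocat:
        a, metz, _ = _oracle_matrix(crn, m)
        if a == metz:
            metzler.add(m)
    return {
        m for m in autocat & metzler if not any(o < m for o in autocat)
    }


def brute_force_count_fluffles(crn: CRN, max_species: int = 5,
                               max_reactions: int = 6) -> int:
    """Count all fluffle subgraphs by literal application of the defining
    conditions: for every child-selection matching and every subset of the
    available reaction-to-product edges among the matched vertices, keep the
    graphs that are strong blocks.  Exponential; guarded like the other
    brute-force routines."""
    import networkx as nx

    if len(crn.species) > max_species or len(crn.reactions) > max_reactions:
        raise GenerationError("network too large for exhaustive fluffle count")
    e1_adj = {
        s.id: sorted(r.id for r in crn.reactions if s.id in r.reactants)
        for s in crn.species
    }
    rxns = {r.id: r for r in crn.reactions}
    order = [s.id for s in crn.species]
    total = 0
    for m in _iter_matchings(e1_adj, order, len(order)):
        xs = {x for x, _ in m}
        rs = {r for _, r in m}
        e2 = sorted(
            (r, x) for r in rs for x in rxns[r].products if x in xs
        )
        for k in range(len(e2) + 1):
            for subset in itertools.combinations(e2, k):
                g = nx.DiGraph()
                g.add_nodes_from(("S", x) for x in xs)
                g.add_nodes_from(("R", r) for r in rs)
                g.add_edges_from((("S", x), ("R", r)) for x, r in m)
                g.add_edges_from((("R", r), ("S", x)) for r, x in subset)
                if g.number_of_nodes() >= 2 and nx.is_strongly_connected(g) \
                        and nx.is_biconnected(g.to_undirected()):
                    total += 1
    return total
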