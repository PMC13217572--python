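"""Fluffle-class assembly: union tests, canonical representatives,
completeness against brute force, and fluffle counting."""

import pytest

import autocatnet as an
from autocatnet.assembly import GuardError
from autocatnet.konig import reaction_vertex, species_vertex
from helpers import classify_network, ids_key


def _edge(i):
    return (species_vertex(f"x{i}"), reaction_vertex(f"r{i}"))


def _circuits(graph):
    return an.enumerate_elementary_circuits(graph).circuits


def test_union_overlapping_on_shared_e1_edge(typeV_graph):
    cs = _circuits(typeV_graph)
    c1 = next(c for c in cs if c.e1edges == {_edge(1), _edge(3)})
    c3 = next(c for c in cs if c.e1edges == {_edge(1), _edge(2)})
    assert an.union_is_fluffle(c1.e1edges, c1.vertexset, c3)


def test_union_disjoint_circuits_rejected():
    crn = an.synth.plant(an.synth.make_ring(2), an.synth.make_ring(2), tag="b")
    g = an.build_konig(crn)
    a, b = _circuits(g)
    assert not an.union_is_fluffle(a.e1edges, a.vertexset, b)


def test_union_shared_vertex_without_shared_e1_rejected():
    # two 4-cycles meeting only in the reaction vertex r: the shared vertex
    # is not covered by a shared E1 edge, so the union is no fluffle
    crn = an.CRN(
        [an.Species("a"), an.Species("b"), an.Species("c"), an.Species("d")],
        [
            an.Reaction("r", {"a": 1, "c": 1}, {"b": 1, "d": 1}),
            an.Reaction("s", {"b": 1}, {"a": 1}),
            an.Reaction("t", {"d": 1}, {"c": 1}),
        ],
    )
    g = an.build_konig(crn)
    cs = _circuits(g)
    c_ab = next(c for c in cs if {v[1] for v in c.vertices} == {"a", "b", "r", "s"})
    c_cd = next(c for c in cs if {v[1] for v in c.vertices} == {"c", "d", "r", "t"})
    # the circuits share the vertex r but no E1 edge covers it in common
    assert c_ab.vertexset & c_cd.vertexset
    assert not an.union_is_fluffle(c_ab.e1edges, c_ab.vertexset, c_cd)


def test_canonical_representative_full_typeV(typeV_graph):
    e1 = frozenset({_edge(1), _edge(2), _edge(3)})
    rep = an.canonical_representative(e1, typeV_graph)
    assert rep.e1 == e1 and rep.e2 == typeV_graph.E2
    assert rep.induced
    assert an.is_fluffle_graph(rep.to_nx())


def test_canonical_representative_subclass_gains_e2(typeV_graph):
    e1 = frozenset({_edge(1), _edge(3)})
    rep = an.canonical_representative(e1, typeV_graph)
    # the 4-cycle edges plus the extra productions among its 4 vertices
    assert rep.e2 == {
        (reaction_vertex("r1"), species_vertex("x3")),
        (reaction_vertex("r3"), species_vertex("x1")),
    }
    assert an.is_fluffle_graph(rep.to_nx())


def test_canonical_representative_rejects_non_matching(typeV_graph):
    bad = frozenset({_edge(1), (species_vertex("x1"), reaction_vertex("r2"))})
    with pytest.raises(an.ValidationError):
        an.canonical_representative(bad, typeV_graph)


def test_single_e1_edge_is_not_a_fluffle(typeV_graph):
    rep = an.canonical_representative(frozenset({_edge(1)}), typeV_graph)
    assert not an.is_fluffle_graph(rep.to_nx())


def test_assemble_typeV_classes(typeV_graph):
    reps = an.circuit_representatives(an.enumerate_elementary_circuits(typeV_graph))
    classes = an.assemble_classes(reps, typeV_graph)
    keys = {frozenset(k) for k in classes}
    assert keys == {
        frozenset({_edge(1), _edge(3)}),
        frozenset({_edge(2), _edge(3)}),
        frozenset({_edge(1), _edge(2)}),
        frozenset({_edge(1), _edge(2), _edge(3)}),
    }


def test_assemble_size_cap(typeV_graph):
    reps = an.circuit_representatives(an.enumerate_elementary_circuits(typeV_graph))
    classes = an.assemble_classes(reps, typeV_graph, size_cap=2)
    assert len(classes) == 3 and all(c.size == 2 for c in classes.values())


def test_size_cap_monotonicity(typeV_graph):
    reps = an.circuit_representatives(an.enumerate_elementary_circuits(typeV_graph))
    seen = set()
    for cap in (2, 3, None):
        keys = set(an.assemble_classes(reps, typeV_graph, size_cap=cap))
        assert seen <= keys
        seen = keys


def test_single_circuit_graph_single_class():
    g = an.build_konig(an.synth.make_ring(3))
    reps = an.circuit_representatives(an.enumerate_elementary_circuits(g))
    classes = an.assemble_classes(reps, g)
    assert len(classes) == 1


def test_predecessor_links_are_proper_subsets(typeV_graph):
    reps = an.circuit_representatives(an.enumerate_elementary_circuits(typeV_graph))
    classes = an.assemble_classes(reps, typeV_graph)
    for key, cls in classes.items():
        for p in cls.predecessors:
            assert p < key
            assert p in classes


@pytest.mark.parametrize("seed", range(25))
def test_class_set_matches_brute_force(seed):
    """Reachability completeness: assembled classes equal the brute-force
    enumeration of all matchings with irreducible Metzler part."""
    crn = an.synth.random_crn(5, 6, 0.4, seed=seed)
    pipeline_keys = set(classify_network(crn))
    oracle_keys = an.synth.brute_force_fluffle_classes(crn)
    assert pipeline_keys == oracle_keys


@pytest.mark.parametrize("seed", range(10))
def test_every_class_satisfies_fluffle_conditions(seed):
    crn = an.synth.random_crn(5, 6, 0.4, seed=100 + seed)
    kg = an.build_konig(crn)
    for comp in an.strongly_connected_components(kg):
        reps = an.circuit_representatives(an.enumerate_elementary_circuits(comp))
        for key, cls in an.assemble_classes(reps, comp).items():
            rep = an.canonical_representative(key, kg)
            assert an.is_fluffle_graph(rep.to_nx())
            # E1 is a perfect matching of the class vertex set
            assert {u for u, _ in key} | {v for _, v in key} == cls.vertexset


def test_count_fluffles_typeV(typeV_graph):
    reps = an.circuit_representatives(an.enumerate_elementary_circuits(typeV_graph))
    classes = an.assemble_classes(reps, typeV_graph)
    n = an.count_fluffles(classes.values(), typeV_graph)
    assert n == an.synth.brute_force_count_fluffles(typeV_graph.crn)
    assert n >= len(classes)


def test_count_fluffles_single_circuit():
    g = an.build_konig(an.synth.make_ring(3))
    reps = an.circuit_representatives(an.enumerate_elementary_circuits(g))
    classes = an.assemble_classes(reps, g)
    assert an.count_fluffles(classes.values(), g) == 1


def test_count_fluffles_guard(typeV_graph):
    reps = an.circuit_representatives(an.enumerate_elementary_circuits(typeV_graph))
    classes = an.assemble_classes(reps, typeV_graph)
    with pytest.raises(GuardError):
        an.count_fluffles(classes.values(), typeV_graph, size_threshold=2)
    # opt-in overrides the refusal
    assert an.count_fluffles(classes.values(), typeV_graph, opt_in=True,
                             size_threshold=2) == 21


def test_is_circuitnet_examples(typeV_graph):
    cs = _circuits(typeV_graph)
    four = [c for c in cs if c.length == 4]
    six = [c for c in cs if c.length == 6]
    assert an.is_circuitnet([four[0]])
    assert an.is_circuitnet(four)
    assert an.is_circuitnet(six)
    assert an.is_circuitnet([four[0], six[0]])
    assert not an.is_circuitnet([])
    # vertex-disjoint circuits can never chain into strong blocks
    crn = an.synth.plant(an.synth.make_ring(2), an.synth.make_ring(2), tag="b")
    a, b = _circuits(an.build_konig(crn))
    assert not an.is_circuitnet([a, b])
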