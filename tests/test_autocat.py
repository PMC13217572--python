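"""CS matrices, spectral/LP autocatalysis tests, and core identification."""

import math
from fractions import Fraction

import numpy as np
import pytest

import autocatnet as an
from autocatnet.autocat import matrix_is_autocatalytic
from autocatnet.konig import reaction_vertex, species_vertex
from helpers import (
    classify_network,
    direct_core_keys,
    ids_key,
    metzler_part,
    random_cs_like,
    random_irreducible_metzler,
)


def _edge(i):
    return (species_vertex(f"x{i}"), reaction_vertex(f"r{i}"))


FULL_TYPEV = frozenset({_edge(1), _edge(2), _edge(3)})


def _crn_from_columns(*columns):
    """Build a CRN whose full CS matrix equals the given integer columns:
    column j belongs to reaction r_{j+1} consuming x_{j+1}."""
    n = len(columns)
    species = [an.Species(f"x{i}") for i in range(1, n + 1)]
    reactions = []
    for j, col in enumerate(columns, start=1):
        reactants = {}
        products = {}
        for i, c in enumerate(col, start=1):
            if c < 0:
                reactants[f"x{i}"] = -c
            elif c > 0:
                products[f"x{i}"] = c
        reactions.append(an.Reaction(f"r{j}", reactants, products))
    return an.CRN(species, reactions)


def test_cs_matrix_typeV(typeV):
    m = an.cs_matrix(FULL_TYPEV, typeV)
    assert [[int(c) for c in row] for row in m.exact] == [
        [-1, 1, 1],
        [1, -1, 1],
        [1, 1, -1],
    ]
    assert m.ismetzler and m.isirreducible
    assert m.species == ("x1", "x2", "x3") and m.reactions == ("r1", "r2", "r3")


def test_cs_matrix_single_consumed_reactant():
    crn = an.CRN(
        [an.Species("x1"), an.Species("x2")],
        [an.Reaction("r1", {"x1": 1}, {"x2": 1})],
    )
    m = an.cs_matrix(frozenset({_edge(1)}), crn)
    assert m.exact == ((Fraction(-1),),)
    assert not m.isirreducible


def test_cs_matrix_non_metzler_cell():
    # x1 is also a reactant of the reaction selected for x2, giving a
    # negative off-diagonal entry that the Metzler part zeroes out
    crn = an.CRN(
        [an.Species("x1"), an.Species("x2"), an.Species("x3")],
        [
            an.Reaction("r1", {"x1": 1}, {"x2": 1}),
            an.Reaction("r2", {"x2": 1, "x1": 2}, {"x3": 1}),
        ],
    )
    m = an.cs_matrix(frozenset({_edge(1), _edge(2)}), crn)
    assert m.exact[0][1] == Fraction(-2)
    assert m.metzler_exact[0][1] == Fraction(0)
    assert not m.ismetzler


def test_cs_matrix_invalid_selection(typeV):
    with pytest.raises(an.ValidationError):
        an.cs_matrix(frozenset({(species_vertex("x1"), reaction_vertex("r2"))}), typeV)


# -- spectral test ------------------------------------------------------------

def test_eigen_typeV_leading_eigenvalue_one(typeV):
    v = an.is_autocatalytic_metzler(an.cs_matrix(FULL_TYPEV, typeV))
    assert v.autocatalytic and abs(v.leadingeig - 1.0) < 1e-9
    assert v.method == "eigen"
    assert v.certificate is not None and np.all(v.certificate > 0)
    # the Perron vector of the symmetric Eq-pattern is uniform
    assert np.allclose(v.certificate, v.certificate[0])


def test_eigen_conservative_two_cycle_not_autocatalytic():
    crn = _crn_from_columns([-1, 1], [1, -1])
    m = an.cs_matrix(frozenset({_edge(1), _edge(2)}), crn)
    v = an.is_autocatalytic_metzler(m)
    assert not v.autocatalytic and abs(v.leadingeig) < 1e-9


def test_eigen_doubling_two_cycle_autocatalytic():
    # [[-1, 2], [1, -1]] has Perron root sqrt(2) - 1 > 0
    crn = _crn_from_columns([-1, 1], [2, -1])
    m = an.cs_matrix(frozenset({_edge(1), _edge(2)}), crn)
    v = an.is_autocatalytic_metzler(m)
    assert v.autocatalytic
    assert abs(v.leadingeig - (math.sqrt(2) - 1)) < 1e-9


def test_eigen_contract_errors(typeV):
    m = an.cs_matrix(frozenset({_edge(1)}), typeV)
    with pytest.raises(ValueError):
        an.is_autocatalytic_metzler(m)


# -- LP test ------------------------------------------------------------------

def test_lp_typeV_certificate(typeV):
    m = an.cs_matrix(FULL_TYPEV, typeV)
    v = an.is_autocatalytic_general(m)
    assert v.autocatalytic and v.method == "lp"
    assert np.all(v.certificate >= 1 - 1e-9)
    assert np.all(m.array @ v.certificate >= 1 - 1e-9)


def test_lp_conservative_cycle_infeasible():
    crn = _crn_from_columns([-1, 1], [1, -1])
    m = an.cs_matrix(frozenset({_edge(1), _edge(2)}), crn)
    assert not an.is_autocatalytic_general(m).autocatalytic


def test_lp_sink_reaction_rejected_structurally():
    # r2 produces nothing inside {x1, x2}: all-nonpositive column
    crn = an.CRN(
        [an.Species("x1"), an.Species("x2"), an.Species("y")],
        [
            an.Reaction("r1", {"x1": 1}, {"x2": 2}),
            an.Reaction("r2", {"x2": 1}, {"y": 1}),
            an.Reaction("r3", {"y": 1}, {"x1": 1}),
        ],
    )
    m = an.cs_matrix(frozenset({_edge(1), _edge(2)}), crn)
    assert not an.is_autocatalytic_general(m).autocatalytic


# -- agreement and necessity property suites ---------------------------------

def test_eigen_lp_agreement_on_random_metzler():
    """For irreducible Metzler matrices the spectral and the LP criteria are
    the same test (>= 1000 random integer matrices)."""
    rng = np.random.default_rng(20240)
    for _ in range(1000):
        m = random_irreducible_metzler(rng)
        eig = an.is_autocatalytic_metzler(m).autocatalytic
        lp = an.is_autocatalytic_general(m).autocatalytic
        assert eig == lp, f"disagreement on {m.exact}"


def test_metzler_part_necessity_on_random_cs_matrices():
    """Autocatalysis of a CS matrix implies autocatalysis of its Metzler
    part (>= 1000 random matrices with mixed-sign off-diagonals)."""
    rng = np.random.default_rng(77)
    checked = 0
    hits = 0
    while checked < 1000:
        a = random_cs_like(rng)
        checked += 1
        if matrix_is_autocatalytic(a):
            hits += 1
            assert matrix_is_autocatalytic(metzler_part(a)), f"violation at {a}"
    assert hits > 20  # the property was actually exercised


# -- cores --------------------------------------------------------------------

def test_typeV_single_core(typeV):
    classes = classify_network(typeV)
    cores = {k for k, c in classes.items() if c.core}
    assert cores == {frozenset({("x1", "r1"), ("x2", "r2"), ("x3", "r3")})}
    two_cycles = [c for c in classes.values() if c.size == 2]
    assert len(two_cycles) == 3 and not any(c.autocatalytic for c in two_cycles)


def test_ring_not_autocatalytic():
    classes = classify_network(an.synth.make_ring(4))
    (cls,) = classes.values()
    assert cls.metzler and not cls.autocatalytic and not cls.core


def test_theorem46_shortcut_superset_of_core():
    """A Metzler class strictly containing an autocatalytic Metzler class is
    autocatalytic by containment, with no explicit solve."""
    # Type V core extended by a fourth species fed back into the cycle
    crn = an.CRN(
        [an.Species(f"x{i}") for i in (1, 2, 3, 4)],
        [
            an.Reaction("r1", {"x1": 1}, {"x2": 1, "x3": 1}),
            an.Reaction("r2", {"x2": 1}, {"x1": 1, "x3": 1}),
            an.Reaction("r3", {"x3": 1}, {"x1": 1, "x2": 1, "x4": 1}),
            an.Reaction("r4", {"x4": 1}, {"x1": 1}),
        ],
    )
    classes = classify_network(crn)
    full = frozenset({(f"x{i}", f"r{i}") for i in (1, 2, 3, 4)})
    core = frozenset({(f"x{i}", f"r{i}") for i in (1, 2, 3)})
    assert classes[core].core
    assert classes[full].autocatalytic and classes[full].metzler
    assert not classes[full].core


def test_core_spectral_invariants():
    """Every detected core is an irreducible Metzler matrix with negative
    diagonal, exactly one eigenvalue of positive real part, and determinant
    sign (-1)^(n-1)."""
    networks = [an.synth.make_typeV(),
                an.synth.plant(an.synth.make_typeV(), an.synth.make_typeV(), tag="b")]
    networks += [an.synth.random_crn(6, 7, 0.4, seed=s) for s in range(40)]
    n_cores = 0
    for crn in networks:
        classes = classify_network(crn)
        for key, cls in classes.items():
            if not cls.core:
                continue
            n_cores += 1
            e1 = frozenset(
                (species_vertex(x), reaction_vertex(r)) for x, r in key
            )
            m = an.cs_matrix(e1, crn)
            assert m.ismetzler and m.isirreducible
            assert all(m.exact[i][i] < 0 for i in range(m.k))
            eigs = np.linalg.eigvals(m.array)
            assert int((eigs.real > 1e-9).sum()) == 1
            det = np.linalg.det(m.array)
            assert math.copysign(1, det) == (-1) ** (m.k - 1)
    assert n_cores >= 3  # the invariants were exercised on real detections


def test_direct_mode_equals_filtered_full_mode():
    fixtures = [
        an.synth.make_typeV(),
        an.synth.make_ring(4),
        an.synth.make_complete_alternating(4),
        an.synth.plant(an.synth.make_typeV(), an.synth.make_typeV(), tag="b"),
    ] + [an.synth.random_crn(5, 6, 0.4, seed=s) for s in range(20)]
    for crn in fixtures:
        classes = classify_network(crn)
        full_cores = {k for k, c in classes.items() if c.core}
        assert direct_core_keys(crn) == full_cores


def test_direct_mode_non_metzler_only_graph_empty():
    # every circuit here has an E1 chord, so no Metzler circuits exist and
    # the direct mode must return nothing
    crn = an.CRN(
        [an.Species(f"x{i}") for i in (1, 2, 3)],
        [
            an.Reaction("r1", {"x1": 1}, {"x2": 1}),
            an.Reaction("r2", {"x2": 1, "x1": 1}, {"x3": 2}),
            an.Reaction("r3", {"x3": 1, "x2": 1}, {"x1": 2}),
        ],
    )
    g = an.build_konig(crn)
    circuits = an.enumerate_elementary_circuits(g).circuits
    if all(not an.is_metzler_circuit(c, g) for c in circuits):
        assert an.enumerate_cores_direct(g, crn) == []


def test_planted_motifs_give_two_cores():
    crn = an.synth.plant(an.synth.make_typeV(), an.synth.make_typeV(), tag="b")
    assert len(direct_core_keys(crn)) == 2


def test_core_minimality_exhaustive_small():
    """For every flagged core, every proper sub-matching that is itself a
    class yields a non-autocatalytic matrix."""
    for seed in range(15):
        crn = an.synth.random_crn(5, 6, 0.45, seed=300 + seed)
        classes = classify_network(crn)
        for key, cls in classes.items():
            if cls.core:
                for other, ocls in classes.items():
                    if other < key:
                        assert not ocls.autocatalytic


def test_reaction_set_minimality_flag(typeV):
    kg = an.build_konig(typeV)
    cores = an.enumerate_cores_direct(kg, typeV)
    assert [c.reaction_set_minimal for c in cores] == [True]
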