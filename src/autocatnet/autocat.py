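"""Child-selection (CS) matrices, autocatalysis tests, and core detection.

A child-selection pairs each selected species x with a reaction kappa(x)
that consumes it; the associated k x k CS matrix has entries
``S[kappa]_{xw} = s+_{x,kappa(w)} - s-_{x,kappa(w)}``, i.e. column w is the
stoichiometric column of reaction kappa(x_w) restricted to the selected
species.  Its diagonal is strictly negative (the selected reactant is
consumed, never co-produced).

A matrix A is *autocatalytic* when (i) some strictly positive vector v has
``A v > 0`` and (ii) every column carries both a negative and a positive
entry: some positive flux combination makes net surplus of every selected
species while each reaction consumes and produces inside the subnetwork.
An *autocatalytic core* is a minimal autocatalytic matrix; cores are always
irreducible Metzler matrices with negative diagonal (up to column order).

Two tests are available:

* irreducible Metzler matrices: autocatalysis is equivalent to
  Hurwitz-instability, decided by the sign of the (real) Perron eigenvalue;
* general CS matrices: a structural no-source/no-sink check plus an LP
  feasibility problem ``{v >= 1, A v >= 1}`` (any strictly positive
  certificate scales into this polytope, so no epsilon tuning is needed).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
from scipy.optimize import linprog

from .assembly import FluffleClass, canonical_representative, union_is_fluffle
from .circuits import CircuitIndex, circuit_representatives, enumerate_elementary_circuits, is_metzler_circuit
from .crn import CRN, CRNError, ValidationError
from .konig import (
    Edge,
    KonigGraph,
    SubgraphHandle,
    as_handle,
    species_vertex,
    reaction_vertex,
    vertex_id,
    vertex_kind,
    SPECIES,
)

logger = logging.getLogger("autocatnet")

__all__ = [
    "EIG_TOL",
    "SolverError",
    "CSMatrix",
    "AutocatVerdict",
    "cs_matrix",
    "matrix_is_autocatalytic",
    "is_autocatalytic_metzler",
    "is_autocatalytic_general",
    "identify_cores",
    "enumerate_cores_direct",
    "write_results_tsv",
    "write_matrix_tsv",
]

#: numerical tolerance on the Perron root; below 1e-6 in magnitude, integer /
#: rational matrices fall back to an exact characteristic-polynomial test.
EIG_TOL = 1e-9
_EXACT_FALLBACK_MARGIN = 1e-6


class SolverError(CRNError):
    """LP solver failed for a reason other than infeasibility."""


@dataclass
class CSMatrix:
    """A CS matrix together with its Metzler part and structure flags.

    Rows are ordered by the host CRN's species order restricted to the
    selected species; column w corresponds to the reaction assigned to the
    w-th selected species.  Exact rational entries are kept alongside the
    float array.
    """

    species: tuple[str, ...]
    reactions: tuple[str, ...]
    exact: tuple[tuple[Fraction, ...], ...]
    metzler_exact: tuple[tuple[Fraction, ...], ...]
    ismetzler: bool
    isirreducible: bool

    @property
    def k(self) -> int:
        return len(self.species)

    @property
    def array(self) -> np.ndarray:
        return np.array([[float(c) for c in row] for row in self.exact])

    @property
    def metzler_array(self) -> np.ndarray:
        return np.array([[float(c) for c in row] for row in self.metzler_exact])


@dataclass
class AutocatVerdict:
    """Outcome of an autocatalysis test."""

    autocatalytic: bool
    certificate: np.ndarray | None = None
    leadingeig: float | None = None
    method: str = "lp"


def _metzler_irreducible(metzler: Sequence[Sequence[Fraction]]) -> bool:
    """Irreducibility of a Metzler part, via strong connectivity of the
    digraph of its positive off-diagonal entries (the substrate graph).

    For k = 1 this returns False: a lone consumed species corresponds to a
    bipartite graph x -> r that is not strongly connected, matching the
    graph-side criterion rather than the trivial matrix convention.
    """
    k = len(metzler)
    if k < 2:
        return False
    g = nx.DiGraph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(k):
            if i != j and metzler[i][j] > 0:
                g.add_edge(j, i)  # kappa(x_j) produces x_i
    return nx.is_strongly_connected(g)


def cs_matrix(e1: frozenset[Edge], crn: CRN) -> CSMatrix:
    """Build the CS matrix of a perfect-matching E1 edge set.

    Raises :class:`ValidationError` if ``e1`` is not a matching or if a
    selected reaction does not actually consume its selected species.
    """
    kappa: dict[str, str] = {}
    rids: set[str] = set()
    for u, v in e1:
        if vertex_kind(u) != SPECIES:
            raise ValidationError(f"not a reactant-to-reaction edge: ({u}, {v})")
        x, r = vertex_id(u), vertex_id(v)
        if x in kappa or r in rids:
            raise ValidationError("E1 edge set is not a matching")
        kappa[x] = r
        rids.add(r)
    order = [s.id for s in crn.species if s.id in kappa]
    if len(order) != len(kappa):
        missing = sorted(set(kappa) - set(order))
        raise ValidationError(f"species not in CRN: {missing}")
    rxns = {r.id: r for r in crn.reactions}
    for x in order:
        rx = rxns.get(kappa[x])
        if rx is None:
            raise ValidationError(f"reaction not in CRN: {kappa[x]!r}")
        if rx.reactants.get(x, Fraction(0)) <= 0:
            raise ValidationError(
                f"selected reaction {kappa[x]!r} does not consume species {x!r}"
            )
    cols = [rxns[kappa[x]] for x in order]
    exact = tuple(
        tuple(
            r.products.get(x, Fraction(0)) - r.reactants.get(x, Fraction(0))
            for r in cols
        )
        for x in order
    )
    metzler = tuple(
        tuple(
            exact[i][j] if i == j or exact[i][j] >= 0 else Fraction(0)
            for j in range(len(order))
        )
        for i in range(len(order))
    )
    return CSMatrix(
        species=tuple(order),
        reactions=tuple(kappa[x] for x in order),
        exact=exact,
        metzler_exact=metzler,
        ismetzler=exact == metzler,
        isirreducible=_metzler_irreducible(metzler),
    )


# ---------------------------------------------------------------------------
# Autocatalysis tests
# ---------------------------------------------------------------------------

def _lp_feasible(a: np.ndarray) -> np.ndarray | None:
    """Feasibility of {v >= 1, A v >= 1}; returns v or None if infeasible."""
    k = a.shape[1]
    res = linprog(
        c=np.zeros(k),
        A_ub=-a,
        b_ub=-np.ones(a.shape[0]),
        bounds=[(1.0, None)] * k,
        method="highs",
    )
    if res.status == 0:
        return res.x
    if res.status == 2:
        return None
    raise SolverError(f"LP solver failed with status {res.status}: {res.message}")


def matrix_is_autocatalytic(a: np.ndarray) -> bool:
    """Direct test of the autocatalysis definition on a raw matrix: every
    column has a positive and a negative entry, and some positive v gives
    ``A v > 0``."""
    a = np.asarray(a, dtype=float)
    if not (np.any(a > 0, axis=0).all() and np.any(a < 0, axis=0).all()):
        return False
    return _lp_feasible(a) is not None


def _exact_has_positive_root(exact: Sequence[Sequence[Fraction]]) -> bool:
    """Exact fallback for borderline Perron roots: does the characteristic
    polynomial have a real positive root?"""
    import sympy

    m = sympy.Matrix([[sympy.Rational(c.numerator, c.denominator) for c in row]
                      for row in exact])
    lam = sympy.Symbol("lam")
    poly = m.charpoly(lam)
    return any(r > 0 for r in sympy.real_roots(poly.as_expr(), lam))


def is_autocatalytic_metzler(m: CSMatrix, tol: float = EIG_TOL) -> AutocatVerdict:
    """Spectral test for irreducible Metzler CS matrices: autocatalytic iff
    the Perron root exceeds zero (Hurwitz-instability).

    Raises ValueError when called on a non-Metzler or reducible matrix; use
    :func:`is_autocatalytic_general` there.
    """
    if not m.ismetzler:
        raise ValueError("matrix is not Metzler; use is_autocatalytic_general")
    if not m.isirreducible:
        raise ValueError("Metzler part is reducible; the spectral test does not apply")
    a = m.array
    vals, vecs = np.linalg.eig(a)
    lead = int(np.argmax(vals.real))
    lam = float(vals[lead].real)
    # A zero Perron root computed in floats lands within ~1e-12 of zero for
    # matrices of this scale, and a genuinely positive root of a small
    # rational matrix cannot hide below ~1e-6; only the window in between is
    # ambiguous and is resolved exactly on the rational entries.
    if tol < lam < _EXACT_FALLBACK_MARGIN:
        autocat = _exact_has_positive_root(m.exact)
    else:
        autocat = lam > tol
    cert = None
    if autocat:
        v = np.abs(vecs[:, lead].real)
        if np.all(v > 0):
            cert = v / v.max()
    return AutocatVerdict(autocatalytic=autocat, certificate=cert, leadingeig=lam,
                          method="eigen")


def is_autocatalytic_general(m: CSMatrix, g: SubgraphHandle | None = None) -> AutocatVerdict:
    """General autocatalysis test for a CS matrix.

    The structural part checks that the induced subgraph on the selected
    vertices has no source or sink: every selected species must be produced
    by some selected reaction (each row needs a positive entry) and every
    selected reaction must produce inside the subnetwork (each column needs
    a positive entry).  Consumption is guaranteed by the negative diagonal.
    If the structure passes, LP feasibility of {v >= 1, S[kappa] v >= 1}
    decides the positive-certificate condition.
    """
    a = m.array
    rows_ok = bool(np.any(a > 0, axis=1).all())
    cols_ok = bool(np.any(a > 0, axis=0).all())
    if not (rows_ok and cols_ok):
        return AutocatVerdict(autocatalytic=False, method="lp")
    v = _lp_feasible(a)
    if v is None:
        return AutocatVerdict(autocatalytic=False, method="lp")
    return AutocatVerdict(autocatalytic=True, certificate=v, method="lp")


# ---------------------------------------------------------------------------
# Classification and core identification
# ---------------------------------------------------------------------------

def classify_class(cls: FluffleClass, crn: CRN,
                   known_autocat_metzler: Sequence[frozenset[Edge]] = ()) -> CSMatrix:
    """Fill in the Metzler/autocatalytic flags of one class, using the
    cheapest sound test.

    A Metzler class containing a known autocatalytic Metzler class (E1
    subset) is autocatalytic without any solve: an irreducible Metzler
    matrix with an autocatalytic principal submatrix is itself
    autocatalytic.
    """
    m = cs_matrix(cls.e1, crn)
    if not m.isirreducible:
        raise ValidationError(
            "fluffle class with reducible Metzler part: assembly invariant violated"
        )
    cls.metzler = m.ismetzler
    if m.ismetzler:
        if any(k < cls.e1 for k in known_autocat_metzler):
            cls.autocatalytic = True
        else:
            cls.autocatalytic = is_autocatalytic_metzler(m).autocatalytic
    else:
        cls.autocatalytic = is_autocatalytic_general(m).autocatalytic
    return m


def identify_cores(
    classes: Mapping[frozenset[Edge], FluffleClass] | Iterable[FluffleClass],
    crn: CRN,
    g: KonigGraph | SubgraphHandle,
) -> list[FluffleClass]:
    """Classify every assembled class and flag the autocatalytic cores.

    A class is a core iff its CS matrix is Metzler (equivalently, its
    canonical representative is an induced subgraph), it is autocatalytic,
    and no other autocatalytic class has a strictly contained E1 set.
    Classes are processed small-to-large so that the containment shortcut
    can skip explicit tests.

    For comparability with reaction-set-minimal conventions, each core is
    additionally annotated with ``reaction_set_minimal``: whether no other
    core uses a strictly contained reaction set.
    """
    if isinstance(classes, Mapping):
        records = list(classes.values())
    else:
        records = list(classes)
    ordered = sorted(records, key=lambda c: (c.size, c.sorted_key()))
    autocat_keys: list[frozenset[Edge]] = []
    autocat_metzler_keys: list[frozenset[Edge]] = []
    for cls in ordered:
        classify_class(cls, crn, autocat_metzler_keys)
        if cls.autocatalytic:
            autocat_keys.append(cls.e1)
            if cls.metzler:
                autocat_metzler_keys.append(cls.e1)
    cores: list[FluffleClass] = []
    for cls in ordered:
        cls.core = bool(
            cls.autocatalytic
            and cls.metzler
            and not any(k < cls.e1 for k in autocat_keys)
        )
        if cls.core:
            cores.append(cls)
    rsets = {c.e1: frozenset(v for _, v in c.e1) for c in cores}
    for c in cores:
        c.reaction_set_minimal = not any(
            rsets[o.e1] < rsets[c.e1] for o in cores if o is not c
        )
    return cores


def enumerate_cores_direct(
    g: KonigGraph | SubgraphHandle,
    crn: CRN,
    size_cap: int | None = None,
) -> list[FluffleClass]:
    """Enumerate autocatalytic cores without assembling all classes.

    Cores are unions of Metzler circuits, and every partial union along a
    suitable ordering is a non-autocatalytic Metzler fluffle, so the search
    (a) seeds only with Metzler circuits, (b) discards any union whose CS
    matrix is non-Metzler (all its supersets are non-Metzler too), and (c)
    withholds autocatalytic Metzler classes from expansion, emitting them as
    core candidates.  A postprocessing pass removes candidates whose E1 set
    strictly contains another candidate's (supersets reached before their
    minimal subsets along some path).
    """
    h = as_handle(g)
    max_len = None if size_cap is None else 2 * size_cap
    idx_all = enumerate_elementary_circuits(h, max_len=max_len)
    metzler_circuits = [c for c in idx_all.circuits if is_metzler_circuit(c, h)]
    tmp = CircuitIndex()
    for c in metzler_circuits:
        tmp.add(c)
    reps = circuit_representatives(tmp)
    idx = CircuitIndex()
    for c in reps:
        idx.add(c)

    status: dict[frozenset[Edge], str] = {}
    candidates: dict[frozenset[Edge], FluffleClass] = {}
    queue: deque[tuple[frozenset[Edge], frozenset]] = deque()

    def process(key: frozenset[Edge], verts: frozenset) -> None:
        m = cs_matrix(key, crn)
        if not m.ismetzler:
            status[key] = "discard"
            return
        if is_autocatalytic_metzler(m).autocatalytic:
            status[key] = "candidate"
            candidates[key] = FluffleClass(
                e1=key, vertexset=verts, metzler=True, autocatalytic=True
            )
        else:
            status[key] = "expand"
            queue.append((key, verts))

    for c in sorted(reps, key=lambda c: (c.length, c.vertices)):
        if size_cap is not None and len(c.e1edges) > size_cap:
            continue
        if c.e1edges not in status:
            process(c.e1edges, c.vertexset)

    while queue:
        key, verts = queue.popleft()
        for c in idx.circuits_sharing(key):
            if not union_is_fluffle(key, verts, c):
                continue
            new = key | c.e1edges
            if new == key or new in status:
                continue
            if size_cap is not None and len(new) > size_cap:
                continue
            process(new, verts | c.vertexset)

    keys = sorted(candidates, key=lambda k: (len(k), tuple(sorted(k))))
    cores = []
    for k in keys:
        if any(o < k for o in keys):
            continue
        cls = candidates[k]
        cls.core = True
        cores.append(cls)
    rsets = {c.e1: frozenset(v for _, v in c.e1) for c in cores}
    for c in cores:
        c.reaction_set_minimal = not any(
            rsets[o.e1] < rsets[c.e1] for o in cores if o is not c
        )
    return cores


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def _key_str(e1: frozenset[Edge]) -> str:
    return ";".join(f"{vertex_id(u)}->{vertex_id(v)}" for u, v in sorted(e1))


def write_results_tsv(
    classes: Iterable[FluffleClass], crn: CRN, path: str | Path
) -> None:
    """Per-class results table: key, size, structure flags, verdicts, and
    the leading eigenvalue (Metzler) or LP certificate norm (non-Metzler)."""
    rows = sorted(classes, key=lambda c: (c.size, c.sorted_key()))
    with open(path, "w") as fh:
        fh.write(
            "class\tn_species\tis_metzler\tis_irreducible\tautocatalytic\tcore\tevidence\n"
        )
        for cls in rows:
            m = cs_matrix(cls.e1, crn)
            if m.ismetzler and m.isirreducible:
                v = is_autocatalytic_metzler(m)
                evidence = f"leading_eig={v.leadingeig:.6g}"
            else:
                v = is_autocatalytic_general(m)
                evidence = (
                    f"lp_cert_norm={float(np.linalg.norm(v.certificate)):.6g}"
                    if v.certificate is not None
                    else "lp_infeasible"
                )
            fh.write(
                f"{_key_str(cls.e1)}\t{cls.size}\t{m.ismetzler}\t{m.isirreducible}\t"
                f"{cls.autocatalytic}\t{cls.core}\t{evidence}\n"
            )


def write_matrix_tsv(m: CSMatrix, path: str | Path) -> None:
    """Dense CS matrix with species row labels and reaction column labels."""
    with open(path, "w") as fh:
        fh.write("species\\reaction\t" + "\t".join(m.reactions) + "\n")
        for sid, row in zip(m.species, m.exact):
            fh.write(sid + "\t" + "\t".join(str(c) for c in row) + "\n")
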