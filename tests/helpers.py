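"""Shared helpers for the test suite."""

from __future__ import annotations

import itertools

import numpy as np

import autocatnet as an
from autocatnet.konig import vertex_id


def ids_key(e1):
    """Convert a vertex-pair E1 key to a plain (species_id, reaction_id) key."""
    return frozenset((vertex_id(u), vertex_id(v)) for u, v in e1)


def classify_network(crn, size_cap=None):
    """Run the full pipeline (per strongly connected component) and return
    {plain key: FluffleClass} with all flags filled in."""
    kg = an.build_konig(crn)
    out = {}
    for comp in an.strongly_connected_components(kg):
        cap = None if size_cap is None else 2 * size_cap
        idx = an.enumerate_elementary_circuits(comp, cap)
        reps = an.circuit_representatives(idx)
        classes = an.assemble_classes(reps, comp, size_cap)
        an.identify_cores(classes, crn, comp)
        for k, cls in classes.items():
            out[ids_key(k)] = cls
    return out


def direct_core_keys(crn, size_cap=None):
    """Plain keys of the cores found by the direct (Metzler-circuit) mode."""
    kg = an.build_konig(crn)
    keys = set()
    for comp in an.strongly_connected_components(kg):
        for c in an.enumerate_cores_direct(comp, crn, size_cap):
            keys.add(ids_key(c.e1))
    return keys


def brute_cycles(nxg):
    """Reference elementary-circuit enumerator: plain DFS where each cycle is
    discovered exactly once, rooted at its smallest vertex."""
    out = set()
    for start in sorted(nxg):
        def dfs(u, path, onpath):
            for v in sorted(nxg.successors(u)):
                if v == start and len(path) > 1:
                    out.add(tuple(path))
                elif v not in onpath and v > start:
                    onpath.add(v)
                    path.append(v)
                    dfs(v, path, onpath)
                    path.pop()
                    onpath.remove(v)

        dfs(start, [start], {start})
    return out


def random_irreducible_metzler(rng, n_max=5, coef_max=3):
    """A random irreducible Metzler integer matrix with negative diagonal,
    wrapped as a CSMatrix (for exercising the spectral test)."""
    from fractions import Fraction

    from autocatnet.autocat import CSMatrix, _metzler_irreducible

    while True:
        n = int(rng.integers(2, n_max + 1))
        a = rng.integers(0, coef_max + 1, size=(n, n))
        np.fill_diagonal(a, -rng.integers(1, coef_max + 1, size=n))
        exact = tuple(tuple(Fraction(int(x)) for x in row) for row in a)
        if _metzler_irreducible(exact):
            return CSMatrix(
                species=tuple(f"x{i}" for i in range(n)),
                reactions=tuple(f"r{i}" for i in range(n)),
                exact=exact,
                metzler_exact=exact,
                ismetzler=True,
                isirreducible=True,
            )


def random_cs_like(rng, n_max=5, coef_max=3):
    """A random square matrix with negative diagonal and mixed-sign
    off-diagonal entries, as a float array."""
    n = int(rng.integers(2, n_max + 1))
    a = rng.integers(-coef_max, coef_max + 1, size=(n, n)).astype(float)
    np.fill_diagonal(a, -rng.integers(1, coef_max + 1, size=n))
    return a


def metzler_part(a):
    out = a.copy()
    off = ~np.eye(a.shape[0], dtype=bool)
    out[off & (out < 0)] = 0.0
    return out


def circuitnet_matches_full(circuits_subset, full_e1):
    union = frozenset().union(*[c.e1edges for c in circuits_subset])
    return union == full_e1 and an.is_circuitnet(list(circuits_subset))


def count_matching_circuitnets(idx, full_e1):
    """Number of nonempty circuit subsets that are circuitnets whose E1
    union equals ``full_e1``."""
    n = 0
    for r in range(1, len(idx.circuits) + 1):
        for sub in itertools.combinations(idx.circuits, r):
            if circuitnet_matches_full(sub, full_e1):
                n += 1
    return n
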