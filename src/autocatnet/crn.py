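"""Reading, validation, and preprocessing of chemical reaction networks.

A chemical reaction network (CRN) is a pair (X, R) of species and reactions.
Each reaction transforms a nonnegative linear combination of species
(reactants, coefficients ``s-``) into another (products, ``s+``).  The
network is summarized by the split stoichiometric matrices ``S- >= 0`` and
``S+ >= 0`` and the net stoichiometric matrix ``S = S+ - S-``.

After preprocessing no species appears on both sides of the same reaction
(no explicit catalysts), so the sign pattern of ``S`` determines the
reactant/product roles and thereby the bipartite graph representation used
downstream.

Coefficients are stored as exact :class:`fractions.Fraction` values whenever
the input is integer or rational; floats are converted to nearby rationals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("autocatnet")

__all__ = [
    "Species",
    "Reaction",
    "CRN",
    "CRNError",
    "FormatError",
    "ValidationError",
    "CatalystError",
    "read_model",
    "read_table",
    "read_sbml",
    "write_table",
    "split_reversible",
    "remove_species",
    "resolve_catalysts",
]


class CRNError(Exception):
    """Base class for CRN-related errors."""


class FormatError(CRNError):
    """Raised when an input file cannot be parsed."""


class ValidationError(CRNError):
    """Raised when a CRN violates a structural invariant."""


class CatalystError(ValidationError):
    """Raised (under policy='error') when a species is both reactant and
    product of the same reaction."""


def _coeff(value) -> Fraction:
    """Convert a coefficient to an exact positive Fraction."""
    if isinstance(value, Fraction):
        f = value
    elif isinstance(value, int):
        f = Fraction(value)
    elif isinstance(value, float):
        if value.is_integer():
            f = Fraction(int(value))
        else:
            f = Fraction(value).limit_denominator(10**9)
    elif isinstance(value, str):
        f = Fraction(value)
    else:
        raise TypeError(f"unsupported coefficient type: {type(value)!r}")
    return f


@dataclass(frozen=True)
class Species:
    """A chemical species (metabolite)."""

    id: str
    name: str | None = None
    compartment: str | None = None


@dataclass
class Reaction:
    """An irreversible (or pre-split reversible) reaction.

    ``reactants`` and ``products`` map species ids to strictly positive
    stoichiometric coefficients.
    """

    id: str
    reactants: dict[str, Fraction] = field(default_factory=dict)
    products: dict[str, Fraction] = field(default_factory=dict)
    reversible: bool = False

    def __post_init__(self) -> None:
        self.reactants = {x: _coeff(c) for x, c in self.reactants.items()}
        self.products = {x: _coeff(c) for x, c in self.products.items()}

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.reactants), dict(self.products), self.reversible)


class CRN:
    """A chemical reaction network with fixed species/reaction ordering.

    The ordering given at construction time is preserved and used for all
    matrix representations.  ``Sminus``, ``Splus`` and ``S`` are dense float
    arrays of shape ``(|X|, |R|)``; the exact rational coefficients remain
    available on the :class:`Reaction` objects.
    """

    def __init__(self, species: Sequence[Species], reactions: Sequence[Reaction],
                 validate: bool = True):
        self.species: list[Species] = list(species)
        self.reactions: list[Reaction] = [r.copy() for r in reactions]
        self._index = {s.id: i for i, s in enumerate(self.species)}
        if validate:
            self.validate()

    # -- basic accessors ---------------------------------------------------

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def species_index(self, sid: str) -> int:
        return self._index[sid]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def sminus(self, x: str, r: Reaction | str) -> Fraction:
        rx = r if isinstance(r, Reaction) else self.reaction(r)
        return rx.reactants.get(x, Fraction(0))

    def splus(self, x: str, r: Reaction | str) -> Fraction:
        rx = r if isinstance(r, Reaction) else self.reaction(r)
        return rx.products.get(x, Fraction(0))

    # -- matrices ----------------------------------------------------------

    def _build(self, which: str) -> np.ndarray:
        m = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            side = r.reactants if which == "minus" else r.products
            for x, c in side.items():
                m[self._index[x], j] = float(c)
        return m

    @property
    def Sminus(self) -> np.ndarray:
        return self._build("minus")

    @property
    def Splus(self) -> np.ndarray:
        return self._build("plus")

    @property
    def S(self) -> np.ndarray:
        return self.Splus - self.Sminus

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        ids = self.species_ids
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate species ids: {dup}")
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise ValidationError(f"duplicate reaction ids: {dup}")
        known = set(ids)
        for r in self.reactions:
            for x, c in list(r.reactants.items()) + list(r.products.items()):
                if x not in known:
                    raise ValidationError(f"reaction {r.id!r} references unknown species {x!r}")
                if c <= 0:
                    raise ValidationError(f"nonpositive coefficient for {x!r} in {r.id!r}")
            if not r.reactants and not r.products:
                raise ValidationError(f"reaction {r.id!r} has neither reactants nor products")

    def has_catalysts(self) -> bool:
        return any(set(r.reactants) & set(r.products) for r in self.reactions)

    def assert_no_catalysts(self) -> None:
        """Check the no-digon invariant: Sminus[x,r] * Splus[x,r] = 0."""
        for r in self.reactions:
            both = sorted(set(r.reactants) & set(r.products))
            if both:
                raise ValidationError(
                    f"species {both[0]!r} is both reactant and product of {r.id!r}"
                )

    # -- equality / representation ----------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, CRN):
            return NotImplemented
        return (
            self.species == other.species
            and self.reaction_ids == other.reaction_ids
            and all(
                a.reactants == b.reactants
                and a.products == b.products
                and a.reversible == b.reversible
                for a, b in zip(self.reactions, other.reactions)
            )
        )

    def __repr__(self) -> str:
        return f"CRN(|X|={len(self.species)}, |R|={len(self.reactions)})"


# ---------------------------------------------------------------------------
# Plain table format
#
# TSV columns: reaction_id, reactants, products, reversible (0/1).
# A side is a "+"-separated list of terms, each "coef species" or just
# "species" (coef 1); coefficients may be integers or rationals like 3/2.
# Empty sides are allowed (e.g. pure outflow after species removal).
# ---------------------------------------------------------------------------

def _parse_side(text: str, rid: str, lineno: int) -> dict[str, Fraction]:
    side: dict[str, Fraction] = {}
    text = text.strip()
    if not text:
        return side
    for term in text.split("+"):
        parts = term.split()
        if len(parts) == 1:
            try:
                Fraction(parts[0])
            except ValueError:
                pass
            else:
                raise FormatError(
                    f"line {lineno}: coefficient without species in {rid!r}"
                )
            coef, sid = Fraction(1), parts[0]
        elif len(parts) == 2:
            try:
                coef = Fraction(parts[0])
            except ValueError as exc:
                raise FormatError(
                    f"line {lineno}: bad coefficient {parts[0]!r} in reaction {rid!r}"
                ) from exc
            sid = parts[1]
        else:
            raise FormatError(f"line {lineno}: cannot parse term {term.strip()!r} in {rid!r}")
        if coef <= 0:
            raise FormatError(f"line {lineno}: nonpositive coefficient in {rid!r}")
        side[sid] = side.get(sid, Fraction(0)) + coef
    return side


def _format_side(side: Mapping[str, Fraction]) -> str:
    terms = []
    for x in side:  # preserve insertion order
        c = side[x]
        terms.append(x if c == 1 else f"{c} {x}")
    return " + ".join(terms)


def read_table(path: str | Path) -> CRN:
    """Parse the plain TSV reaction-list format."""
    path = Path(path)
    reactions: list[Reaction] = []
    species_order: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0].strip().lower() == "reaction_id":
                continue  # header
            if len(cols) < 4:
                raise FormatError(f"line {lineno}: expected 4 tab-separated columns")
            rid = cols[0].strip()
            reactants = _parse_side(cols[1], rid, lineno)
            products = _parse_side(cols[2], rid, lineno)
            rev = cols[3].strip()
            if rev not in {"0", "1"}:
                raise FormatError(f"line {lineno}: reversible flag must be 0 or 1")
            reactions.append(Reaction(rid, reactants, products, rev == "1"))
            for x in list(reactants) + list(products):
                if x not in seen:
                    seen.add(x)
                    species_order.append(x)
    species = [Species(x) for x in species_order]
    return CRN(species, reactions)


def write_table(crn: CRN, path: str | Path) -> None:
    """Write a CRN in the plain TSV reaction-list format (round-trips with
    :func:`read_table` up to species metadata)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("reaction_id\treactants\tproducts\treversible\n")
        for r in crn.reactions:
            fh.write(
                f"{r.id}\t{_format_side(r.reactants)}\t{_format_side(r.products)}\t"
                f"{1 if r.reversible else 0}\n"
            )


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def read_sbml(path: str | Path) -> CRN:
    """Read an SBML Level 2/3 model (species, reactions, stoichiometries,
    reversible attribute).  Modifier species references are ignored with a
    warning; kinetic laws, gene rules etc. are not interpreted."""
    import libsbml

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    doc = libsbml.readSBML(str(path))
    nerr = doc.getNumErrors()
    fatal = [
        doc.getError(i)
        for i in range(nerr)
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if fatal:
        e = fatal[0]
        raise FormatError(
            f"SBML parse error at line {e.getLine()}: {e.getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise FormatError(f"{path}: no model element found")

    species = [
        Species(
            s.getId(),
            s.getName() or None,
            s.getCompartment() or None,
        )
        for s in model.getListOfSpecies()
    ]
    reactions: list[Reaction] = []
    for rx in model.getListOfReactions():
        if rx.getNumModifiers() > 0:
            logger.warning(
                "reaction %s: ignoring %d modifier species reference(s)",
                rx.getId(), rx.getNumModifiers(),
            )
        reactants: dict[str, Fraction] = {}
        products: dict[str, Fraction] = {}
        for i in range(rx.getNumReactants()):
            sr = rx.getReactant(i)
            c = _coeff(sr.getStoichiometry())
            reactants[sr.getSpecies()] = reactants.get(sr.getSpecies(), Fraction(0)) + c
        for i in range(rx.getNumProducts()):
            sr = rx.getProduct(i)
            c = _coeff(sr.getStoichiometry())
            products[sr.getSpecies()] = products.get(sr.getSpecies(), Fraction(0)) + c
        reactions.append(Reaction(rx.getId(), reactants, products, rx.getReversible()))
    return CRN(species, reactions)


def read_model(path: str | Path, format: str | None = None) -> CRN:
    """Read a reaction network from ``path``.

    ``format`` is ``"sbml"`` or ``"table"``; when omitted it is inferred
    from the file extension (``.xml``/``.sbml`` vs anything else).
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "table"
    if format == "sbml":
        return read_sbml(path)
    if format == "table":
        if not path.exists():
            raise FormatError(f"no such file: {path}")
        return read_table(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def split_reversible(crn: CRN) -> CRN:
    """Replace every reversible reaction by a forward/backward pair.

    The forward copy keeps the written direction (id suffixed ``_fwd``), the
    backward copy swaps sides (``_rev``).  Irreversible reactions are kept
    unchanged; the result carries no reversible flags.
    """
    out: list[Reaction] = []
    for r in crn.reactions:
        if r.reversible:
            out.append(Reaction(r.id + "_fwd", dict(r.reactants), dict(r.products), False))
            out.append(Reaction(r.id + "_rev", dict(r.products), dict(r.reactants), False))
        else:
            out.append(r.copy())
    return CRN(crn.species, out)


def remove_species(crn: CRN, blacklist: Iterable[str]) -> CRN:
    """Delete the listed species (e.g. currency/exchange metabolites).

    Ids absent from the network are ignored with a warning.  Reactions left
    with empty reactant *and* product sets are dropped.
    """
    bl = set(blacklist)
    unknown = bl - set(crn.species_ids)
    if unknown:
        logger.warning("blacklist species not in network: %s", sorted(unknown))
    species = [s for s in crn.species if s.id not in bl]
    reactions: list[Reaction] = []
    for r in crn.reactions:
        reactants = {x: c for x, c in r.reactants.items() if x not in bl}
        products = {x: c for x, c in r.products.items() if x not in bl}
        if not reactants and not products:
            logger.info("dropping emptied reaction %s", r.id)
            continue
        reactions.append(Reaction(r.id, reactants, products, r.reversible))
    return CRN(species, reactions)


def resolve_catalysts(crn: CRN, policy: str = "net") -> CRN:
    """Enforce the no-explicit-catalyst invariant.

    For each reaction with a species on both sides:

    * ``policy='error'``  -- raise :class:`CatalystError` naming the first
      offending (species, reaction) pair;
    * ``policy='net'``    -- replace by the net coefficient ``|s+ - s-|`` on
      the majority side (drop the species from the reaction if equal);
    * ``policy='drop_reaction'`` -- delete the whole reaction.
    """
    if policy not in {"error", "net", "drop_reaction"}:
        raise ValueError(f"unknown catalyst policy {policy!r}")
    reactions: list[Reaction] = []
    for r in crn.reactions:
        both = [x for x in r.reactants if x in r.products]
        if not both:
            reactions.append(r.copy())
            continue
        if policy == "error":
            raise CatalystError(
                f"species {both[0]!r} is both reactant and product of reaction {r.id!r}"
            )
        if policy == "drop_reaction":
            logger.warning("dropping reaction %s (catalytic species: %s)", r.id, both)
            continue
        # policy == "net"
        logger.warning("netting catalytic species %s in reaction %s", both, r.id)
        reactants = dict(r.reactants)
        products = dict(r.products)
        for x in both:
            net = products[x] - reactants[x]
            del reactants[x]
            del products[x]
            if net > 0:
                products[x] = net
            elif net < 0:
                reactants[x] = -net
        if not reactants and not products:
            logger.warning("dropping emptied reaction %s", r.id)
            continue
        reactions.append(Reaction(r.id, reactants, products, r.reversible))
    out = CRN(crn.species, reactions)
    out.assert_no_catalysts()
    return out
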