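# Methods

## Model and assumptions

The package operates on catalyst-free CRNs: after preprocessing, no species
is both reactant and product of the same reaction, so the sign pattern of
the stoichiometric matrix **S** determines all roles and the bipartite
König graph has no digons.  Reversible reactions are split into a
forward/backward pair (`_fwd`/`_rev` suffixes) before analysis — the
fluffle theory is built on directed reactant/product roles.  Explicitly
catalytic reactions are resolved by policy: `net` (default, replace by the
net coefficient; genome-scale models routinely carry cofactor
carry-through), `error` (strict semantics), or `drop_reaction`.
Blacklisted species (currency and exchange metabolites) are removed before
splitting; reactions emptied on both sides are dropped, one-sided reactions
are kept (they become pure in/outflows).

Stoichiometric coefficients are exact rationals (`fractions.Fraction`)
end-to-end; float inputs are converted to nearby rationals.  CS matrices
carry both the exact entries and a float view for numerics.

## Correctness structure

The enumeration rests on three equivalences used as implemented
invariants, each covered by tests:

* E1 edge sets of fluffles are perfect matchings, and the matching alone
  determines the CS matrix; classes are therefore keyed by the frozen E1
  set (matrix identity is column-order-free, so no row ordering enters the
  key).
* K(κ) is a strong block ⇔ the Metzler part of **S**[κ] is irreducible.
  The assembly only ever produces strong blocks, and `classify_class`
  re-derives irreducibility from the matrix and asserts it.
* A union of a fluffle with a circuit is a fluffle ⇔ the vertex overlap is
  nonempty and equals the vertices of the shared E1 edges.  This makes the
  breadth-first assembly purely set-based: no graph structures are
  maintained per class.

Completeness (every class is reachable by adding one circuit to a smaller
class's representative) is not re-proved but checked empirically: on random
networks with ≤ 6 species the assembled class set equals a brute-force
enumeration of all matchings with irreducible Metzler part, and verdicts
and cores match a definition-level LP oracle that never uses the spectral
shortcut (200 seeded networks in the acceptance suite).

Core identification deviates from pure predecessor-link traversal:
predecessor links recorded during assembly (expanded class + contributing
circuit per accepted union) underestimate the containment order, so
minimality is decided by direct subset comparison among autocatalytic class
keys — exactly matrix minimality restricted to the enumerated classes, and
cheap at realistic class counts.  The links are still used for the
containment shortcut: a Metzler class with a known autocatalytic Metzler
subset is flagged autocatalytic without a solve.  Each core is additionally
annotated with `reaction_set_minimal` for comparison with conventions that
minimize over reaction sets only.

## Numerical choices

* Spectral test: `numpy.linalg.eig` on the float view; autocatalytic ⇔
  Perron root > 1e-9.  Perron roots that are exactly zero (conservative
  subnetworks, ubiquitous with unit coefficients) compute to ~1e-13 and
  take the fast path.  Only roots in (1e-9, 1e-6) — possible in principle
  for larger rational entries — are re-decided exactly via the
  characteristic polynomial of the exact matrix (sympy real roots).
* LP test: feasibility of {v ≥ 1, **S**[κ] v ≥ 1} with `scipy` HiGHS.  Any
  strict certificate scales into this polytope, so no epsilon appears.
  Infeasibility (status 2) is a negative verdict; any other solver failure
  raises a distinct error rather than being read as a verdict.
* Matrix irreducibility for k = 1 is taken as false: a lone consumed
  species has a strictly negative 1×1 matrix and its graph x → r is not
  strongly connected; this matches the graph-side criterion and keeps the
  oracle and pipeline aligned.
* Spectral bisection: leading eigenvector of the generalized modularity
  matrix of the undirected simple shadow (antiparallel edges merged);
  eigenvector sign fixed by making its first nonzero entry positive, so
  partitions are deterministic.  Recursion stops at `max_module` vertices,
  at a non-positive leading eigenvalue, or at non-positive modularity gain.

## Tunable parameters

| parameter | meaning | default |
| --- | --- | --- |
| `max_species` | species per subnetwork (circuit cap = 2× in vertices) | unlimited |
| `min_reactions` | SCC filter: keep components with ≥ this many reactions | 2 |
| `catalyst_policy` | `net` / `error` / `drop_reaction` | `net` |
| `max_module` | spectral module size bound (enables partitioning) | off |
| `max_len_intra` / `max_len_cross` | vertex-count caps inside / across modules | from `max_species` |
| eigen tolerance | Perron-root threshold | 1e-9 |

Size caps count species (a cap of k species allows circuits of up to 2k
vertices); the vertex-count convention is available directly through the
`max_len_*` parameters for users who prefer it.

## Synthetic data

The generators define the test conditions.  `random_crn(n_species,
n_reactions, density, seed)` assigns each (species, reaction) pair the role
reactant or product with probability density/2 each, forces at least one
reactant and one product per reaction, and uses unit coefficients by
default (`coef_max` exercises non-unit entries, which are needed for
autocatalysis without species gain, e.g. doubling 2-cycles).  The oracle
comparisons run at 3–6 species, 3–8 reactions, densities 0.2–0.5 — sparse
enough to resemble metabolic connectivity, dense enough that circuits and
cores actually occur (the suites assert they were exercised).  What the
generator does not emulate: compartments, mass conservation constraints,
realistic degree distributions, or reversibility patterns of real
metabolic models; passing tests therefore establish algorithmic
correctness against the definitions, not biological calibration.
Published genome-scale counts can only be reproduced from the original
model files plus their exact removed-metabolite lists, which are not
bundled.

## Limitations

* `count_fluffles` (distinct fluffle subgraphs rather than classes) and the
  brute-force oracles are exponential and guarded; they refuse beyond a
  size threshold without an explicit opt-in.  Fluffles are counted as
  distinct subgraphs (vertex set plus full edge set), so two members of one
  class differing only in E2 edges count separately.
* The assembly is sequential; components and modules are independent work
  units, but no process pool is used at the scales exercised here.
* Centralized vs noncentralized classification of autocatalytic matrices,
  and minimal-autocatalytic-subsystem (reaction-set) enumeration, are out
  of scope; the `reaction_set_minimal` flag is provided for comparability
  only.
* Kinetics, stability, and oscillation analysis are out of scope: verdicts
  are purely stoichiometric.
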