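# autocatnet

Enumeration of irreducible autocatalytic subnetworks and autocatalytic
cores in chemical reaction networks (CRNs), for systems biologists and
origin-of-life researchers who want to locate the self-amplifying
substructures of a metabolic model rather than just test whether one
exists.

## The problem and the method

A CRN Γ = (X, R) is summarized by its stoichiometric matrix
**S** = **S**⁺ − **S**⁻.  Following the algebraic definition of
autocatalysis, a matrix **A** is *autocatalytic* when

1. there is a strictly positive vector v with **A** v > 0, and
2. every column of **A** has both a negative and a positive entry,

i.e. some positive combination of reaction fluxes produces a net surplus of
every participating species while each reaction both consumes and produces
inside the subnetwork.  A network is autocatalytic when **S** has an
autocatalytic submatrix, and an *autocatalytic core* is a minimal such
submatrix.  Cores are always square, invertible, and — after reordering
columns so the diagonal is negative — irreducible Metzler matrices.

Searching submatrices directly is hopeless at scale, so the search runs on
the bipartite **König graph** K(X, R): species vertices, reaction vertices,
reactant→reaction edges E1 (s⁻ₓᵣ > 0) and reaction→product edges E2
(s⁺ₓᵣ > 0).  A *child-selection* κ assigns each selected species a reaction
consuming it — a perfect matching inside E1 — and its k × k CS matrix
**S**[κ] has entries s⁺_{x,κ(w)} − s⁻_{x,κ(w)}.  CS matrices whose Metzler
part (negative off-diagonal entries zeroed) is irreducible correspond
exactly to *fluffles*: bipartite subgraphs with |X′| = |R′|, species
out-degree 1, reaction in-degree 1, that are strong blocks (strongly
connected, no cut vertex in the undirected shadow).  The pipeline is:

1. enumerate elementary circuits of K per strongly connected component
   (Johnson's algorithm, optionally length-capped);
2. superimpose circuits breadth-first into representatives of
   *CS-equivalence classes* of fluffles (classes share the same E1 edge
   set, hence the same CS matrix); a union is accepted iff the vertex
   overlap is nonempty and covered by shared E1 edges;
3. test each class: irreducible Metzler matrices by the sign of the Perron
   root (autocatalytic ⇔ Hurwitz-unstable), general matrices by a
   no-source/no-sink check plus LP feasibility of {v ≥ 1, **S**[κ] v ≥ 1};
4. flag cores: autocatalytic Metzler classes containing no smaller
   autocatalytic class.

A direct mode (`cores`) enumerates cores alone by seeding with Metzler
circuits (no species→reaction chords) and discarding non-Metzler unions;
large networks can additionally be decomposed by spectral (leading
eigenvector) modularity bisection, enumerating circuits exhaustively within
modules and with a separate length cap across module borders.

## Worked example

The Type V core motif — three species, reaction rᵢ converting xᵢ into the
other two species — has CS matrix

```
S[κ] = [[-1,  1,  1],
        [ 1, -1,  1],
        [ 1,  1, -1]]
```

with Perron root 1 > 0.  Running the CLI on it:

```sh
autocatnet fixtures --kind typeV -o typeV.tsv
autocatnet run -i typeV.tsv -o out
```

prints

```
species      	3
reactions    	3
components   	1
circuits     	5
classes      	4
autocatalytic	1
cores        	1
```

The König graph has five elementary circuits (three 4-cycles, two
6-cycles) collapsing into four CS-equivalence classes: three 2-species
classes with the conservative matrix [[-1, 1], [1, -1]] (Perron root 0,
not autocatalytic) and the full 3-species class above, which is
autocatalytic and, being minimal, the unique core.  `out/summary.tsv`
holds the size distribution and `out/classes.jsonl` one record per class
with its E1 key, flags, and predecessor links.

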