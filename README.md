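# efmx

Exact enumeration of **elementary flux modes (EFMs)** and **elementary flux
vectors (EFVs)** in metabolic networks — model ingestion, loss-free
stoichiometric compression, the three geometric problem formulations, two
built-in enumeration engines (double description and lexicographic reverse
search), lrs/efmtool file interoperability, and post-processing analytics.
Every stored matrix and every mode is an exact rational; no floating-point
value ever enters the enumeration path.

## The problem

A metabolic network with stoichiometric matrix *N* (metabolites × reactions)
operates at steady state when the flux vector *r* satisfies *N r* = 0 with
*r*ᵢ ≥ 0 for every irreversible reaction. After replacing each reversible
reaction by two opposed irreversible ones, the feasible set is the **flux
cone**

    FC = { r : N r = 0, r ≥ 0 }.

Its extreme rays — excluding the artifactual two-cycles made of one
forward/backward pair — are the EFMs: the support-minimal pathways from
which every steady-state flux distribution can be composed conically.
Adding inhomogeneous capacity constraints *E x* ≥ *f* (e.g. a substrate
uptake limit) turns the cone into a flux **polyhedron**

    P = { x : C x = d, E x ≥ f, x ≥ 0 },

whose extreme points are the EFVs and extreme rays the EFMs. Any polyhedron
can in turn be embedded one dimension higher as a **polyhedral cone** via a
homogenizing variable ζ (P is recovered at ζ = 1), or slack-embedded
directly into a flux cone

    N' = [ C  0  −d ;  E  −I  −f ],   r' = (x, ξ, ζ),

so every vertex-enumeration problem can be solved by a pure extreme-ray
enumerator. `efmx` implements all three formulations and the exact maps
between them, so results from any route agree vector-for-vector.

Enumeration engines:

* **ddm** — the binary null-space double description method: start from a
  rational kernel basis of *N*, enforce one nonnegativity constraint per
  iteration by conic combination of adjacent positive/negative rays, prune
  non-extreme candidates with a bitset zero-set superset test.
* **rs** — sequential lexicographic reverse search: invert the simplex
  method on the lexicographically perturbed program and walk the spanning
  tree of pivot paths depth-first, emitting vertices and unbounded edge
  directions; exact Fraction arithmetic throughout.

Before enumeration, models are compressed losslessly (dead-end metabolite
removal, kernel-blocked reaction removal, enzyme-subset merging,
conservation-relation elimination); after enumeration, modes are
decompressed exactly, two-cycles removed, split pairs merged back to signed
fluxes.

## Worked example

```python
from efmx import enumerate_efms, enumerate_efvs, BoundsTable, compute_yields
from efmx.fixtures import toy_branch

model = toy_branch()          # uptake R1 -> A; A -> B -> out (R2, R4)
                              # or A <=> C -> out (R3 reversible, R5)
efms = enumerate_efms(model)  # compress, split, enumerate, merge back
for mode in efms:
    print(mode.kind, [str(v) for v in mode.values])
```

prints the two elementary pathways (the R3/R3_rev two-cycle is removed):

```
efm ['1', '1', '0', '1', '0']
efm ['1', '0', '1', '0', '1']
```

Adding capacity bounds turns extreme rays into extreme points (EFVs):

```python
bounds = BoundsTable((("R1", "<=", 10), ("R4", ">=", 1)))
efvs, report = enumerate_efvs(model, bounds, formulation="flux_cone")
for mode in efvs:
    print(mode.kind, [str(v) for v in mode.values])
```

```
efv ['1', '1', '0', '1', '0']
efv ['10', '10', '0', '10', '0']
efv ['10', '1', '9', '1', '9']
```

The same three EFVs come back from the `polyhedral_cone` and `polyhedron`
formulations; the polyhedron route additionally reports its emission
multiplicity (`report["mean_multiplicity"]`, 1.5 here), since degenerate
vertices are emitted once per simplex basis.

The command line mirrors the library:

```
efmx fixtures toy_branch --out toy.xml
efmx pre toy.xml --out pre/                 # compress + transform + .ine
efmx enumerate pre/model.ine --out toy.ext  # ddm engine (or --engine rs)
efmx post toy.ext --records pre/ --out out/ # decompress to signed modes
efmx analyze out/modes.tsv --out ana/ --substrate R1 --target R4
```

The `.ine`/`.ext` files use the lrs dialect, so `pre` output can be handed
to an external lrs/mplrs run and its output fed back into `post` unchanged.

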