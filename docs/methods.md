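# Methods

## Model and scope

`efmx` enumerates the elementary flux modes (EFMs) and elementary flux
vectors (EFVs) of constraint-based metabolic models in exact rational
arithmetic. The steady-state assumption *N r* = 0 together with
irreversibility constraints defines a pointed polyhedral set whose extreme
elements are the modes; everything the package computes is a consequence of
that geometry, with no kinetic parameters and no objective function.

Three equivalent problem shapes are supported: the flux cone (homogeneous),
the flux polyhedron (with inhomogeneous capacity/allocation constraints
*E x* ≥ *f*), and the homogenized polyhedral cone. The transformations
between them — reversible splitting, ζ-homogenization and slack embedding —
are implemented exactly and logged in transform records, so any enumerated
mode maps back to the original signed reaction space without loss. The
three routes are required (and tested) to give identical mode sets; the
general-polyhedron route may emit degenerate vertices more than once, which
is reported as a mean multiplicity rather than silently hidden.

## Exact arithmetic

All stored matrices, H-representations and modes use `fractions.Fraction`.
SBML stoichiometries and bound values are read from the XML attribute
strings and converted digit-exactly; a float never intermediates. The two
deliberate floating-point exceptions are the LP-based *consistency* check
(flux variability of each reaction under box bounds) and the LP-based
*redundant row* test, which are diagnostics over the same feasible set and
do not feed the enumeration arithmetic. Both use scipy's HiGHS solver with
tolerance 1e-9 and box constant M = 1000 — conventional constraint-based
modelling defaults; the sources do not prescribe specific values, so these
are package choices.

Flux bounds of magnitude ≥ 1000 coming from SBML are treated as "no
constraint": they are solver defaults in published models, not capacities a
modeller chose. Only explicitly supplied bounds-table entries become
polyhedron rows.

## Compression

Four null-space reductions run in a fixed order (dead-end removal,
kernel-blocked removal, enzyme-subset merge, dependent-row removal), looped
to a fixpoint:

* a metabolite without producer or consumer forces its incident reactions
  to zero (iterated, so cascades resolve);
* a reaction whose row in an exact kernel basis of *N* is zero can carry no
  steady-state flux;
* reactions with pairwise proportional kernel rows form an enzyme subset
  with fixed flux ratios c_j and merge into one column Σ c_j S_j (a
  negative ratio between two irreversible members blocks the whole subset;
  orientation is chosen so the merged reaction runs forward);
* metabolite rows linearly dependent on earlier rows (conservation
  relations) are eliminated.

Compression operates on the signed model *before* reversible splitting,
because the enzyme-subset sign logic needs direction information. Every
step records the pre-step reaction namespace and its ratio coefficients, so
decompression is a pure replay in reverse; losslessness (identical EFM sets
with and without compression) is asserted by tests on every fixture rather
than assumed. No attempt is made to match the compressed dimensions of any
external tool — step order differs between implementations and only
losslessness is normative. Reactions carrying user bounds are protected
from removal and merging so the bound rows keep their meaning.

## Double description engine

The binary null-space variant: initialize the ray set with an exact kernel
basis in reduced echelon form (the basis is simplicial and already
nonnegative on the free coordinates), then enforce the remaining
nonnegativity constraints one coordinate at a time. At each step rays are
partitioned by sign; each adjacent (positive, negative) pair contributes
the combination r′ = r_h(p)·q − r_h(q)·p, and adjacency is decided by the
combinatorial test: a candidate is extreme iff no third ray's zero set
contains zs(p) ∩ zs(q). Zero sets over processed coordinates are stored as
integer bitsets (the observable content of "binarization"), while ray
values stay rational so the output is numeric modes. When all coordinates
fit one machine word the superset scan is vectorized over a packed uint64
array; a pure-Python path covers wider systems.

The processing order is chosen greedily to minimize |Pos|·|Neg| — the
classic guard against intermediate blow-up; the final set is provably
order-independent and the engine exposes an explicit `order` argument that
tests use to verify this. A configurable ray-count guard raises a resumable
error naming the coordinate reached instead of exhausting memory.

## Reverse search engine

A sequential lexicographic reverse search over simplex bases:

* Inequalities are relaxed by a symbolic perturbation b_i → b_i − ε^(i+1),
  which makes every dictionary nondegenerate; basic solutions are
  polynomials in ε held as sparse {power: Fraction} maps.
* Equalities are eliminated beforehand by exact Gaussian substitution;
  pointedness is checked on the reduced system and violations are rejected
  with an explicit lineality witness.
* The objective is the (minimized) sum of all inequality rows — interior to
  the dual of the recession cone whenever the input is pointed, hence
  always bounded — with the identity rows appended as lexicographic
  tie-breakers, making the optimal basis unique.
* Phase 1 adds one slack variable t with A x + t·1 ≥ b and minimizes
  (t, Σ rows, lex); a strictly feasible starting point exists by
  construction and a feasible basis is reached by an exact "crawl": walk
  along null directions of the current tight set until d independent tight
  rows accumulate.
* From the root (the unique lex-optimal basis) the engine enumerates
  children by reverse pivots: a candidate child is accepted iff the fixed
  pivot rule (lowest-index improving direction, lexicographic minimum
  ratio) maps it back to the current basis. The traversal is a tree, so no
  visited set is needed and memory stays proportional to the tree depth.

Vertices are emitted once per feasible basis; degenerate vertices of the
*original* polyhedron own several perturbed bases and therefore appear with
multiplicity in the raw stream, exactly as the duplicate phenomenon known
from polyhedron-formulation enumeration. Unbounded pivot directions emit
rays. For homogeneous inputs (a pointed cone, origin the only vertex) the
engine prints the origin once and each ray on first discovery, so cone-mode
output is duplicate-free; this is implemented with an explicit
first-discovery set rather than a local lexmin test — at package scale the
output fits comfortably in memory and the observable contract (uniqueness,
determinism) is identical. Emission order is deterministic: identical input
files produce identical streams.

The companion `brute_force_enumerate` oracle enumerates all row subsets of
size d (vertices) and d−1 (rays) and is deliberately independent of the
pivoting code; it refuses instances beyond a subset-count guard.

## Fixtures: what they emulate and what they do not

Test inputs are generated, not downloaded. The permutahedron (simple, n!
vertices) and the Birkhoff polytope of doubly stochastic matrices (highly
degenerate, n! permutation-matrix vertices) stand in for the classic
vertex-enumeration benchmarks; they probe the two regimes that
differentiate the engines — reverse search excels on simple polytopes,
double description on degenerate ones — and their factorial vertex counts
are encoding-independent ground truth. The order-7 Birkhoff polytope
(5040 vertices) exceeds the single-process desk scale of this
implementation, so the enumerated gate stops at order 6 (720 vertices,
tens of seconds) with the order-7 H-representation checked structurally;
the order-10 permutahedron is likewise asserted via its generated 1023-row
H-representation rather than a 3.6-million-vertex run.

The toy branched network (two pathways sharing an uptake, one reversible
branch) exercises splitting, two-cycle removal, compression and yields
end-to-end with hand-checkable answers. Seeded sparse random flux cones
(entries in {−3..3}, m < n ≤ 14) supply the property-test corpus; the seed
sweep provably contains degenerate instances. None of these fixtures
emulate genome-scale features — thousands of reactions, compartments,
biomass stoichiometry with awkward decimals — so green tests certify
algorithmic exactness at small scale, not performance or numerical
behaviour on published models (there is none to certify: the arithmetic is
exact at every scale it reaches).

Acceptance-style computations use 200 random cones in the test suite and
60 in the standalone script, with brute-force oracles capped at the sizes
where exhaustive enumeration stays in seconds; these sizes are package
choices balancing coverage against a desk-scale run.

## Conventions and degenerate cases

* Mode vectors: EFMs are scaled to coprime integers with orientation
  preserved (a negative entry means an originally reversible reaction runs
  backward); EFVs are actual flux vectors and are never rescaled.
* Canonical order: modes sort by support bitmask, then lexicographically by
  value; all outputs are deterministic and diffable.
* The zero flux vector is a genuine vertex of any flux polyhedron that
  contains it, and `dehomogenize` keeps it; reported mode sets drop it as
  trivial. With `--keep-two-cycles` the retained split-pair cycles surface
  as explicit net-zero EFM rows (their forward and backward half-fluxes
  cancel by construction).
* lrs dialect: `a x ≥ b` is written as the row `(−b, a)` with rows cleared
  to coprime integers; `linearity` indices are 1-based in files and 0-based
  internally. ζ is always the last column; slack variables precede it.
* Two-cycle removal deletes exactly the modes whose support equals one
  split forward/reverse pair; a genuine cycle between two distinct
  reactions is kept.
* A model that compresses to emptiness warns instead of raising; an
  infeasible H-representation is reported as such (CLI exit 1), and an
  internal contradiction (e.g. a non-two-cycle mode using both directions
  of a split pair) exits 2.

## Known limitations

* Single-threaded; no parallel tree search or MPI-style load balancing.
  The reverse-search engine visits every perturbed basis, so highly
  degenerate polytopes (Birkhoff-type) are better served by the double
  description engine, mirroring the known division of labour between the
  algorithm families.
* The double description engine accepts flux-cone-shaped input only;
  general inequality systems must go through the slack embedding (the CLI
  enforces this and points to the reverse-search engine otherwise).
* SBML writing requires coefficients with terminating decimal expansions
  (the format stores doubles); arbitrary rationals round-trip through the
  lrs and efmtool text dialects instead.
* Gene–protein–reaction rules, flux-balance objectives and minimal-medium
  computation are out of scope.
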