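"""Deterministic generators for test inputs.

Classic polytopes with known vertex counts (permutahedron, Birkhoff
polytope of doubly stochastic matrices -- both have n! vertices), a toy
branched metabolic network with two pathways, seeded random flux cones for
property testing, and nested uptake-reaction model series.  Same
parameters always yield a bit-identical fixture.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .geometry import FluxCone, GeneralHRep
from .model import MetabolicModel

ZERO = Fraction(0)
ONE = Fraction(1)


def permutahedron(n: int) -> GeneralHRep:
    """H-representation of the permutahedron on (1..n).

    One linearity (total sum) plus one facet per proper nonempty subset S:
    ``sum_{i in S} x_i >= 1 + 2 + ... + |S|``.  Vertices are exactly the
    n! permutations of (1..n); the polytope is simple (dimension n-1).
    Subset rows are generated in ascending bitmask order.
    """
    if not 2 <= n <= 10:
        raise ValueError("permutahedron supports 2 <= n <= 10")
    A: list[tuple] = []
    b: list[Fraction] = []
    A.append(tuple(ONE for _ in range(n)))
    b.append(Fraction(n * (n + 1), 2))
    for mask in range(1, 2**n - 1):
        size = mask.bit_count()
        row = tuple(ONE if (mask >> i) & 1 else ZERO for i in range(n))
        A.append(row)
        b.append(Fraction(size * (size + 1), 2))
    return GeneralHRep(
        tuple(A), tuple(b), frozenset({0}),
        tuple(f"x{i + 1}" for i in range(n)), f"perm{n}",
    )


def birkhoff(n: int) -> GeneralHRep:
    """H-representation of the Birkhoff polytope of n x n doubly
    stochastic matrices: n^2 nonnegative variables with 2n unit row/column
    sums.  Vertices are the n! permutation matrices (highly degenerate for
    n >= 3)."""
    if not 2 <= n <= 7:
        raise ValueError("birkhoff supports 2 <= n <= 7")
    nv = n * n
    A: list[tuple] = []
    b: list[Fraction] = []
    lin = set()
    for i in range(n):  # row sums
        lin.add(len(A))
        A.append(tuple(ONE if j // n == i else ZERO for j in range(nv)))
        b.append(ONE)
    for c in range(n):  # column sums
        lin.add(len(A))
        A.append(tuple(ONE if j % n == c else ZERO for j in range(nv)))
        b.append(ONE)
    for j in range(nv):  # nonnegativity
        A.append(tuple(ONE if k == j else ZERO for k in range(nv)))
        b.append(ZERO)
    ids = tuple(f"x{j // n + 1}{j % n + 1}" for j in range(nv))
    return GeneralHRep(tuple(A), tuple(b), frozenset(lin), ids, f"bv{n}")


def toy_branch() -> MetabolicModel:
    """Minimal branched network: uptake R1 feeds A, which exits either via
    R2 (A->B) and R4 (B out) or via the reversible R3 (A<=>C) and R5
    (C out).  Exactly two EFMs after two-cycle removal: {R1,R2,R4} and
    {R1,R3,R5}."""
    mets = ("A", "B", "C")
    rxns = ("R1", "R2", "R3", "R4", "R5")
    S = (
        (ONE, -ONE, -ONE, ZERO, ZERO),   # A
        (ZERO, ONE, ZERO, -ONE, ZERO),   # B
        (ZERO, ZERO, ONE, ZERO, -ONE),   # C
    )
    rev = (False, False, True, False, False)
    return MetabolicModel(mets, rxns, S, rev)


def random_flux_cone(m: int, n: int, density: float = 0.4,
                     seed: int = 0) -> FluxCone:
    """Seeded sparse random stoichiometry with entries in {-3..3}.

    Reproducible: identical parameters give identical matrices.  Across
    seeds the family contains both degenerate and non-degenerate cones.
    """
    if not (0 <= m < n <= 14):
        raise ValueError("require 0 <= m < n <= 14")
    rng = np.random.default_rng(seed)
    while True:
        mask = rng.random((m, n)) < density
        vals = rng.integers(-3, 4, size=(m, n))
        M = np.where(mask, vals, 0)
        if m == 0 or (np.any(M != 0, axis=1).all()):
            break
    rows = tuple(tuple(Fraction(int(x)) for x in row) for row in M)
    return FluxCone(rows, tuple(f"R{j + 1}" for j in range(n)),
                    name=f"rand_m{m}_n{n}_s{seed}")


def nested_uptake_series(model: MetabolicModel, ordered_uptake_ids):
    """Series of nested sub-models differing by one uptake reaction each.

    ``models[0]`` has every listed uptake removed; ``models[i]`` adds back
    the first i ids.  Each listed reaction must be an uptake: a single
    nonzero stoichiometric entry, positive (pure source).  EFM sets of the
    series are nested.
    """
    ids = list(ordered_uptake_ids)
    for rid in ids:
        j = model.reaction_index(rid)
        col = model.column(j)
        nonzero = [x for x in col if x]
        if len(nonzero) != 1 or nonzero[0] <= 0:
            raise ValueError(f"{rid} is not an uptake reaction")
    out = []
    for i in range(len(ids) + 1):
        included = set(ids[:i])
        keep = [
            j for j, rid in enumerate(model.reaction_ids)
            if rid not in ids or rid in included
        ]
        out.append(
            MetabolicModel(
                metabolite_ids=model.metabolite_ids,
                reaction_ids=tuple(model.reaction_ids[j] for j in keep),
                S=tuple(
                    tuple(row[j] for j in keep) for row in model.S
                ),
                rev=tuple(model.rev[j] for j in keep),
                lb=tuple(model.lb[j] for j in keep),
                ub=tuple(model.ub[j] for j in keep),
            )
        )
    return out
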