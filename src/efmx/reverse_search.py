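"""Sequential lexicographic reverse-search vertex/ray enumeration.

The engine inverts the simplex method: it finds the unique optimal basis of
a lexicographically perturbed, lexicographically tie-broken linear program
and then walks the spanning tree of simplex pivot paths depth-first,
discovering every feasible basis exactly once.  Degeneracy is handled by
the symbolic perturbation ``b_i -> b_i - eps^(i+1)`` (each inequality
relaxed by its own infinitesimal), which makes every dictionary
nondegenerate; basic solutions become polynomials in eps, represented
sparsely as {eps-power: Fraction} dicts.

Equalities are eliminated by exact Gaussian substitution before the search;
vertices and rays are mapped back to the input variable space afterwards.

A vertex is emitted once per feasible basis (degenerate vertices of the
original polyhedron own several perturbed bases, so raw emissions may
contain duplicates -- the cone formulations are free of this); an unbounded
pivot direction emits a ray.  Deduplicated sets are returned alongside the
raw emission streams.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb

from ._linalg import Vec, invert, nullspace, rref
from .postprocess import FluxMode, ModeSet, _normalize_ray

ZERO = Fraction(0)
ONE = Fraction(1)


class InfeasibleError(ValueError):
    """The H-representation has an empty feasible set."""


class NotPointedError(ValueError):
    """The feasible set contains a line; reverse search requires pointedness."""

    def __init__(self, witness: Vec):
        self.witness = witness
        super().__init__(
            "input is not pointed; lineality direction "
            f"({', '.join(map(str, witness))})"
        )


# ---------------------------------------------------------------------------
# sparse eps-polynomial helpers (keys: 0 = constant, k >= 1 = eps^k)


def _lex_sign(sv: dict) -> int:
    for k in sorted(sv):
        v = sv[k]
        if v:
            return 1 if v > 0 else -1
    return 0


def _ratio_less(s1: dict, a1: Fraction, s2: dict, a2: Fraction) -> bool:
    """True iff s1/a1 < s2/a2 lexicographically (a1, a2 > 0)."""
    for k in sorted(set(s1) | set(s2)):
        lhs = s1.get(k, ZERO) * a2
        rhs = s2.get(k, ZERO) * a1
        if lhs != rhs:
            return lhs < rhs
    return False


def _lex_vec_sign(v: tuple) -> int:
    for x in v:
        if x:
            return 1 if x > 0 else -1
    return 0


# ---------------------------------------------------------------------------
# linearity elimination


@dataclass
class _Reduced:
    A: list  # inequality rows over the reduced variables
    b: list
    x0: Vec  # particular solution in input space
    F: list  # input_dim x d basis of the equality nullspace (columns)
    d: int


def _eliminate(rep) -> _Reduced:
    g = rep.as_general()
    nv = g.n_vars
    lin = sorted(g.linearity_rows)
    aug = [list(g.A[i]) + [g.b[i]] for i in lin]
    red, pivots = rref(aug, nv + 1)
    if nv in pivots:
        raise InfeasibleError("equality rows are inconsistent")
    free = [c for c in range(nv) if c not in pivots]
    x0 = [ZERO] * nv
    for r, pc in enumerate(pivots):
        x0[pc] = red[r][nv]
    F = [[ZERO] * len(free) for _ in range(nv)]
    for idx, fc in enumerate(free):
        F[fc][idx] = ONE
        for r, pc in enumerate(pivots):
            F[pc][idx] = -red[r][fc]
    A, b = [], []
    for i in range(len(g.A)):
        if i in g.linearity_rows:
            continue
        row = g.A[i]
        a_new = tuple(
            sum(row[r] * F[r][c] for r in range(nv) if row[r])
            for c in range(len(free))
        )
        beta = g.b[i] - sum(row[r] * x0[r] for r in range(nv) if row[r])
        if any(a_new):
            A.append(a_new)
            b.append(beta)
        elif beta > 0:
            raise InfeasibleError(f"constraint row {i} reduces to 0 >= {beta}")
    return _Reduced(A, b, tuple(x0), F, len(free))


# ---------------------------------------------------------------------------
# the perturbed lexicographic LP


class _LexLP:
    """Pointed LP ``min W x  s.t.  A x >= b - eps`` in dictionary form."""

    def __init__(self, A, b, primary_rows):
        self.A = [tuple(row) for row in A]
        self.b = list(b)
        self.m = len(A)
        self.d = len(A[0]) if A else 0
        eye = [
            tuple(ONE if j == i else ZERO for j in range(self.d))
            for i in range(self.d)
        ]
        self.W = [tuple(r) for r in primary_rows] + eye

    # -- node data -------------------------------------------------------
    def node(self, C: tuple):
        """Tableau data for cobasis C, or None if A_C is singular."""
        U = invert([self.A[c] for c in C])
        if U is None:
            return None
        d = self.d
        # X columns: constant part, then eps^(c+1) parts for c in C
        x_const = [
            sum(U[r][k] * self.b[C[k]] for k in range(d)) for r in range(d)
        ]
        x_eps = [[-U[r][k] for r in range(d)] for k in range(d)]
        dirs = [tuple(U[r][k] for r in range(d)) for k in range(d)]
        return U, x_const, x_eps, dirs

    def slack(self, i: int, C: tuple, x_const, x_eps) -> dict:
        a = self.A[i]
        sv: dict = {}
        c0 = sum(a[r] * x_const[r] for r in range(self.d) if a[r]) - self.b[i]
        if c0:
            sv[0] = c0
        for k, c in enumerate(C):
            v = sum(a[r] * x_eps[k][r] for r in range(self.d) if a[r])
            if v:
                sv[c + 1] = v
        sv[i + 1] = sv.get(i + 1, ZERO) + ONE
        if not sv[i + 1]:
            del sv[i + 1]
        return sv

    def w_of(self, u: tuple) -> tuple:
        return tuple(
            sum(wr[r] * u[r] for r in range(self.d) if u[r]) for wr in self.W
        )

    def ratio_argmin(self, C: tuple, u: tuple, x_const, x_eps):
        """First blocking row moving along +u, or None if unbounded."""
        best = None
        Cset = set(C)
        for i in range(self.m):
            if i in Cset:
                continue
            alpha = sum(self.A[i][r] * u[r] for r in range(self.d) if u[r])
            if alpha >= 0:
                continue
            s = self.slack(i, C, x_const, x_eps)
            a = -alpha
            if best is None or _ratio_less(s, a, best[1], best[2]):
                best = (i, s, a)
        return None if best is None else best[0]

    # -- simplex to the root --------------------------------------------
    def pivot_choice(self, C: tuple, dirs) -> int | None:
        """Position k of the entering direction per the fixed rule
        (smallest cobasis row index with lex-negative objective change)."""
        for k in range(self.d):
            if _lex_vec_sign(self.w_of(dirs[k])) < 0:
                return k
        return None

    def optimize(self, C: tuple) -> tuple:
        guard = 0
        while True:
            guard += 1
            if guard > 100000:
                raise RuntimeError("simplex failed to converge (internal)")
            data = self.node(C)
            if data is None:
                raise RuntimeError("singular basis during simplex (internal)")
            _, x_const, x_eps, dirs = data
            k = self.pivot_choice(C, dirs)
            if k is None:
                return C
            i_star = self.ratio_argmin(C, dirs[k], x_const, x_eps)
            if i_star is None:
                raise RuntimeError(
                    "lex objective unbounded; input not pointed (internal)"
                )
            C = tuple(sorted(set(C) - {C[k]} | {i_star}))

    # -- crawl: feasible point -> lex-feasible basis ---------------------
    def crawl_to_basis(self, z0) -> tuple:
        d = self.d
        X = [{0: z0[r]} for r in range(d)] if d else []
        tight: list[int] = []
        while len(tight) < d:
            ns = nullspace([self.A[t] for t in tight], d) if tight else [
                tuple(ONE if j == 0 else ZERO for j in range(d))
            ]
            if not ns:
                raise RuntimeError("tight rows lost rank (internal)")
            u = ns[0]
            for attempt in (u, tuple(-x for x in u)):
                blocking = []
                for i in range(self.m):
                    if i in tight:
                        continue
                    alpha = sum(
                        self.A[i][r] * attempt[r] for r in range(d) if attempt[r]
                    )
                    if alpha < 0:
                        blocking.append((i, alpha))
                if blocking:
                    u = attempt
                    break
            else:
                raise RuntimeError("lineality direction found while crawling")
            best = None
            for i, alpha in blocking:
                s = self._point_slack(i, X)
                a = -alpha
                if best is None or _ratio_less(s, a, best[1], best[2]):
                    best = (i, s, a)
            i_star, s_star, a_star = best
            t_star = {k: v / a_star for k, v in s_star.items()}
            for r in range(d):
                if u[r]:
                    for k, v in t_star.items():
                        X[r][k] = X[r].get(k, ZERO) + u[r] * v
                        if not X[r][k]:
                            del X[r][k]
            tight.append(i_star)
        return tuple(sorted(tight))

    def _point_slack(self, i: int, X) -> dict:
        a = self.A[i]
        sv: dict = {}
        for r in range(self.d):
            if not a[r]:
                continue
            for k, v in X[r].items():
                sv[k] = sv.get(k, ZERO) + a[r] * v
        sv[0] = sv.get(0, ZERO) - self.b[i]
        sv[i + 1] = sv.get(i + 1, ZERO) + ONE
        return {k: v for k, v in sv.items() if v}


# ---------------------------------------------------------------------------
# public engine


@dataclass
class RSResult:
    """Raw emission streams plus deduplicated vertex/ray sets."""

    var_ids: tuple[str, ...]
    vertex_emissions: list
    ray_emissions: list
    vertices: ModeSet
    rays: ModeSet
    n_bases: int

    @property
    def emission_counts(self) -> dict:
        counts: dict = {}
        for v in self.vertex_emissions:
            counts[("vertex", v)] = counts.get(("vertex", v), 0) + 1
        for r in self.ray_emissions:
            counts[("ray", r)] = counts.get(("ray", r), 0) + 1
        return counts


def enumerate_vertices_rs(rep, max_bases: int | None = None) -> RSResult:
    """Enumerate all vertices and extreme rays of a pointed H-representation.

    *rep* is anything with ``as_general()`` (GeneralHRep, PolyhedronH,
    ConeH, FluxCone).  Raises :class:`InfeasibleError` on empty input and
    :class:`NotPointedError` (with a lineality witness) on non-pointed
    input.  Deterministic: identical input yields identical emission order.
    """
    red = _eliminate(rep)
    g = rep.as_general()
    var_ids = g.var_ids
    nv = len(red.x0)

    def back_point(z) -> Vec:
        return tuple(
            red.x0[r]
            + sum(red.F[r][c] * z[c] for c in range(red.d) if z[c])
            for r in range(nv)
        )

    def back_ray(u) -> Vec:
        return _normalize_ray(
            tuple(
                sum(red.F[r][c] * u[c] for c in range(red.d) if u[c])
                for r in range(nv)
            )
        )

    if red.d == 0:
        # equalities pin a single point; rows were checked during elimination
        v = back_point(())
        vs = [v]
        return RSResult(
            var_ids, vs, [],
            ModeSet(var_ids, (FluxMode(v, "efv"),)),
            ModeSet(var_ids, ()), 1,
        )

    lin_basis = nullspace(red.A, red.d)
    if lin_basis:
        raise NotPointedError(back_ray(lin_basis[0]))

    sum_row = tuple(
        sum(row[c] for row in red.A) for c in range(red.d)
    )

    # phase 1: find a feasible point
    if all(beta <= 0 for beta in red.b):
        z0 = (ZERO,) * red.d
    else:
        A_aug = [tuple(row) + (ONE,) for row in red.A]
        A_aug.append((ZERO,) * red.d + (ONE,))
        b_aug = list(red.b) + [ZERO]
        t_row = (ZERO,) * red.d + (ONE,)
        sum_aug = tuple(
            sum(row[c] for row in A_aug) for c in range(red.d + 1)
        )
        lp1 = _LexLP(A_aug, b_aug, [t_row, sum_aug])
        t0 = max(beta for beta in red.b) + 1
        start = lp1.crawl_to_basis([ZERO] * red.d + [t0])
        root1 = lp1.optimize(start)
        data = lp1.node(root1)
        _, x_const, _, _ = data
        if x_const[red.d] > 0:
            raise InfeasibleError(
                f"no feasible point (phase-1 optimum {x_const[red.d]})"
            )
        z0 = tuple(x_const[: red.d])

    lp = _LexLP(red.A, red.b, [sum_row])
    start = lp.crawl_to_basis(list(z0))
    root = lp.optimize(start)

    # cone mode: homogeneous input => origin is the only vertex and every
    # basis is a basis of it.  The vertex is printed once (at the root) and
    # each ray on first discovery, matching lrs's uniqueness guarantee for
    # pointed cones.  Inhomogeneous inputs emit per basis; degenerate
    # vertices/rays then appear with multiplicity.
    cone_mode = all(beta == 0 for beta in red.b)

    vertex_emissions: list[Vec] = []
    ray_emissions: list[Vec] = []
    seen_rays: set[Vec] = set()
    n_bases = 0
    stack = [root]
    while stack:
        C = stack.pop()
        n_bases += 1
        if max_bases is not None and n_bases > max_bases:
            raise RuntimeError(
                f"basis count exceeded guard {max_bases}; "
                "raise max_bases to continue"
            )
        data = lp.node(C)
        _, x_const, x_eps, dirs = data
        if not cone_mode or n_bases == 1:
            vertex_emissions.append(back_point(x_const))
        children = []
        for k in range(lp.d):
            wk = lp.w_of(dirs[k])
            sign = _lex_vec_sign(wk)
            if sign < 0:
                continue  # towards the root: parent edge or sibling subtree
            i_star = lp.ratio_argmin(C, dirs[k], x_const, x_eps)
            if i_star is None:
                ray = back_ray(dirs[k])
                if cone_mode:
                    if ray not in seen_rays:
                        seen_rays.add(ray)
                        ray_emissions.append(ray)
                else:
                    ray_emissions.append(ray)
                continue
            C_child = tuple(sorted(set(C) - {C[k]} | {i_star}))
            child_data = lp.node(C_child)
            if child_data is None:
                continue
            _, _, _, dirs_c = child_data
            kc = lp.pivot_choice(C_child, dirs_c)
            if kc is not None and C_child[kc] == i_star:
                children.append(C_child)
        stack.extend(reversed(children))

    vset = ModeSet(
        var_ids, tuple(FluxMode(v, "efv") for v in set(vertex_emissions))
    )
    rset = ModeSet(
        var_ids, tuple(FluxMode(r, "efm") for r in set(ray_emissions))
    )
    return RSResult(
        var_ids, vertex_emissions, ray_emissions, vset, rset, n_bases
    )


# ---------------------------------------------------------------------------
# exhaustive oracle


def brute_force_enumerate(rep, max_subsets: int = 500_000):
    """All vertices and extreme rays by exhaustive basis enumeration.

    Vertices: every feasible basic solution over row subsets of size d.
    Rays: every feasible one-dimensional nullspace direction of subsets of
    size d-1.  Exact and deduplicated; refuses instances beyond the size
    guard (exponential -- a test oracle, not an engine).
    """
    red = _eliminate(rep)
    g = rep.as_general()
    var_ids = g.var_ids
    nv = len(red.x0)
    d, m = red.d, len(red.A)
    if d > 0 and (comb(m, d) > max_subsets or comb(m, max(d - 1, 0)) > max_subsets):
        raise ValueError(f"instance too large for brute force (C({m},{d}))")

    def back_point(z):
        return tuple(
            red.x0[r]
            + sum(red.F[r][c] * z[c] for c in range(d) if z[c])
            for r in range(nv)
        )

    def back_ray(u):
        return _normalize_ray(
            tuple(
                sum(red.F[r][c] * u[c] for c in range(d) if u[c])
                for r in range(nv)
            )
        )

    if d == 0:
        v = back_point(())
        return (
            ModeSet(var_ids, (FluxMode(v, "efv"),)),
            ModeSet(var_ids, ()),
        )

    vertices = set()
    for S in combinations(range(m), d):
        U = invert([red.A[i] for i in S])
        if U is None:
            continue
        z = tuple(
            sum(U[r][k] * red.b[S[k]] for k in range(d)) for r in range(d)
        )
        feasible = all(
            sum(red.A[i][r] * z[r] for r in range(d) if z[r]) >= red.b[i]
            for i in range(m)
        )
        if feasible:
            vertices.add(back_point(z))

    rays = set()
    if vertices:
        for S in combinations(range(m), d - 1) if d >= 1 else ():
            ns = nullspace([red.A[i] for i in S], d)
            if len(ns) != 1:
                continue
            for u in (ns[0], tuple(-x for x in ns[0])):
                vals = [
                    sum(red.A[i][r] * u[r] for r in range(d) if u[r])
                    for i in range(m)
                ]
                if all(v >= 0 for v in vals) and any(vals):
                    rays.add(back_ray(u))
                    break

    return (
        ModeSet(var_ids, tuple(FluxMode(v, "efv") for v in vertices)),
        ModeSet(var_ids, tuple(FluxMode(r, "efm") for r in rays)),
    )
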