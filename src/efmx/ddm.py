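"""Binary null-space double description method for pointed flux cones.

The engine starts from an exact rational kernel basis of the stoichiometric
matrix (a simplicial cone, trivially described by its basis vectors) and
enforces one nonnegativity constraint per iteration: rays negative at the
current coordinate are replaced by conic combinations with positive rays,
and non-extreme candidates are pruned by the combinatorial zero-set
superset (adjacency) test.  Zero sets over processed coordinates are kept
as integer bitsets -- the observable content of efmtool's "binarization" --
while ray values stay fully rational.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from typing import Iterable, Sequence

from ._linalg import nullspace, rank
from .geometry import FluxCone
from .postprocess import FluxMode, ModeSet, _normalize_ray

ZERO = Fraction(0)


def _adjacent_pairs(zsets, pos, neg, n):
    """Adjacent (positive, negative) ray pairs by the zero-set test.

    A candidate combination is kept iff no third ray's zero set contains
    ``zs_p & zs_q`` (then p and q span a 2-face and their combination is an
    extreme ray of the next cone).  Identical zero sets arising from
    different pairs are generated once.  Returns ``[(zs, p, q), ...]``.

    The scan is vectorized with packed-uint64 bitsets when all coordinates
    fit one word; a pure-Python loop covers wider cones.
    """
    if not pos or not neg:
        return []
    if n <= 63:
        import numpy as np

        Z = np.array(zsets, dtype=np.uint64)
        zp = Z[pos]
        zq = Z[neg]
        cand: dict[int, tuple[int, int]] = {}
        for a, p in enumerate(pos):
            inter = zp[a] & zq
            for b, z in enumerate(inter.tolist()):
                if z not in cand:
                    cand[z] = (p, neg[b])
        kept = []
        for z, (p, q) in cand.items():
            zz = np.uint64(z)
            if int(((Z & zz) == zz).sum()) == 2:
                kept.append((z, p, q))
        return kept

    cand = {}
    for p in pos:
        zsp = zsets[p]
        for q in neg:
            z = zsp & zsets[q]
            if z not in cand:
                cand[z] = (p, q)
    kept = []
    for z, (p, q) in cand.items():
        ok = True
        for k, zk in enumerate(zsets):
            if k != p and k != q and (zk & z) == z:
                ok = False
                break
        if ok:
            kept.append((z, p, q))
    return kept


class RayLimitExceeded(RuntimeError):
    """Raised when the intermediate ray set outgrows the configured guard.

    Carries the coordinate index reached so a caller can retry with a
    larger guard.
    """

    def __init__(self, row: int, count: int, limit: int):
        self.row = row
        super().__init__(
            f"ray count {count} exceeded guard {limit} while processing "
            f"coordinate {row}"
        )


def enumerate_efms_ddm(
    cone: FluxCone,
    max_rays: int | None = None,
    order: list[int] | None = None,
) -> ModeSet:
    """Enumerate the extreme rays of ``{r : N r = 0, r >= 0}``.

    Returns all extreme rays (including two-cycle modes of split models) as
    gcd-normalized EFMs in canonical order.  The cone is pointed by
    construction (full nonnegativity), so the zero-set adjacency test is
    exact.  ``max_rays`` guards against intermediate blow-up.

    By default each iteration processes the unresolved coordinate
    minimizing ``|Pos| * |Neg|`` (bounding candidate growth); *order*
    overrides this with an explicit coordinate sequence -- the final mode
    set is independent of the choice.
    """
    from ._linalg import rref

    n = cone.n_vars
    red, pivots = rref(list(cone.N), n)
    free = [c for c in range(n) if c not in pivots]
    if not free:
        return ModeSet(cone.reaction_ids, ())
    kernel = []
    for fc in free:
        v = [ZERO] * n
        v[fc] = Fraction(1)
        for r, pc in enumerate(pivots):
            v[pc] = -red[r][fc]
        kernel.append(tuple(v))

    # initial simplicial description: basis vectors, nonneg on free coords
    processed_mask = 0
    for j in free:
        processed_mask |= 1 << j

    def zero_bits(vec, mask):
        bits = 0
        j = 0
        m = mask
        while m:
            if m & 1 and not vec[j]:
                bits |= 1 << j
            m >>= 1
            j += 1
        return bits

    rays = [list(v) for v in kernel]
    zsets = [zero_bits(v, processed_mask) for v in rays]
    remaining = [j for j in range(n) if not (processed_mask >> j) & 1]

    forced = [h for h in (order or []) if not (processed_mask >> h) & 1]
    if order is not None and set(forced) != set(remaining):
        raise ValueError("order must cover exactly the unresolved coordinates")

    while remaining:
        if forced:
            h = forced.pop(0)
        else:
            # heuristic: process the coordinate minimizing |Pos| * |Neg|
            best = None
            for h_cand in remaining:
                npos = sum(1 for r in rays if r[h_cand] > 0)
                nneg = sum(1 for r in rays if r[h_cand] < 0)
                cost = npos * nneg
                if best is None or cost < best[0]:
                    best = (cost, h_cand)
            h = best[1]
        remaining.remove(h)

        pos = [k for k, r in enumerate(rays) if r[h] > 0]
        neg = [k for k, r in enumerate(rays) if r[h] < 0]
        zero = [k for k, r in enumerate(rays) if not r[h]]
        bit_h = 1 << h

        kept = _adjacent_pairs(zsets, pos, neg, n)

        new_rays = [rays[k] for k in pos] + [rays[k] for k in zero]
        new_zsets = [zsets[k] for k in pos] + [zsets[k] | bit_h for k in zero]
        for zs, p, q in kept:
            a, b = rays[p][h], rays[q][h]
            combo = [a * rays[q][j] - b * rays[p][j] for j in range(n)]
            combo = list(_normalize_ray(combo))
            new_rays.append(combo)
            new_zsets.append((zs | bit_h))
        rays, zsets = new_rays, new_zsets
        processed_mask |= bit_h
        if max_rays is not None and len(rays) > max_rays:
            raise RayLimitExceeded(h, len(rays), max_rays)

    modes = tuple(FluxMode(tuple(r), "efm") for r in rays)
    return ModeSet(cone.reaction_ids, modes)


# ---------------------------------------------------------------------------
# independent oracle


def efm_support_test(N: Sequence[Sequence], support: Iterable[int],
                     n: int | None = None) -> bool:
    """True iff *support* is the support of an EFM of ``{Nr=0, r>=0}``.

    The restricted kernel must be one-dimensional with a generator nonzero
    on the whole support and of uniform sign (so a nonnegative
    representative exists).  An empty support is not elementary.
    """
    support = sorted(set(support))
    if not support:
        return False
    rows = list(N)
    if n is None:
        n = len(rows[0]) if rows else max(support) + 1
    sub = [[row[j] for j in support] for row in rows]
    basis = nullspace(sub, len(support))
    if len(basis) != 1:
        return False
    gen = basis[0]
    if any(not x for x in gen):
        return False
    return all(x > 0 for x in gen) or all(x < 0 for x in gen)


def brute_force_efms(N: Sequence[Sequence], n: int) -> set[tuple]:
    """All EFMs of ``{Nr=0, r>=0}`` by exhaustive support search.

    An EFM support satisfies ``|support| = rank(N_support) + 1``, so only
    subsets up to ``rank(N) + 1`` need scanning.  Returns gcd-normalized
    nonnegative generator tuples.  Exponential; for test oracles only.
    """
    rows = list(N)
    max_size = min(n, rank(rows, n) + 1)
    out: set[tuple] = set()
    for k in range(1, max_size + 1):
        for support in combinations(range(n), k):
            sub = [[row[j] for j in support] for row in rows]
            basis = nullspace(sub, k)
            if len(basis) != 1:
                continue
            gen = basis[0]
            if any(not x for x in gen):
                continue
            if all(x > 0 for x in gen) or all(x < 0 for x in gen):
                vec = [ZERO] * n
                sign = 1 if gen[0] > 0 else -1
                for idx, j in enumerate(support):
                    vec[j] = sign * gen[idx]
                out.add(_normalize_ray(vec))
    return out
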