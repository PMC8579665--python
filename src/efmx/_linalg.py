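"""Exact rational linear algebra on ``fractions.Fraction`` matrices.

Matrices are lists of row tuples/lists of :class:`~fractions.Fraction`.
These routines are deliberately dependency-free and allocation-light: the
brute-force elementarity oracle calls :func:`nullspace` once per candidate
support, so constant factors matter more than asymptotics here.
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd
from typing import Iterable, Sequence

Vec = tuple[Fraction, ...]

ZERO = Fraction(0)
ONE = Fraction(1)


def frac_rows(rows: Iterable[Sequence]) -> list[list[Fraction]]:
    """Copy *rows* into mutable lists of Fractions."""
    return [[Fraction(x) for x in row] for row in rows]


def rref(rows: Iterable[Sequence], ncols: int | None = None):
    """Reduced row echelon form.

    Returns ``(reduced_rows, pivot_cols)`` where zero rows are dropped.
    """
    m = frac_rows(rows)
    if not m:
        return [], []
    n = ncols if ncols is not None else len(m[0])
    pivots: list[int] = []
    r = 0
    for c in range(n):
        if r >= len(m):
            break
        piv = None
        for i in range(r, len(m)):
            if m[i][c]:
                piv = i
                break
        if piv is None:
            continue
        m[r], m[piv] = m[piv], m[r]
        inv = ONE / m[r][c]
        if inv != 1:
            m[r] = [x * inv for x in m[r]]
        row_r = m[r]
        for i in range(len(m)):
            if i != r and m[i][c]:
                f = m[i][c]
                mi = m[i]
                for j in range(c, n):
                    if row_r[j]:
                        mi[j] -= f * row_r[j]
        pivots.append(c)
        r += 1
    return m[:r], pivots


def rank(rows: Iterable[Sequence], ncols: int | None = None) -> int:
    return len(rref(rows, ncols)[1])


def nullspace(rows: Iterable[Sequence], ncols: int) -> list[Vec]:
    """Exact basis of ``{v : M v = 0}`` for the ``len(rows) x ncols`` matrix."""
    red, pivots = rref(rows, ncols)
    free = [c for c in range(ncols) if c not in pivots]
    basis: list[Vec] = []
    for fc in free:
        v = [ZERO] * ncols
        v[fc] = ONE
        for r, pc in enumerate(pivots):
            v[pc] = -red[r][fc]
        basis.append(tuple(v))
    return basis


def mat_vec(rows: Sequence[Sequence[Fraction]], v: Sequence[Fraction]) -> list[Fraction]:
    return [sum((a * b for a, b in zip(row, v) if a), ZERO) for row in rows]


def invert(rows: Sequence[Sequence[Fraction]]) -> list[list[Fraction]] | None:
    """Inverse of a square rational matrix, or None if singular."""
    n = len(rows)
    aug = [list(rows[i]) + [ONE if j == i else ZERO for j in range(n)] for i in range(n)]
    for c in range(n):
        piv = None
        for i in range(c, n):
            if aug[i][c]:
                piv = i
                break
        if piv is None:
            return None
        aug[c], aug[piv] = aug[piv], aug[c]
        inv = ONE / aug[c][c]
        if inv != 1:
            aug[c] = [x * inv for x in aug[c]]
        rc = aug[c]
        for i in range(n):
            if i != c and aug[i][c]:
                f = aug[i][c]
                ai = aug[i]
                for j in range(c, 2 * n):
                    if rc[j]:
                        ai[j] -= f * rc[j]
    return [row[n:] for row in aug]


def solve_particular(rows: Iterable[Sequence], rhs: Sequence, ncols: int):
    """One exact solution of ``M x = rhs`` or None if inconsistent."""
    aug = [list(r) + [Fraction(b)] for r, b in zip(frac_rows(rows), rhs)]
    red, pivots = rref(aug, ncols + 1)
    if ncols in pivots:
        return None
    x = [ZERO] * ncols
    for r, pc in enumerate(pivots):
        x[pc] = red[r][ncols]
    return tuple(x)


def gcd_normalize(vec: Sequence[Fraction]) -> Vec:
    """Scale *vec* to coprime integers; first nonzero entry made positive.

    The canonical representative of a ray direction.  Returns the zero
    vector unchanged.
    """
    den = 1
    for x in vec:
        if x:
            den = den * x.denominator // gcd(den, x.denominator)
    ints = [int(x * den) for x in vec]
    g = 0
    for v in ints:
        g = gcd(g, v)
    if g == 0:
        return tuple(Fraction(0) for _ in ints)
    lead = next(v for v in ints if v)
    if lead < 0:
        g = -g
    return tuple(Fraction(v // g) for v in ints)


def support_bits(vec: Sequence[Fraction]) -> int:
    """Support of *vec* as a bitmask (bit i set iff vec[i] != 0)."""
    bits = 0
    for i, x in enumerate(vec):
        if x:
            bits |= 1 << i
    return bits


def mode_sort_key(vec: Sequence[Fraction]):
    """Canonical ordering: by support bitmask, then by value lexicographically."""
    return (support_bits(vec), tuple(vec))
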