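"""Geometric formulations of the enumeration problem and lrs file interop.

Three H-form objects describe the same biology at different levels of
generality:

* :class:`FluxCone` -- ``{r : N r = 0, r >= 0}``, the steady-state cone of a
  reversible-split network; extreme rays are the EFMs (up to two-cycles).
* :class:`PolyhedronH` -- adds inhomogeneous capacity constraints
  ``E x >= f``; extreme points are EFVs, extreme rays EFMs.
* :class:`ConeH` -- the homogenization of a polyhedron, one slack variable
  zeta higher; setting ``zeta = 1`` recovers the polyhedron.

The transformations between them (reversible splitting, homogenization,
slack embedding into a flux cone, dehomogenization) are exact and logged in
:class:`TransformRecord` so every enumerated mode maps back to the original
reaction space.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from fractions import Fraction
from math import gcd
from typing import Sequence

from ._linalg import Vec, nullspace
from .model import BoundsTable, MetabolicModel
from .postprocess import FluxMode, ModeSet

ZERO = Fraction(0)
ONE = Fraction(1)


def _matrix(rows) -> tuple[Vec, ...]:
    return tuple(tuple(Fraction(x) for x in row) for row in rows)


def _vector(v) -> Vec:
    return tuple(Fraction(x) for x in v)


@dataclass(frozen=True)
class GeneralHRep:
    """General H-representation ``A x >= b``; rows in *linearity_rows* are
    read as equalities (the lrs ``linearity`` convention)."""

    A: tuple[Vec, ...]
    b: Vec
    linearity_rows: frozenset[int] = frozenset()
    var_ids: tuple[str, ...] | None = None
    name: str = "polyhedron"

    def __post_init__(self):
        object.__setattr__(self, "A", _matrix(self.A))
        object.__setattr__(self, "b", _vector(self.b))
        object.__setattr__(self, "linearity_rows", frozenset(self.linearity_rows))
        if len(self.A) != len(self.b):
            raise ValueError("A and b row counts differ")
        if any(i < 0 or i >= len(self.A) for i in self.linearity_rows):
            raise ValueError("linearity row index out of range")
        nv = self.n_vars
        if self.var_ids is None:
            object.__setattr__(self, "var_ids", tuple(f"x{i}" for i in range(nv)))
        elif len(self.var_ids) != nv:
            raise ValueError("var_ids length mismatch")

    @property
    def n_vars(self) -> int:
        return len(self.A[0]) if self.A else (len(self.var_ids or ()))

    def as_general(self) -> "GeneralHRep":
        return self


@dataclass(frozen=True)
class PolyhedronH:
    """``{x : C x = d, E x >= f, x >= 0}`` -- variables already sign-split."""

    C: tuple[Vec, ...]
    d: Vec
    E: tuple[Vec, ...]
    f: Vec
    var_ids: tuple[str, ...]
    name: str = "polyhedron"

    def __post_init__(self):
        object.__setattr__(self, "C", _matrix(self.C))
        object.__setattr__(self, "d", _vector(self.d))
        object.__setattr__(self, "E", _matrix(self.E))
        object.__setattr__(self, "f", _vector(self.f))
        object.__setattr__(self, "var_ids", tuple(self.var_ids))
        l = len(self.var_ids)
        if any(len(r) != l for r in self.C) or any(len(r) != l for r in self.E):
            raise ValueError("row length does not match var count")
        if len(self.C) != len(self.d) or len(self.E) != len(self.f):
            raise ValueError("matrix/vector row counts differ")

    @property
    def n_vars(self) -> int:
        return len(self.var_ids)

    @property
    def nonneg(self) -> tuple[bool, ...]:
        return (True,) * self.n_vars

    def as_general(self) -> GeneralHRep:
        l = self.n_vars
        eye = [[ONE if j == i else ZERO for j in range(l)] for i in range(l)]
        A = list(self.C) + list(self.E) + eye
        b = list(self.d) + list(self.f) + [ZERO] * l
        return GeneralHRep(
            A, b, frozenset(range(len(self.C))), self.var_ids, self.name
        )


@dataclass(frozen=True)
class ConeH:
    """Homogenized cone ``{y : G y = 0, H y >= 0}``; the homogenizing
    variable zeta is the last coordinate."""

    G: tuple[Vec, ...]
    H: tuple[Vec, ...]
    var_ids: tuple[str, ...]
    name: str = "cone"

    def __post_init__(self):
        object.__setattr__(self, "G", _matrix(self.G))
        object.__setattr__(self, "H", _matrix(self.H))
        object.__setattr__(self, "var_ids", tuple(self.var_ids))
        l1 = len(self.var_ids)
        if any(len(r) != l1 for r in self.G) or any(len(r) != l1 for r in self.H):
            raise ValueError("row length does not match var count")

    @property
    def n_vars(self) -> int:
        return len(self.var_ids)

    @property
    def zeta_index(self) -> int:
        return self.n_vars - 1

    def as_general(self) -> GeneralHRep:
        A = list(self.G) + list(self.H)
        b = [ZERO] * (len(self.G) + len(self.H))
        return GeneralHRep(
            A, b, frozenset(range(len(self.G))), self.var_ids, self.name
        )


@dataclass(frozen=True)
class FluxCone:
    """``{r : N r = 0, r >= 0}`` over named (already irreversible) reactions."""

    N: tuple[Vec, ...]
    reaction_ids: tuple[str, ...]
    name: str = "flux_cone"

    def __post_init__(self):
        object.__setattr__(self, "N", _matrix(self.N))
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        n = len(self.reaction_ids)
        if any(len(r) != n for r in self.N):
            raise ValueError("N row length does not match reaction count")

    @property
    def n_vars(self) -> int:
        return len(self.reaction_ids)

    def as_general(self) -> GeneralHRep:
        n = self.n_vars
        eye = [[ONE if j == i else ZERO for j in range(n)] for i in range(n)]
        A = list(self.N) + eye
        b = [ZERO] * (len(self.N) + n)
        return GeneralHRep(
            A, b, frozenset(range(len(self.N))), self.reaction_ids, self.name
        )


@dataclass(frozen=True)
class TransformRecord:
    """Bookkeeping mapping transformed variables back to original reactions.

    ``split_pairs`` maps each original reaction id to its (forward column,
    reverse column or None) in the transformed space; ``slack_columns`` and
    ``zeta_column`` locate the xi / zeta variables of the flux-cone
    embedding.
    """

    original_ids: tuple[str, ...]
    split_pairs: dict[str, tuple[int, int | None]]
    slack_columns: tuple[int, ...] = ()
    zeta_column: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "original_ids", tuple(self.original_ids))
        object.__setattr__(self, "slack_columns", tuple(self.slack_columns))
        used: set[int] = set()
        for rid in self.original_ids:
            if rid not in self.split_pairs:
                raise ValueError(f"reaction {rid} missing from split_pairs")
            fwd, bwd = self.split_pairs[rid]
            for c in (fwd,) + ((bwd,) if bwd is not None else ()):
                if c in used:
                    raise ValueError("transform columns overlap")
                used.add(c)
        for c in self.slack_columns:
            if c in used:
                raise ValueError("slack column overlaps reaction column")
            used.add(c)
        if self.zeta_column is not None and self.zeta_column in used:
            raise ValueError("zeta column overlaps another column")

    # JSON round trip (rationals never appear here; indices only)
    def to_json(self, path) -> None:
        payload = {
            "original_ids": list(self.original_ids),
            "split_pairs": {
                rid: [fwd, bwd] for rid, (fwd, bwd) in self.split_pairs.items()
            },
            "slack_columns": list(self.slack_columns),
            "zeta_column": self.zeta_column,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TransformRecord":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            tuple(payload["original_ids"]),
            {
                rid: (fwd, bwd)
                for rid, (fwd, bwd) in payload["split_pairs"].items()
            },
            tuple(payload["slack_columns"]),
            payload["zeta_column"],
        )


# ---------------------------------------------------------------------------
# transformations


def split_reversible(model: MetabolicModel):
    """Replace each reversible reaction by two counteracting irreversible
    ones; the reverse column sits immediately after its forward and carries
    the ``_rev`` suffix.  Returns ``(split_model, TransformRecord)``."""
    cols: list[Vec] = []
    ids: list[str] = []
    pairs: dict[str, tuple[int, int | None]] = {}
    for j, rid in enumerate(model.reaction_ids):
        col = model.column(j)
        pairs[rid] = (len(cols), len(cols) + 1 if model.rev[j] else None)
        ids.append(rid)
        cols.append(col)
        if model.rev[j]:
            ids.append(rid + "_rev")
            cols.append(tuple(-x for x in col))
    split = MetabolicModel(
        metabolite_ids=model.metabolite_ids,
        reaction_ids=tuple(ids),
        S=tuple(
            tuple(cols[j][i] for j in range(len(cols)))
            for i in range(model.n_metabolites)
        ),
        rev=(False,) * len(ids),
    )
    record = TransformRecord(model.reaction_ids, pairs)
    return split, record


def build_polyhedron(
    split_model: MetabolicModel,
    bounds: BoundsTable | None = None,
    record: TransformRecord | None = None,
    name: str = "polyhedron",
) -> PolyhedronH:
    """Assemble the flux polyhedron of a reversible-split model.

    ``C x = 0`` is the steady-state condition; each bound becomes one row of
    ``E x >= f`` (a ``<=`` bound is negated).  A bound on an originally
    reversible reaction constrains the *net* flux forward - reverse through
    a two-entry row, which requires the :class:`TransformRecord` from
    :func:`split_reversible`.
    """
    if any(split_model.rev):
        raise ValueError("model must be reversible-split first")
    n = split_model.n_reactions
    if record is None:
        record = TransformRecord(
            split_model.reaction_ids,
            {rid: (j, None) for j, rid in enumerate(split_model.reaction_ids)},
        )
    E: list[list[Fraction]] = []
    f: list[Fraction] = []
    if bounds is not None:
        for rid, rel, val in bounds.entries:
            if rid not in record.split_pairs:
                raise KeyError(f"bound references unknown reaction {rid!r}")
            fwd, bwd = record.split_pairs[rid]
            row = [ZERO] * n
            sign = ONE if rel == ">=" else -ONE
            row[fwd] = sign
            if bwd is not None:
                row[bwd] = -sign
            E.append(row)
            f.append(sign * val)
    return PolyhedronH(
        C=split_model.S,
        d=(ZERO,) * split_model.n_metabolites,
        E=E,
        f=f,
        var_ids=split_model.reaction_ids,
        name=name,
    )


def as_polyhedron(rep: GeneralHRep, name: str | None = None) -> PolyhedronH:
    """Reinterpret a general H-rep whose feasible set lies in the
    nonnegative orthant as a :class:`PolyhedronH`.

    Linearity rows become ``C x = d``; all other rows go to ``E x >= f``
    (explicit unit rows ``x_i >= 0`` are absorbed into the implicit
    nonnegativity block).  The caller asserts nonnegativity; it is not
    verified here.
    """
    C, d, E, f = [], [], [], []
    nv = rep.n_vars
    for i, (row, rhs) in enumerate(zip(rep.A, rep.b)):
        if i in rep.linearity_rows:
            C.append(row)
            d.append(rhs)
            continue
        nz = [j for j, x in enumerate(row) if x]
        if len(nz) == 1 and row[nz[0]] > 0 and rhs == 0:
            continue  # plain x_j >= 0, already implied
        E.append(row)
        f.append(rhs)
    return PolyhedronH(C, d, E, f, rep.var_ids, name or rep.name)


def homogenize(P: PolyhedronH) -> ConeH:
    """Embed *P* one dimension higher: ``G = (C | -d)``, ``H`` stacks
    ``(E | -f)``, the nonnegativity rows of the original variables, and
    ``zeta >= 0``.  Any solution with ``zeta = 1`` satisfies *P* exactly."""
    l = P.n_vars
    G = [list(row) + [-dv] for row, dv in zip(P.C, P.d)]
    H = [list(row) + [-fv] for row, fv in zip(P.E, P.f)]
    for i in range(l):
        H.append([ONE if j == i else ZERO for j in range(l)] + [ZERO])
    H.append([ZERO] * l + [ONE])
    return ConeH(G, H, P.var_ids + ("zeta",), name=P.name + "_pc")


def to_flux_cone(P: PolyhedronH):
    """Slack-embed *P* into a flux cone: ``N = [[C, 0, -d], [E, -I, -f]]``
    with variable order ``(x..., xi..., zeta)``.  Returns
    ``(FluxCone, TransformRecord)`` locating the xi and zeta columns."""
    l, k2 = P.n_vars, len(P.E)
    rows = []
    for row, dv in zip(P.C, P.d):
        rows.append(list(row) + [ZERO] * k2 + [-dv])
    for i, (row, fv) in enumerate(zip(P.E, P.f)):
        slack = [-ONE if j == i else ZERO for j in range(k2)]
        rows.append(list(row) + slack + [-fv])
    ids = P.var_ids + tuple(f"xi{i}" for i in range(k2)) + ("zeta",)
    record = TransformRecord(
        P.var_ids,
        {rid: (j, None) for j, rid in enumerate(P.var_ids)},
        slack_columns=tuple(range(l, l + k2)),
        zeta_column=l + k2,
    )
    return FluxCone(rows, ids, name=P.name + "_fc"), record


def dehomogenize(modes: ModeSet, record: TransformRecord) -> ModeSet:
    """Project cone rays back to the original variables.

    Rays with ``zeta > 0`` are rescaled to ``zeta = 1`` and become EFVs
    (extreme points); rays with ``zeta = 0`` are EFMs (recession
    directions), gcd-normalized.  Slack and zeta coordinates are dropped.
    The zero vector maps to the zero EFV whenever the origin is a vertex
    of the polyhedron (e.g. for any pure cone); callers that do not want
    the trivial mode drop it downstream.
    """
    if record.zeta_column is None:
        raise ValueError("record has no zeta column; nothing to dehomogenize")
    zc = record.zeta_column
    keep = [record.split_pairs[rid][0] for rid in record.original_ids]
    out = []
    for mode in modes:
        zeta = mode.values[zc]
        if zeta < 0:
            raise ValueError("mode violates zeta >= 0")
        if zeta > 0:
            vals = tuple(mode.values[j] / zeta for j in keep)
            out.append(FluxMode(vals, "efv"))
        else:
            vals = tuple(mode.values[j] for j in keep)
            if any(vals):
                out.append(FluxMode(vals, "efm"))
    return ModeSet(tuple(record.original_ids), tuple(out))


# ---------------------------------------------------------------------------
# pointedness and redundancy


def lineality_witness(rep) -> Vec | None:
    """A nonzero vector of the lineality space, or None if pointed."""
    g = rep.as_general()
    basis = nullspace(g.A, g.n_vars)
    return basis[0] if basis else None


def assert_pointed(rep) -> None:
    w = lineality_witness(rep)
    if w is not None:
        raise ValueError(
            f"input is not pointed; lineality direction {tuple(map(str, w))}"
        )


def remove_redundant_rows(obj, tol: float = 1e-9):
    """Drop inequality rows that cannot be tight on the feasible set.

    Row i is removed iff minimizing its left-hand side subject to every
    *surviving* other constraint already attains at least its right-hand
    side (an LP certificate that the feasible set is unchanged).  Rows are
    scanned in ascending index order, so of two duplicated rows exactly the
    first is removed.  Equality (linearity) rows are never touched.

    Accepts :class:`GeneralHRep`, :class:`PolyhedronH` or :class:`ConeH`;
    returns ``(same_type, removed_report)``.
    """
    import numpy as np
    from scipy.optimize import linprog

    g = obj.as_general()
    nv = g.n_vars
    eq_rows = sorted(g.linearity_rows)
    ineq_rows = [i for i in range(len(g.A)) if i not in g.linearity_rows]
    A_eq = (
        np.array([[float(x) for x in g.A[i]] for i in eq_rows])
        if eq_rows
        else None
    )
    b_eq = np.array([float(g.b[i]) for i in eq_rows]) if eq_rows else None

    # feasibility probe
    A_ub0 = np.array([[-float(x) for x in g.A[i]] for i in ineq_rows])
    b_ub0 = np.array([-float(g.b[i]) for i in ineq_rows])
    probe = linprog(
        np.zeros(nv), A_ub=A_ub0 if len(ineq_rows) else None,
        b_ub=b_ub0 if len(ineq_rows) else None, A_eq=A_eq, b_eq=b_eq,
        bounds=[(None, None)] * nv, method="highs",
    )
    if probe.status == 2:
        raise ValueError("system is infeasible; refusing redundancy removal")

    surviving = list(ineq_rows)
    removed: list[int] = []
    for row_idx in list(ineq_rows):
        others = [i for i in surviving if i != row_idx]
        c = np.array([float(x) for x in g.A[row_idx]])
        A_ub = (
            np.array([[-float(x) for x in g.A[i]] for i in others])
            if others
            else None
        )
        b_ub = np.array([-float(g.b[i]) for i in others]) if others else None
        res = linprog(
            c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
            bounds=[(None, None)] * nv, method="highs",
        )
        if res.status == 0 and res.fun >= float(g.b[row_idx]) - tol:
            surviving.remove(row_idx)
            removed.append(row_idx)

    report = {"removed_rows": removed}
    if isinstance(obj, GeneralHRep):
        keep = sorted(eq_rows + surviving)
        remap = {old: new for new, old in enumerate(keep)}
        out = GeneralHRep(
            tuple(g.A[i] for i in keep),
            tuple(g.b[i] for i in keep),
            frozenset(remap[i] for i in eq_rows),
            g.var_ids,
            g.name,
        )
        return out, report
    if isinstance(obj, PolyhedronH):
        # general-form row i maps to: C rows, then E rows, then nonneg rows
        k1 = len(obj.C)
        kept_E = [
            i - k1
            for i in surviving
            if k1 <= i < k1 + len(obj.E)
        ]
        out = PolyhedronH(
            obj.C, obj.d,
            tuple(obj.E[i] for i in kept_E),
            tuple(obj.f[i] for i in kept_E),
            obj.var_ids, obj.name,
        )
        report["removed_rows"] = [
            i - k1 for i in removed if k1 <= i < k1 + len(obj.E)
        ]
        return out, report
    if isinstance(obj, ConeH):
        k1 = len(obj.G)
        kept_H = [i - k1 for i in surviving]
        out = ConeH(
            obj.G, tuple(obj.H[i] for i in kept_H), obj.var_ids, obj.name
        )
        report["removed_rows"] = [i - k1 for i in removed]
        return out, report
    raise TypeError(f"unsupported type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# lrs file dialect


def _integerize(row: Sequence[Fraction]) -> list[int]:
    den = 1
    for x in row:
        if x:
            den = den * x.denominator // gcd(den, x.denominator)
    ints = [int(x * den) for x in row]
    g = 0
    for v in ints:
        g = gcd(g, v)
    if g > 1:
        ints = [v // g for v in ints]
    return ints


def write_lrs_ine(obj, path, name: str | None = None) -> None:
    """Write an lrs H-representation (.ine).

    Each constraint ``a x >= b`` becomes the row ``(-b, a)`` per the lrs
    convention; rows are scaled to coprime integers, and ``linearity``
    indices are 1-based.
    """
    g = obj.as_general()
    lin = sorted(g.linearity_rows)
    with open(path, "w") as fh:
        fh.write(f"{name or g.name}\n")
        fh.write("H-representation\n")
        if lin:
            fh.write(
                f"linearity {len(lin)} " + " ".join(str(i + 1) for i in lin) + "\n"
            )
        fh.write("begin\n")
        fh.write(f"{len(g.A)} {g.n_vars + 1} rational\n")
        for row, rhs in zip(g.A, g.b):
            ints = _integerize([-rhs] + list(row))
            fh.write(" ".join(str(v) for v in ints) + "\n")
        fh.write("end\n")


def parse_lrs_ine(path) -> GeneralHRep:
    """Parse an lrs H-representation back into a :class:`GeneralHRep`."""
    with open(path) as fh:
        lines = fh.readlines()
    name = "polyhedron"
    lin: list[int] = []
    i = 0
    body_start = None
    ncols = nrows = None
    for i, line in enumerate(lines):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "H-representation":
            continue
        if tok[0] == "linearity":
            lin = [int(t) - 1 for t in tok[2:]]
        elif tok[0] == "begin":
            hdr = lines[i + 1].split()
            if len(hdr) < 2:
                raise ValueError(f"{path}:{i + 2}: malformed size header")
            nrows, ncols = int(hdr[0]), int(hdr[1])
            body_start = i + 2
            break
        elif body_start is None and tok[0] not in ("V-representation",):
            if i == 0:
                name = line.strip()
    if body_start is None:
        raise ValueError(f"{path}: no 'begin' section found")
    A, b = [], []
    for k in range(nrows):
        tok = lines[body_start + k].split()
        if len(tok) != ncols:
            raise ValueError(f"{path}:{body_start + k + 1}: expected {ncols} fields")
        vals = [Fraction(t) for t in tok]
        b.append(-vals[0])
        A.append(tuple(vals[1:]))
    return GeneralHRep(tuple(A), tuple(b), frozenset(lin), None, name)


def write_lrs_ext(vertices, rays, n_vars: int, path, name: str = "output") -> None:
    """Write an lrs V-representation (.ext): leading field 1 marks a vertex
    row, 0 a ray row."""
    with open(path, "w") as fh:
        fh.write(f"{name}\n")
        fh.write("V-representation\n")
        fh.write("begin\n")
        fh.write(f"{len(vertices) + len(rays)} {n_vars + 1} rational\n")
        for v in vertices:
            fh.write("1 " + " ".join(str(Fraction(x)) for x in v) + "\n")
        for r in rays:
            ints = _integerize(list(r))
            fh.write("0 " + " ".join(str(v) for v in ints) + "\n")
        fh.write("end\n")


def parse_lrs_ext(path):
    """Parse an lrs V-representation; returns ``(vertices, rays)`` as lists
    of exact rational tuples."""
    with open(path) as fh:
        lines = fh.readlines()
    body_start = None
    nrows = ncols = None
    for i, line in enumerate(lines):
        tok = line.split()
        if tok and tok[0] == "begin":
            hdr = lines[i + 1].split()
            if len(hdr) < 2:
                raise ValueError(f"{path}:{i + 2}: malformed size header")
            nrows, ncols = int(hdr[0]), int(hdr[1])
            body_start = i + 2
            break
    if body_start is None:
        raise ValueError(f"{path}: no 'begin' section found")
    vertices, rays = [], []
    row = 0
    k = body_start
    while row < nrows:
        if k >= len(lines):
            raise ValueError(f"{path}: truncated body")
        tok = lines[k].split()
        k += 1
        if not tok:
            continue
        if tok[0] == "end":
            raise ValueError(f"{path}:{k}: premature 'end'")
        if len(tok) != ncols:
            raise ValueError(f"{path}:{k}: expected {ncols} fields")
        lead = tok[0]
        vals = tuple(Fraction(t) for t in tok[1:])
        if lead == "1":
            vertices.append(vals)
        elif lead == "0":
            rays.append(vals)
        else:
            raise ValueError(f"{path}:{k}: leading field must be 0 or 1")
        row += 1
    return vertices, rays


def write_ine(obj, path, name=None):  # pragma: no cover - thin alias
    write_lrs_ine(obj, path, name)
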